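# Methods

## Problem and model

Barcoded bulk RNA sequencing (SPIso-seq, Loop-Seq, Tell-Seq) attaches a
molecular barcode to each mRNA before fragmentation, so the paired-end short
reads sharing a barcode — a *read cloud* — sample one transcript molecule.
Per-cloud coverage is very low (around 1x), so assembling each cloud in
isolation fragments badly.  isocloud instead:

1. builds one compacted, double-stranded de Bruijn graph from **all** reads
   combined, where coverage is deep enough to be clean after light
   simplification;
2. reconstructs each cloud's isoform as a path in that shared graph, using
   the cloud's own alignments to select and clean a small subgraph;
3. clusters equivalent paths across barcodes and counts distinct supporting
   barcodes as an abundance estimate, since two isoforms of one gene almost
   never share a barcode.

The central assumption is barcode purity: one barcode ≈ one molecule.  A
configurable collision rate in the simulator, and the multi-isoform barcode
filter in the pipeline, handle the exceptions.

## Graph construction and global simplification

The graph is node-centric on (k-1)-mers with unitig edges, closed under
reverse complement (every edge has a twin; operations are symmetric).  k
must be odd so no k-mer is its own reverse complement; palindromic
(k-1)-mer *junctions* can still occur and always terminate unitigs —
crossing one would fuse a unitig with its own twin.  Reads are split at
ambiguous bases rather than discarded, to avoid biasing thin clouds.

Global simplification is deliberately minimal, in three cycled stages:

* **coverage pruning** — edges below an absolute floor
  (`min_coverage = 2`) *or* below `rel_err_frac = 0.02` x the coverage of
  their best-covered adjacent edge are removed.  The relative component is
  essential: substitution errors recur in proportion to depth (an
  erroneous k-mer appears roughly error_rate/3 as often as its true
  counterpart, ~0.2% at our 0.5% error rate), so at deep coverage an
  absolute floor alone leaves error edges standing.  0.02 sits an order of
  magnitude above the expected error ratio and a factor of ~3 below the
  relative coverage of the rarest true junction in a 16-isoform gene with
  uniform expression (1/16).
* **tip clipping** — dead-end/dead-start edges shorter than `tip_len = 2k`
  whose coverage is below their adjacent continuation.
* **bulge removal** — of two edge-disjoint parallel walks of <= 2 edges
  with spelled-length ratio >= `bulge_similarity = 0.8`, the lower-covered
  side is removed (equal coverage: lexicographically larger spelling
  loses).  Similarity 0 disables the stage, making the all-zero threshold
  configuration an exact no-op.

All removals operate on the underlying k-mer multiset and the graph is
re-compacted, which keeps twin symmetry and maximality invariants by
construction.

## Read-to-graph alignment

Reads are anchored at their first exact k-mer hit (unique by construction
in a compacted graph) and threaded outward base by base, substitutions
only, with a budget of `ceil(0.03 x read length)`.  At a junction the
extension takes the single branch whose next base matches; a lone branch
may consume a mismatch; anything else truncates the alignment — chimeric
walks are worse than short ones.  Both read orientations are tried; the
longer alignment wins, with deterministic tie-breaking (fewer mismatches,
then '+' orientation, then smallest edge-id walk).  Indels are not
threaded: the simulator and the dominant short-read error mode are
substitutions, and substitution-only threading is linear-time.

## Cloud subgraphs and local simplification

A cloud's subgraph is the set of edges its alignments touch, annotated per
edge with barcode-specific coverage — aligned-base depth (cloud bases on
the edge / edge length), because k-mer multiplicities are uninformative at
1x — and the extreme (leftmost/rightmost) alignment positions, which
later become the terminal offsets distinguishing isoforms that differ only
at their ends.  Junction-overlap bases count toward both flanking edges;
this slightly inflates depth but keeps extents exact.

Three procedures cycle (at most `max_cycles = 10` times, normally 2-3) to a
fixpoint:

* **tip clipping** (`max_tip_len = 2k`, `rel_cov = 0.33`): a subgraph
  dead-end/dead-start is clipped when short or when dominated by its
  neighbour's barcode coverage — but only when its attachment junction has
  an alternative cloud continuation.  Without that spur condition the
  terminal edges of every genuine simple path would be candidates, and
  clipping them would eat real isoform sequence; the sole edge of a
  component is likewise protected.
* **bulge removal** (`cov_ratio = 0.5`): between walks of <= 3 member
  edges sharing both junctions, a side whose minimum barcode coverage is
  dominated loses its private edges; mutual domination resolves by
  spelled-sequence order.
* **gap closing** (`max_gap_edge_len = 150`, <= 3 edges): uncovered parent
  edges are pulled in when they form the *unique* short connection between
  a path end and a path start.  Joining two different connected components
  additionally requires at least one read pair linking them.  This linkage
  gate is what protects precision: a genuine junction coverage gap is
  spanned by insert-sized pairs, whereas two fragments separated by a
  whole unread exon cannot be linked by any contiguous fragment of the
  true molecule — closing such a gap through the exon-skipping junction
  edge would fabricate a chimeric isoform that classifies uniquely and
  *wrongly*.  Ambiguous (>= 2 candidate walks) or over-long gaps stay
  open; a fragmented cloud is recoverable downstream (fixed recall), a
  chimeric one is not.

## Path extraction and clustering

Paths are seeded on the longest unconsumed edge and extended in both
directions.  At a junction with several member branches, each branch is
scored by the cloud links — read pairs with one mate on the path and one
in the branch's *territory* (edges reachable only through that branch),
plus single reads whose own walk spans from the path into it — and the
branch with strictly more support wins; otherwise extension stops rather
than forking.  Scoring territories instead of bare branch edges matters
because gap-filled edges carry no reads: the evidence for taking them
lives beyond them.  An edge may be traversed twice in one walk (short
internal repeats) but only in the same orientation — stepping onto the
twin of an edge already in the walk would fold the path into a hairpin at
palindromic junctions.  Edges consumed by one path are off-limits to later
paths of the same cloud (one molecule, edge-disjoint isoform paths).
Spelled paths shorter than `min_contig_len = 300` bp are dropped.

Clustering across barcodes is greedy and representative-based: sorted
paths join the first cluster with the identical edge walk (a walk and its
reverse complement unify) whose founder offsets differ by at most
`offset_tol = 10` bp at both termini, else found a new cluster.  Greedy
assignment keeps the result a deterministic partition despite the
non-transitive tolerance.  Cluster abundance is the number of distinct
supporting barcodes; no further expression modelling is attempted.

## Filtering

* **min-barcode filter**: keep clusters with >= `min_barcodes` supporters.
* **multi-isoform barcode fix**: when one barcode supports >= 2 clusters
  in the same gene locus — reference-free, a locus is a weakly connected
  component of the simplified global graph — the cloud was fragmented or
  collided, and that barcode's support is withdrawn from those clusters
  (emptied clusters are dropped).  Support removal, not whole-contig
  removal, is the conservative reading: other barcodes may still support
  the contig.

## Synthetic data

The generator emulates sparse isoform sequencing.  Genes are random exon
blocks (default 150-400 bp, long relative to k so each exon interior forms
its own unitig, near the scale of human internal exons); isoforms are
distinct increasing exon subsets that always retain both terminal exons,
producing the shared-flank bubble structures that make isoform assembly
hard.  Expression is uniform across isoforms by default.

Cloud sizes follow a zero-truncated negative binomial with size r = 1.2
and success probability solved numerically (0.147389) so that
P(>= 5 pairs | >= 1 pair) = 320/539 ≈ 0.594, the fraction observed in real
sparse-isoform data; the truncated mean is ~7.7 pairs ≈ 1x of a ~1.5 kb
transcript.  The shape parameter itself is unconstrained by any published
value; r = 1.2 gives the over-dispersed many-tiny-clouds regime the method
targets.  Reads are 100 bp pairs with Gaussian inserts (250 ± 30 bp,
clipped to the transcript), uniform fragment placement and uniform
substitution errors (default 0.5%).  With probability
`barcode_collision_rate = 0.001` a cloud carries a second molecule from a
*different* gene (cross-gene only: same-gene collisions are vanishingly
unlikely in a large barcode space).  A `fixed_coverage` mode replaces the
size draw with a deterministic per-cloud coverage for oracle scenarios.

What the simulator does **not** emulate: indels, quality-dependent or
position-dependent error profiles, PCR duplicates, intron retention or
exon shuffling, expression skew, rRNA/adapter contamination, and real
human gene sequence composition.  Passing tests therefore demonstrate the
algorithmic contract (graph correctness, cloud deconvolution, linkage
logic, determinism) under the stated statistical regime — not performance
on real libraries.

Uniform fragment placement has an edge effect: the outermost few bases of
a transcript are rarely sequenced, so assembled contigs typically start
and end a few bases inside the true termini.  Evaluation uses infix
matching and is insensitive to this.

## Evaluation

Each cluster contig is compared to every truth isoform by strand-agnostic
infix edit distance (edlib); an isoform qualifies at <= 1% of contig
length.  Exactly one qualifying isoform → unique (distance 0) or
unique-with-minor-difference; several → ambiguous; none → inconsistent;
contigs under 300 bp are non-informative.  Per barcode: uniquely assigned
means exactly one unique-category contig and no gene receiving two of the
barcode's contigs.  Precision is correct/uniquely-assigned; recall divides
correct unique barcodes by all truth barcodes with >= 5 pairs; fixed
recall removes barcodes that produced >= 2 contigs for one gene from the
denominator — the self-diagnostic available on real data, where such
barcodes indicate fragmented clouds or collisions.  These denominators are
an explicit choice; the per-barcode comparison concept they implement has
no canonical closed form.

## Numerical and determinism notes

* Coordinates are 0-based half-open everywhere (edge offsets, extents).
* All randomness flows from explicit seeds through `numpy.random.Generator`;
  fixed seed + fixed input ⇒ byte-identical FASTA/TSV/GFA outputs.
* Ties anywhere (anchor choice, bulge sides, cluster order, seeds for path
  extraction) break lexicographically on edge ids or spelled sequences.
* Degenerate inputs: empty FASTQ and barcode-less records produce empty
  outputs plus warnings, not exceptions; even k and infeasible isoform
  counts raise parameter errors.

## Problem sizes used by the test-suite and acceptance script

The complex-gene scenario runs one 6-exon, 16-isoform gene with 1,000
clouds (five replicates in the test suite); the noiseless oracle uses 20
single-isoform genes with 200 clouds at 3x per cloud, enough pooled depth
(~30x per gene) for a gap-free global graph; calibration is checked on
10,000 cloud-size draws.  These sizes give stable metrics at desk scale —
a full run of everything completes in about a minute on one CPU.

## Known limitations

* Substitution-only alignment: an indel-bearing read truncates at the
  indel; at short-read indel rates this is negligible, but the aligner is
  not a general sequence-to-graph aligner.
* Whole-exon coverage dropouts in a cloud fragment that cloud's isoform
  (by design — the linkage gate refuses to guess); such barcodes lower
  recall and are the ones fixed recall excludes.
* The gene-locus proxy (connected component) merges genes that share
  sequence; on synthetic data with random exons this never happens, on
  real genomes paralogs would blur the multi-isoform filter.
* Bulge search is bounded (<= 2 edges globally, <= 3 per cloud); deeply
  nested error structures at extreme depth can survive, though relative
  coverage pruning removes almost all of them first.
* Abundances are raw barcode counts; no length or capture-efficiency
  normalization is applied.
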