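"""Isoform path extraction from simplified cloud subgraphs, and clustering.

Traversal is seeded on the longest unused edge and extended in both
directions.  At a junction with several cloud branches the branch supported
by strictly more cloud-local links wins; a link is either a read pair with
one mate on the current path and one in the branch's territory, or a single
read whose own walk spans from the path into it.  A branch's territory is
the set of subgraph edges reachable only through that branch — counting the
branch edge alone would blind the rule at gap-filled edges, which carry no
reads by construction.  Without a strict majority the extension stops —
forking would fabricate isoforms the cloud cannot distinguish.  Extracted paths are clustered across barcodes by their exact
edge walk (a walk and its reverse complement are one) plus terminal offsets
within a tolerance; the number of distinct barcodes per cluster is the
isoform abundance estimate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from ._dna import revcomp
from .align import GraphAlignment
from .cloud import CloudSubgraph
from .graph import AssemblyGraph

__all__ = ["IsoformPath", "PathCluster", "extract_paths", "cluster_paths",
           "write_clusters_fasta", "write_clusters_tsv"]


@dataclass(frozen=True)
class IsoformPath:
    """One extracted isoform candidate of one cloud."""

    barcode: str
    edge_walk: Tuple[str, ...]
    start_offset: int
    end_offset: int
    sequence: str


@dataclass
class PathCluster:
    """Equivalent isoform paths pooled across barcodes."""

    cluster_id: str
    representative: IsoformPath
    members: List[IsoformPath] = field(default_factory=list)
    barcodes: Set[str] = field(default_factory=set)

    @property
    def abundance(self) -> int:
        return len(self.barcodes)

    @property
    def sequence(self) -> str:
        """Reported orientation: lexicographically smaller of seq / revcomp."""
        s = self.representative.sequence
        return min(s, revcomp(s))


# ------------------------------------------------------------------ extract


class _LinkIndex:
    """Cloud-local linkage: per-read edge sets and mate pairing."""

    def __init__(self, graph: AssemblyGraph, alignments: Sequence[GraphAlignment]):
        self.read_sets: List[frozenset] = []
        by_pair: Dict[str, List[frozenset]] = {}
        for a in alignments:
            s = frozenset(graph.canonical_id(e) for e in a.edge_walk)
            self.read_sets.append(s)
            if a.pair_id is not None:
                by_pair.setdefault(a.pair_id, []).append(s)
        self.pair_links: List[Tuple[frozenset, frozenset]] = []
        for pid in sorted(by_pair):
            mates = by_pair[pid]
            for i in range(len(mates)):
                for j in range(i + 1, len(mates)):
                    self.pair_links.append((mates[i], mates[j]))

    def support(self, path_edges: Set[str], region: Set[str]) -> int:
        """Links between the current path and a branch's territory."""
        n = 0
        for s in self.read_sets:
            if s & region and s & path_edges:
                n += 1
        for a, b in self.pair_links:
            if (a & region and b & path_edges) or (b & region and a & path_edges):
                n += 1
        return n


def _terminal_offsets(sub: CloudSubgraph, walk: Sequence[str]) -> Tuple[int, int]:
    g = sub.parent
    first, last = walk[0], walk[-1]

    def left_of(oid: str) -> int:
        st = sub.stat_of(oid)
        L = len(g.edges[oid])
        return st.leftmost if g.canonical_id(oid) == oid else L - st.rightmost

    def right_of(oid: str) -> int:
        st = sub.stat_of(oid)
        L = len(g.edges[oid])
        return st.rightmost if g.canonical_id(oid) == oid else L - st.leftmost

    start = left_of(first)
    end = right_of(last)
    if len(walk) == 1 and start >= end:
        start, end = 0, len(g.edges[first])
    return start, end


def extract_paths(
    sub: CloudSubgraph,
    cloud_alignments: Sequence[GraphAlignment],
    min_contig_len: int = 300,
) -> List[IsoformPath]:
    """Extract isoform paths from a simplified cloud subgraph.

    Seeds one path per longest unused edge, extends both directions under
    the strict-majority link rule, marks consumed edges and repeats until
    every member edge is used or unusable.  An edge may be re-entered once
    (short internal repeats) when links resolve the traversal.  Paths
    spelling fewer than ``min_contig_len`` bases are dropped.
    """
    g = sub.parent
    if not sub.stats:
        return []
    links = _LinkIndex(g, cloud_alignments)
    unused = set(sub.stats)
    used: Set[str] = set()
    paths: List[IsoformPath] = []
    max_walk = 2 * len(sub.stats) + 4

    def territory(branch: str, walk: List[str]) -> Set[str]:
        """Canonical edges reachable from ``branch`` without re-entering the path."""
        blocked = {g.canonical_id(e) for e in walk}
        seen = {g.canonical_id(branch)}
        frontier = [branch]
        for _ in range(6):  # bounded horizon; clouds are small
            nxt_frontier = []
            for oid in frontier:
                for s in sub.succ_in(oid) + sub.pred_in(oid):
                    c = g.canonical_id(s)
                    if c in seen or c in blocked:
                        continue
                    seen.add(c)
                    nxt_frontier.append(s)
            if not nxt_frontier:
                break
            frontier = nxt_frontier
        return seen

    def choose(cands: List[str], walk: List[str]) -> Optional[str]:
        counts = Counter(g.canonical_id(e) for e in walk)
        walk_set = set(walk)

        def admissible(x: str) -> bool:
            c = g.canonical_id(x)
            if counts[c] >= 2:
                return False
            if counts[c] == 1 and x not in walk_set:
                return False  # re-entry only in the same orientation (no hairpins)
            if c in used and counts[c] == 0:
                return False  # consumed by an earlier path of this cloud
            return True

        cands = sorted(x for x in set(cands) if admissible(x))
        if not cands:
            return None
        if len(cands) == 1:
            return cands[0]
        path_edges = set(counts)
        terr = {x: territory(x, walk) for x in cands}
        scored = []
        for x in cands:
            others = set().union(*(terr[y] for y in cands if y != x))
            unique_region = terr[x] - others
            scored.append((links.support(path_edges, unique_region), x))
        best = max(s for s, _ in scored)
        top = [x for s, x in scored if s == best]
        return top[0] if len(top) == 1 else None

    while unused:
        seed = sorted(unused, key=lambda c: (-len(g.edges[c]), c))[0]
        walk = [seed]
        while len(walk) < max_walk:
            nxt = choose(sub.succ_in(walk[-1]), walk)
            if nxt is None:
                break
            walk.append(nxt)
        while len(walk) < max_walk:
            prv = choose(sub.pred_in(walk[0]), walk)
            if prv is None:
                break
            walk.insert(0, prv)
        used_now = {g.canonical_id(e) for e in walk}
        unused -= used_now
        used |= used_now
        start, end = _terminal_offsets(sub, walk)
        try:
            seq = g.spell_path(walk, start, end)
        except ValueError:
            start, end = 0, len(g.edges[walk[-1]])
            seq = g.spell_path(walk, start, end)
        if len(seq) >= min_contig_len:
            paths.append(IsoformPath(sub.barcode, tuple(walk), start, end, seq))
    return paths


# ------------------------------------------------------------------ cluster


def _canonical_path_key(graph: AssemblyGraph, path: IsoformPath):
    """Orientation-invariant (walk, start, end) key for clustering."""
    walk = path.edge_walk
    rcw = graph.rc_walk(walk)
    if rcw < tuple(walk):
        first_len = len(graph.edges[walk[-1]])
        last_len = len(graph.edges[walk[0]])
        return rcw, first_len - path.end_offset, last_len - path.start_offset
    return tuple(walk), path.start_offset, path.end_offset


def cluster_paths(paths: Sequence[IsoformPath], offset_tol: int = 10,
                  graph: Optional[AssemblyGraph] = None) -> List[PathCluster]:
    """Greedy representative-based clustering of paths across barcodes.

    Two paths cluster together when their edge walks are identical (up to
    reverse complement) and both terminal offsets differ from the founder's
    by at most ``offset_tol``.  Greedy assignment to the first matching
    founder keeps the result a deterministic partition despite the
    non-transitive tolerance.
    """
    keyed = []
    for p in paths:
        if graph is not None:
            key = _canonical_path_key(graph, p)
        else:
            key = (tuple(p.edge_walk), p.start_offset, p.end_offset)
        keyed.append((key, p))
    keyed.sort(key=lambda t: (t[0][0], t[0][1], t[0][2], t[1].barcode, t[1].sequence))

    clusters: List[PathCluster] = []
    founders: Dict[Tuple[str, ...], List[Tuple[int, int, PathCluster]]] = {}
    for (walk, s, e), p in keyed:
        hit = None
        for fs, fe, c in founders.get(walk, []):
            if abs(s - fs) <= offset_tol and abs(e - fe) <= offset_tol:
                hit = c
                break
        if hit is None:
            hit = PathCluster(cluster_id=f"cluster_{len(clusters) + 1:05d}",
                              representative=p)
            clusters.append(hit)
            founders.setdefault(walk, []).append((s, e, hit))
        hit.members.append(p)
        hit.barcodes.add(p.barcode)
    return clusters


# ------------------------------------------------------------------- output


def write_clusters_fasta(clusters: Sequence[PathCluster], path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            seq = c.sequence
            fh.write(
                f">{c.cluster_id} abundance={c.abundance} "
                f"n_edges={len(c.representative.edge_walk)} length={len(seq)}\n"
            )
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_clusters_tsv(clusters: Sequence[PathCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tabundance\tn_edges\tedge_walk\tstart_offset\t"
                 "end_offset\tlength\tbarcodes\n")
        for c in clusters:
            r = c.representative
            fh.write(
                f"{c.cluster_id}\t{c.abundance}\t{len(r.edge_walk)}\t"
                f"{','.join(r.edge_walk)}\t{r.start_offset}\t{r.end_offset}\t"
                f"{len(c.sequence)}\t{','.join(sorted(c.barcodes))}\n"
            )
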