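"""Compacted double-stranded de Bruijn graph and its global simplification.

The graph is built from the *entire* read set (all clouds combined).  Nodes
are (k-1)-mers, edges are maximal non-branching k-mer paths (unitigs).  The
graph is skew-symmetric: every unitig edge has a reverse-complement twin and
all operations treat the two as one double-stranded object.  Global
simplification is deliberately light — it only prunes extremely low-coverage
edges, short low-covered tips and small bulges — because per-cloud
information is what resolves the remaining ambiguity downstream.

Edge identifiers are ``e<N>`` for the canonical orientation (sequence
lexicographically <= its reverse complement) and ``e<N>r`` for the twin; a
palindromic unitig is its own twin.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

from ._dna import canonical_kmer, revcomp, split_at_ambiguous

__all__ = [
    "UnitigEdge",
    "AssemblyGraph",
    "build_graph",
    "simplify_global",
    "spell_path",
    "write_gfa",
]


@dataclass(frozen=True)
class UnitigEdge:
    """A maximal non-branching path of the de Bruijn graph, stored compacted.

    ``coverage`` is the mean multiplicity of the edge's constituent k-mers
    over the whole read set (both strands of a k-mer count as one).
    """

    id: str
    sequence: str
    coverage: float
    rc_id: str

    @property
    def kmer_count(self) -> int:
        return len(self.sequence) - self._k + 1

    # k is attached after construction by the graph; stored privately to keep
    # the dataclass hashable/frozen on the identifying fields only.
    _k: int = field(default=0, compare=False, repr=False)

    def __len__(self) -> int:
        return len(self.sequence)


class WalkError(ValueError):
    """Raised when consecutive edges of a walk are not adjacent."""


class AssemblyGraph:
    """Compacted, double-stranded de Bruijn graph.

    Attributes
    ----------
    k : int
        k-mer size (odd).
    edges : dict
        edge id -> :class:`UnitigEdge`, both orientations present.
    kmer_cov : dict
        canonical k-mer -> multiplicity in the reads. This is the ground
        truth from which the unitig structure is (re)compacted.
    """

    def __init__(self, k: int, kmer_cov: Dict[str, float]):
        if k % 2 == 0:
            raise ValueError(f"k must be odd (got {k}); even k admits palindromic k-mers")
        if k < 3:
            raise ValueError(f"k must be >= 3 (got {k})")
        self.k = k
        self.kmer_cov = kmer_cov
        self.edges: Dict[str, UnitigEdge] = {}
        self._out: Dict[str, List[str]] = defaultdict(list)  # (k-1)-mer -> edge ids starting there
        self._in: Dict[str, List[str]] = defaultdict(list)  # (k-1)-mer -> edge ids ending there
        self.kmer_index: Dict[str, Tuple[str, int]] = {}  # oriented k-mer -> (edge id, offset)
        self._compact()

    # ------------------------------------------------------------------ build

    def _compact(self) -> None:
        k = self.k
        oriented = set()
        for c in self.kmer_cov:
            oriented.add(c)
            oriented.add(revcomp(c))

        def succs(km: str) -> List[str]:
            base = km[1:]
            return [base + b for b in "ACGT" if base + b in oriented]

        def preds(km: str) -> List[str]:
            base = km[:-1]
            return [b + base for b in "ACGT" if b + base in oriented]

        visited = set()
        unitigs: List[Tuple[str, List[str]]] = []  # (sequence, oriented kmer walk)

        def emit(walk: List[str]) -> None:
            seq = walk[0] + "".join(km[-1] for km in walk[1:])
            visited.update(walk)
            visited.update(revcomp(km) for km in walk)
            unitigs.append((seq, walk))

        def palindromic(node: str) -> bool:
            # (k-1)-mers have even length and may equal their own reverse
            # complement; crossing such a node would merge a unitig with its
            # own twin, so it always acts as a junction
            return node == revcomp(node)

        ordered = sorted(oriented)
        for km in ordered:
            if km in visited:
                continue
            ps = preds(km)
            is_start = (len(ps) != 1 or len(succs(ps[0])) != 1
                        or palindromic(km[:-1]))
            if not is_start:
                continue
            walk = [km]
            seen = {km}
            cur = km
            while True:
                if palindromic(cur[1:]):
                    break
                ss = succs(cur)
                if len(ss) != 1:
                    break
                nxt = ss[0]
                if len(preds(nxt)) != 1 or nxt in seen:
                    break
                walk.append(nxt)
                seen.add(nxt)
                cur = nxt
            emit(walk)
        # remaining oriented k-mers lie on perfect cycles; break each at its
        # smallest k-mer for determinism
        for km in ordered:
            if km in visited:
                continue
            walk = [km]
            seen = {km}
            cur = km
            while True:
                nxt = succs(cur)[0]
                if nxt in seen:
                    break
                walk.append(nxt)
                seen.add(nxt)
                cur = nxt
            emit(walk)

        # pair twins and assign deterministic ids
        by_seq: Dict[str, List[str]] = {}
        for seq, walk in unitigs:
            by_seq[seq] = walk
        canon_seqs = sorted({min(seq, revcomp(seq)) for seq in by_seq})
        for i, cseq in enumerate(canon_seqs, start=1):
            rseq = revcomp(cseq)
            cid, rid = f"e{i}", f"e{i}r"
            if cseq == rseq:
                rid = cid
            cov = self._mean_cov(cseq)
            self.edges[cid] = UnitigEdge(cid, cseq, cov, rid, _k=self.k)
            if rid != cid:
                self.edges[rid] = UnitigEdge(rid, rseq, cov, cid, _k=self.k)

        for eid in sorted(self.edges):
            seq = self.edges[eid].sequence
            self._out[seq[: k - 1]].append(eid)
            self._in[seq[-(k - 1):]].append(eid)
            for pos in range(len(seq) - k + 1):
                self.kmer_index.setdefault(seq[pos : pos + k], (eid, pos))

    def _mean_cov(self, seq: str) -> float:
        k = self.k
        n = len(seq) - k + 1
        return sum(self.kmer_cov[canonical_kmer(seq[i : i + k])] for i in range(n)) / n

    # ------------------------------------------------------------- navigation

    def succ_ids(self, eid: str) -> List[str]:
        return self._out.get(self.edges[eid].sequence[-(self.k - 1):], [])

    def pred_ids(self, eid: str) -> List[str]:
        return self._in.get(self.edges[eid].sequence[: self.k - 1], [])

    def canonical_id(self, eid: str) -> str:
        e = self.edges[eid]
        return min(eid, e.rc_id, key=lambda x: (len(x), x))

    def rc_walk(self, walk: Sequence[str]) -> Tuple[str, ...]:
        return tuple(self.edges[e].rc_id for e in reversed(walk))

    def canonical_edges(self) -> Iterator[UnitigEdge]:
        """Iterate each double-stranded edge once (its canonical orientation)."""
        for eid in sorted(self.edges, key=_id_sort_key):
            if self.canonical_id(eid) == eid:
                yield self.edges[eid]

    @property
    def n_edges(self) -> int:
        """Number of double-stranded edges (twin pairs counted once)."""
        return sum(1 for _ in self.canonical_edges())

    def connected_components(self) -> Dict[str, int]:
        """Weakly connected components over canonical edge ids.

        Used as a reference-free gene-locus proxy by the multi-isoform
        barcode filter.
        """
        parent: Dict[str, str] = {self.canonical_id(e.id): self.canonical_id(e.id)
                                  for e in self.canonical_edges()}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: str, b: str) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

        for e in self.canonical_edges():
            for oid in {e.id, e.rc_id}:
                for s in self.succ_ids(oid):
                    union(self.canonical_id(oid), self.canonical_id(s))
        roots = sorted({find(x) for x in parent})
        root_idx = {r: i for i, r in enumerate(roots)}
        return {x: root_idx[find(x)] for x in parent}

    # ------------------------------------------------------------------ spell

    def spell_path(self, edge_walk: Sequence[str], start_offset: int, end_offset: int) -> str:
        """Spell the DNA sequence of an edge walk, collapsing (k-1) overlaps.

        Offsets are 0-based half-open: ``start_offset`` on the first edge,
        ``end_offset`` (exclusive) on the last.
        """
        if not edge_walk:
            return ""
        k = self.k
        seqs = [self.edges[e].sequence for e in edge_walk]
        for a, b in zip(seqs, seqs[1:]):
            if a[-(k - 1):] != b[: k - 1]:
                raise WalkError("consecutive edges in walk are not adjacent")
        full = seqs[0] + "".join(s[k - 1:] for s in seqs[1:])
        if not (0 <= start_offset < len(seqs[0])):
            raise ValueError(f"start_offset {start_offset} outside first edge")
        if not (0 < end_offset <= len(seqs[-1])):
            raise ValueError(f"end_offset {end_offset} outside last edge")
        tail_trim = len(seqs[-1]) - end_offset
        return full[start_offset : len(full) - tail_trim]


def _id_sort_key(eid: str):
    rc = eid.endswith("r")
    return (int(eid[1:-1] if rc else eid[1:]), rc)


# ---------------------------------------------------------------------- build


def build_graph(reads: Iterable[str], k: int = 29) -> AssemblyGraph:
    """Build the compacted de Bruijn graph of all reads combined.

    Reads are uppercased and split at ambiguous bases; fragments shorter
    than k are skipped.  Per-edge coverage is the mean multiplicity of the
    edge's canonical k-mers.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd (got {k})")
    kmer_cov: Dict[str, float] = defaultdict(float)
    n_kmers = 0
    for read in reads:
        for frag in split_at_ambiguous(read):
            if len(frag) < k:
                continue
            rc = revcomp(frag)
            L = len(frag)
            for i in range(L - k + 1):
                fwd = frag[i : i + k]
                bwd = rc[L - k - i : L - i]
                kmer_cov[fwd if fwd <= bwd else bwd] += 1.0
                n_kmers += 1
    if n_kmers == 0:
        warnings.warn("no read fragment of length >= k; returning empty graph")
    return AssemblyGraph(k, dict(kmer_cov))


def spell_path(graph: AssemblyGraph, edge_walk: Sequence[str], start_offset: int, end_offset: int) -> str:
    return graph.spell_path(edge_walk, start_offset, end_offset)


# ------------------------------------------------------------- simplification


def _edge_kmers(graph: AssemblyGraph, eid: str) -> List[str]:
    seq = graph.edges[eid].sequence
    k = graph.k
    return [canonical_kmer(seq[i : i + k]) for i in range(len(seq) - k + 1)]


def _rebuild_without(graph: AssemblyGraph, remove_edge_ids: Iterable[str]) -> AssemblyGraph:
    cov = dict(graph.kmer_cov)
    for eid in remove_edge_ids:
        for km in _edge_kmers(graph, eid):
            cov.pop(km, None)
    return AssemblyGraph(graph.k, cov)


def _find_tips(graph: AssemblyGraph, tip_len: int) -> List[str]:
    tips = []
    for e in graph.canonical_edges():
        for oid in {e.id, e.rc_id}:
            succ = graph.succ_ids(oid)
            pred = graph.pred_ids(oid)
            if succ or not pred:
                continue  # only dead-end orientation; rc covers dead starts
            if len(e) >= tip_len:
                continue
            junction = graph.edges[oid].sequence[: graph.k - 1]
            neighbours = [x for x in graph.pred_ids(oid)] + [
                x for x in graph._out.get(junction, []) if x != oid
            ]
            neighbours = [x for x in neighbours
                          if graph.canonical_id(x) != graph.canonical_id(oid)]
            if not neighbours:
                continue
            cont_cov = max(graph.edges[x].coverage for x in neighbours)
            if e.coverage < cont_cov:
                tips.append(e.id)
                break
    return tips


def _walk_len(graph: AssemblyGraph, walk: Sequence[str]) -> int:
    return sum(graph.edges[e].kmer_count for e in walk) + graph.k - 1


def _find_bulge(graph: AssemblyGraph, bulge_similarity: float):
    """Find one two-path bulge (parallel walks of <= 2 edges) to resolve."""
    for start_j in sorted(graph._out):
        walks_by_end: Dict[str, List[Tuple[str, ...]]] = defaultdict(list)
        for e1 in graph._out[start_j]:
            walks_by_end[graph.edges[e1].sequence[-(graph.k - 1):]].append((e1,))
            for e2 in graph.succ_ids(e1):
                walks_by_end[graph.edges[e2].sequence[-(graph.k - 1):]].append((e1, e2))
        for end_j in sorted(walks_by_end):
            if end_j == start_j:
                continue
            walks = sorted(walks_by_end[end_j])
            for i in range(len(walks)):
                for j in range(i + 1, len(walks)):
                    a, b = walks[i], walks[j]
                    ca = {graph.canonical_id(x) for x in a}
                    cb = {graph.canonical_id(x) for x in b}
                    if ca & cb:
                        continue
                    la, lb = _walk_len(graph, a), _walk_len(graph, b)
                    if min(la, lb) / max(la, lb) < bulge_similarity:
                        continue
                    cov_a = min(graph.edges[x].coverage for x in a)
                    cov_b = min(graph.edges[x].coverage for x in b)
                    if cov_a < cov_b:
                        lose = a
                    elif cov_b < cov_a:
                        lose = b
                    else:
                        sa = graph.spell_path(a, 0, len(graph.edges[a[-1]]))
                        sb = graph.spell_path(b, 0, len(graph.edges[b[-1]]))
                        lose = a if sa > sb else b
                    return [graph.canonical_id(x) for x in lose]
    return None


def _find_low_coverage(g: AssemblyGraph, min_coverage: float,
                       rel_err_frac: float) -> List[str]:
    """Edges below the absolute floor or far below their local depth.

    Sequencing-error edges scale with depth (an error k-mer recurs roughly
    error_rate/3 as often as the true base), so an absolute floor alone
    cannot prune them at high coverage; an edge whose coverage is below
    ``rel_err_frac`` x the best adjacent edge is error-like as well.
    """
    low = []
    for e in g.canonical_edges():
        if e.coverage < min_coverage:
            low.append(e.id)
            continue
        neigh = []
        for oid in {e.id, e.rc_id}:
            neigh.extend(g.succ_ids(oid))
            neigh.extend(g.pred_ids(oid))
        neigh = [x for x in neigh if g.canonical_id(x) != e.id]
        if neigh and e.coverage < rel_err_frac * max(g.edges[x].coverage for x in neigh):
            low.append(e.id)
    return low


def simplify_global(
    graph: AssemblyGraph,
    min_coverage: float = 2.0,
    tip_len: int | None = None,
    bulge_similarity: float = 0.8,
    rel_err_frac: float = 0.02,
    max_rounds: int = 10,
) -> AssemblyGraph:
    """Basic global simplification: coverage pruning, tips, bulges.

    Removes (a) edges with coverage below ``min_coverage`` or below
    ``rel_err_frac`` x the coverage of their best-covered adjacent edge,
    (b) dead-end / dead-start edges shorter than ``tip_len`` (default 2k)
    whose coverage is below that of their adjacent continuation, (c) the
    lower-covered side of two-path bulges whose lengths agree within
    ``bulge_similarity``.  The three steps cycle until a fixpoint; the graph
    is re-compacted after each removal round and removal is symmetric on
    reverse-complement twins by construction.  Idempotent.
    """
    if min_coverage < 0 or bulge_similarity < 0 or rel_err_frac < 0:
        raise ValueError("thresholds must be non-negative")
    if tip_len is None:
        tip_len = 2 * graph.k
    g = graph
    for _ in range(max_rounds):
        n_before = len(g.kmer_cov)
        # (a) low coverage until fixpoint
        while True:
            low = _find_low_coverage(g, min_coverage, rel_err_frac)
            if not low:
                break
            g = _rebuild_without(g, low)
        # (b) tips until fixpoint
        while True:
            tips = _find_tips(g, tip_len)
            if not tips:
                break
            g = _rebuild_without(g, tips)
        # (c) bulges until fixpoint; similarity 0 disables the stage
        while bulge_similarity > 0:
            lose = _find_bulge(g, bulge_similarity)
            if lose is None:
                break
            g = _rebuild_without(g, lose)
        if len(g.kmer_cov) == n_before:
            break
    return g


# ------------------------------------------------------------------------ GFA


def write_gfa(graph: AssemblyGraph, path) -> None:
    """Write the graph as GFA 1.0 (one S record per canonical edge)."""
    k = graph.k
    lines = ["H\tVN:Z:1.0"]
    for e in graph.canonical_edges():
        lines.append(f"S\t{e.id}\t{e.sequence}\tdp:f:{e.coverage:.3f}")

    def as_canonical(oid: str) -> Tuple[str, str]:
        cid = graph.canonical_id(oid)
        return cid, "+" if cid == oid else "-"

    links = set()
    for e in graph.canonical_edges():
        for oid in {e.id, e.rc_id}:
            for s in graph.succ_ids(oid):
                a, oa = as_canonical(oid)
                b, ob = as_canonical(s)
                flip = {"+": "-", "-": "+"}
                dual = (b, flip[ob], a, flip[oa])
                rec = (a, oa, b, ob)
                links.add(min(rec, dual))
    for a, oa, b, ob in sorted(links):
        lines.append(f"L\t{a}\t{oa}\t{b}\t{ob}\t{k - 1}M")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
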