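"""Per-barcode alignment-induced subgraphs and their local simplification.

For one read cloud the subgraph is the set of global-graph edges touched by
at least one alignment, annotated with *barcode-specific* coverage
(aligned-base depth: cloud read bases on the edge divided by edge length —
k-mer multiplicities are too sparse at ~1x per cloud) and with the extreme
(leftmost/rightmost) alignment positions per edge.  Three procedures run in
cycles until a fixpoint:

* **tip clipping** — spurs (dead ends/starts whose attachment junction has
  an alternative cloud continuation) that are short or low-covered relative
  to their neighbour;
* **bulge removal** — of two edge-disjoint parallel walks, the one whose
  minimum barcode coverage is dominated by the other is dropped;
* **gap closing** — short uncovered edges of the parent graph are pulled in
  when they form the *unique* short connection between two cloud path ends
  (ambiguous gaps stay open: a wrong join creates a chimeric isoform, the
  costlier error).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .align import GraphAlignment
from .graph import AssemblyGraph

__all__ = [
    "EdgeCloudStats",
    "CloudSubgraph",
    "CloudParams",
    "extract_subgraph",
    "clip_cloud_tips",
    "remove_cloud_bulges",
    "close_gaps",
    "simplify_cloud",
]


@dataclass
class EdgeCloudStats:
    """Per-edge aggregate of one cloud's alignments, in canonical-edge coordinates."""

    edge_id: str
    barcode_coverage: float
    leftmost: int
    rightmost: int
    n_reads: int
    aligned_bases: int
    from_gap_fill: bool = False


@dataclass
class CloudParams:
    """Tunables of the cloud-local simplification, all exposed as config."""

    max_tip_len: Optional[int] = None  # default 2k, resolved against the graph
    rel_cov: float = 0.33
    cov_ratio: float = 0.5
    max_gap_edge_len: int = 150
    max_gap_edges: int = 3
    max_cycles: int = 10

    def tip_len(self, k: int) -> int:
        return 2 * k if self.max_tip_len is None else self.max_tip_len


class CloudSubgraph:
    """Subset of global-graph edges induced by one cloud's alignments."""

    def __init__(self, barcode: str, parent: AssemblyGraph,
                 stats: Optional[Dict[str, EdgeCloudStats]] = None):
        self.barcode = barcode
        self.parent = parent
        self.stats: Dict[str, EdgeCloudStats] = stats if stats is not None else {}

    # -- membership ---------------------------------------------------------

    @property
    def members(self):
        return self.stats.keys()

    def contains(self, eid: str) -> bool:
        return self.parent.canonical_id(eid) in self.stats

    def stat_of(self, eid: str) -> EdgeCloudStats:
        return self.stats[self.parent.canonical_id(eid)]

    def copy(self) -> "CloudSubgraph":
        return CloudSubgraph(self.barcode, self.parent,
                             {k: replace(v) for k, v in self.stats.items()})

    def __len__(self) -> int:
        return len(self.stats)

    # -- restricted adjacency ----------------------------------------------

    def succ_in(self, eid: str) -> List[str]:
        return [s for s in self.parent.succ_ids(eid) if self.contains(s)]

    def pred_in(self, eid: str) -> List[str]:
        return [p for p in self.parent.pred_ids(eid) if self.contains(p)]

    def oriented_members(self) -> List[str]:
        out = []
        for c in sorted(self.stats):
            e = self.parent.edges[c]
            out.append(c)
            if e.rc_id != c:
                out.append(e.rc_id)
        return out

    def components(self) -> Dict[str, int]:
        parent = {c: c for c in self.stats}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for oid in self.oriented_members():
            c = self.parent.canonical_id(oid)
            for s in self.succ_in(oid):
                ra, rb = find(c), find(self.parent.canonical_id(s))
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
        return {c: find(c) for c in self.stats}


# ------------------------------------------------------------------- extract


def _alignment_intervals(graph: AssemblyGraph, a: GraphAlignment):
    """Per-edge covered intervals of one alignment, in that edge's own coordinates.

    Bases in the (k-1) junction overlap are attributed to both flanking
    edges; this slightly inflates aligned-base depth but keeps extents exact.
    """
    walk = a.edge_walk
    if len(walk) == 1:
        yield walk[0], a.start_offset, a.end_offset
        return
    yield walk[0], a.start_offset, len(graph.edges[walk[0]])
    for eid in walk[1:-1]:
        yield eid, 0, len(graph.edges[eid])
    yield walk[-1], 0, a.end_offset


def extract_subgraph(graph: AssemblyGraph, alignments: Sequence[GraphAlignment],
                     barcode: str) -> CloudSubgraph:
    """Edges touched by >= 1 alignment, with per-edge cloud statistics.

    Reverse-complement twins are unified: statistics live on the canonical
    orientation, with positions mirrored as needed.
    """
    stats: Dict[str, EdgeCloudStats] = {}
    for a in alignments:
        for eid, s, t in _alignment_intervals(graph, a):
            cid = graph.canonical_id(eid)
            L = len(graph.edges[eid])
            if eid != cid:
                s, t = L - t, L - s
            st = stats.get(cid)
            if st is None:
                stats[cid] = EdgeCloudStats(cid, 0.0, s, t, 1, t - s)
            else:
                st.leftmost = min(st.leftmost, s)
                st.rightmost = max(st.rightmost, t)
                st.aligned_bases += t - s
                st.n_reads += 1
    for cid, st in stats.items():
        st.barcode_coverage = st.aligned_bases / len(graph.edges[cid])
    return CloudSubgraph(barcode, graph, stats)


# ---------------------------------------------------------------------- tips


def clip_cloud_tips(sub: CloudSubgraph, max_tip_len: Optional[int] = None,
                    rel_cov: float = 0.33) -> CloudSubgraph:
    """Remove spur edges (subgraph dead ends/starts) that are short or low-covered.

    An edge is a clip candidate only when its attachment junction offers an
    alternative cloud continuation — otherwise it is the terminal edge of a
    simple path and clipping it would eat real isoform sequence.  The sole
    edge of a connected component is never removed.
    """
    g = sub.parent
    tip_len = 2 * g.k if max_tip_len is None else max_tip_len
    out = sub.copy()
    while True:
        comp = out.components()
        sizes: Dict[str, int] = {}
        for c, r in comp.items():
            sizes[r] = sizes.get(r, 0) + 1
        removed = []
        for c in sorted(out.stats):
            if sizes[comp[c]] == 1:
                continue
            e = g.edges[c]
            for oid in {c, e.rc_id}:
                if out.succ_in(oid):
                    continue
                preds = out.pred_in(oid)
                if not preds:
                    continue
                has_alt = any(
                    any(g.canonical_id(x) != c for x in out.succ_in(p)) for p in preds
                )
                if not has_alt:
                    continue
                cov = out.stats[c].barcode_coverage
                neigh_cov = max(out.stat_of(p).barcode_coverage for p in preds)
                if len(e) < tip_len or cov < rel_cov * neigh_cov:
                    removed.append(c)
                    break
        if not removed:
            return out
        for c in removed:
            out.stats.pop(c, None)


# -------------------------------------------------------------------- bulges


def _subgraph_walks(sub: CloudSubgraph, max_edges: int = 3):
    """All oriented walks of <= max_edges member edges, grouped by junction pair."""
    g = sub.parent
    k = g.k
    walks: Dict[Tuple[str, str], List[Tuple[str, ...]]] = {}

    def record(walk: Tuple[str, ...]):
        sj = g.edges[walk[0]].sequence[: k - 1]
        tj = g.edges[walk[-1]].sequence[-(k - 1):]
        walks.setdefault((sj, tj), []).append(walk)

    def extend(walk: Tuple[str, ...]):
        record(walk)
        if len(walk) == max_edges:
            return
        seen = {g.canonical_id(x) for x in walk}
        for s in sub.succ_in(walk[-1]):
            if g.canonical_id(s) in seen:
                continue
            extend(walk + (s,))

    for oid in sub.oriented_members():
        extend((oid,))
    return walks


def remove_cloud_bulges(sub: CloudSubgraph, cov_ratio: float = 0.5) -> CloudSubgraph:
    """Collapse barcode-coverage-dominated alternative walks between junction pairs.

    Of two edge-disjoint walks sharing both endpoints, a walk whose minimum
    barcode coverage is <= cov_ratio x the other's loses its private edges;
    when the domination is mutual the walk with the lexicographically larger
    spelled sequence is removed.
    """
    g = sub.parent
    out = sub.copy()
    while True:
        walks = _subgraph_walks(out)
        victim = None
        for key in sorted(walks):
            sj, tj = key
            if sj == tj:
                continue
            group = sorted(set(walks[key]))
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    a, b = group[i], group[j]
                    ca = {g.canonical_id(x) for x in a}
                    cb = {g.canonical_id(x) for x in b}
                    if ca & cb:
                        continue
                    cov_a = min(out.stat_of(x).barcode_coverage for x in a)
                    cov_b = min(out.stat_of(x).barcode_coverage for x in b)
                    dom_a = cov_a <= cov_ratio * cov_b
                    dom_b = cov_b <= cov_ratio * cov_a
                    if dom_a and dom_b:
                        sa = g.spell_path(a, 0, len(g.edges[a[-1]]))
                        sb = g.spell_path(b, 0, len(g.edges[b[-1]]))
                        victim = ca if sa > sb else cb
                    elif dom_a:
                        victim = ca
                    elif dom_b:
                        victim = cb
                    if victim is not None:
                        break
                if victim is not None:
                    break
            if victim is not None:
                break
        if victim is None:
            return out
        for c in victim:
            out.stats.pop(c, None)


# ---------------------------------------------------------------------- gaps


def _gap_walks(g: AssemblyGraph, sub: CloudSubgraph, from_j: str, to_j: str,
               max_len: int, max_edges: int) -> List[Tuple[str, ...]]:
    """Parent-graph walks from junction from_j to to_j over non-member edges only."""
    found: List[Tuple[str, ...]] = []

    def extend(walk: Tuple[str, ...], spelled: int):
        last = walk[-1]
        if g.edges[last].sequence[-(g.k - 1):] == to_j:
            found.append(walk)
            return
        if len(walk) == max_edges:
            return
        for s in g.succ_ids(last):
            if sub.contains(s) or s in walk:
                continue
            nlen = spelled + g.edges[s].kmer_count
            if nlen + g.k - 1 <= max_len:
                extend(walk + (s,), nlen)

    for e in g._out.get(from_j, []):
        if sub.contains(e):
            continue
        if g.edges[e].kmer_count + g.k - 1 <= max_len:
            extend((e,), g.edges[e].kmer_count)
    return sorted(set(found))


def close_gaps(sub: CloudSubgraph, max_gap_edge_len: int = 150,
               max_gap_edges: int = 3, link_index=None) -> CloudSubgraph:
    """Add short uncovered parent edges that uniquely join two cloud path ends.

    For each ordered (path-end, path-start) pair the parent graph is searched
    for connecting walks of absent edges with spelled length <=
    ``max_gap_edge_len``; the edges are added only when exactly one such walk
    exists.  When ``link_index`` (cloud read linkage, see
    :class:`isocloud.paths._LinkIndex`) is given, joining two different
    connected components additionally requires at least one read pair linking
    them: a genuine coverage gap at a junction is spanned by insert-sized
    pairs, whereas two fragments separated by a whole unread exon cannot be —
    closing the latter would fabricate an exon-skipping chimera.  Added edges
    carry zero barcode coverage and full-edge extents.
    """
    g = sub.parent
    k = g.k
    ends = [o for o in sub.oriented_members() if not sub.succ_in(o)]
    starts = [o for o in sub.oriented_members() if not sub.pred_in(o)]
    comp = sub.components()
    comp_edges: Dict[int, set] = {}
    for c, r in comp.items():
        comp_edges.setdefault(r, set()).add(c)

    def linked(ce, cf) -> bool:
        if link_index is None or ce == cf:
            return True
        a_set, b_set = comp_edges[ce], comp_edges[cf]
        for a, b in link_index.pair_links:
            if (a & a_set and b & b_set) or (b & a_set and a & b_set):
                return True
        return False

    to_add: List[str] = []
    for e in ends:
        for f in starts:
            if g.canonical_id(e) == g.canonical_id(f):
                continue
            if not linked(comp[g.canonical_id(e)], comp[g.canonical_id(f)]):
                continue
            from_j = g.edges[e].sequence[-(k - 1):]
            to_j = g.edges[f].sequence[: k - 1]
            cands = _gap_walks(g, sub, from_j, to_j, max_gap_edge_len, max_gap_edges)
            if len(cands) == 1:
                to_add.extend(g.canonical_id(x) for x in cands[0])
    if not to_add:
        return sub
    out = sub.copy()
    for c in sorted(set(to_add)):
        if c in out.stats:
            continue
        out.stats[c] = EdgeCloudStats(c, 0.0, 0, len(g.edges[c]), 0, 0,
                                      from_gap_fill=True)
    return out


# ------------------------------------------------------------------- cycling


def simplify_cloud(sub: CloudSubgraph, params: Optional[CloudParams] = None,
                   link_index=None) -> CloudSubgraph:
    """Run tip clipping, bulge removal and gap closing in cycles to a fixpoint."""
    p = params or CloudParams()
    cur = sub
    for _ in range(p.max_cycles):
        before = frozenset(cur.stats)
        cur = clip_cloud_tips(cur, p.max_tip_len, p.rel_cov)
        cur = remove_cloud_bulges(cur, p.cov_ratio)
        cur = close_gaps(cur, p.max_gap_edge_len, p.max_gap_edges, link_index)
        if frozenset(cur.stats) == before:
            break
    return cur
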