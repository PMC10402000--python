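"""Alignment of cloud reads to the assembly graph.

Reads are anchored by their first exact k-mer hit and then threaded along
the graph in both directions, allowing substitutions only (short-read errors
are substitution-dominated and substitution-only threading stays linear
time).  At a branching junction the extension continues only when exactly
one branch matches the next read base; with a single continuation a
mismatch may be consumed from the budget.  Anything else truncates the
alignment at the junction — a conservative rule that avoids chimeric walks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from ._dna import revcomp
from .graph import AssemblyGraph

__all__ = ["ReadPair", "ReadCloud", "GraphAlignment", "align_read", "align_cloud"]


@dataclass(frozen=True)
class ReadPair:
    barcode: str
    read1: str
    read2: str
    pair_id: str

    def __post_init__(self):
        if not self.barcode:
            raise ValueError("barcode must be non-empty")
        if not self.read1 or not self.read2:
            raise ValueError("both mates must be non-empty")


@dataclass
class ReadCloud:
    """All read pairs sharing one barcode."""

    barcode: str
    pairs: List[ReadPair] = field(default_factory=list)

    def __post_init__(self):
        for p in self.pairs:
            if p.barcode != self.barcode:
                raise ValueError("all pairs must share the cloud's barcode")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class GraphAlignment:
    """A read threaded through the graph as an edge walk with offsets.

    ``start_offset``/``end_offset`` are 0-based half-open positions on the
    first/last edge of the walk.  ``read_start``/``read_end`` delimit the
    aligned part of the (possibly reverse-complemented) read; orientation
    '-' means the walk describes the reverse complement of the input read.
    """

    read_id: str
    edge_walk: Tuple[str, ...]
    start_offset: int
    end_offset: int
    mismatches: int
    orientation: str
    read_start: int
    read_end: int
    read_len: int
    barcode: Optional[str] = None
    pair_id: Optional[str] = None

    @property
    def aligned_length(self) -> int:
        return self.read_end - self.read_start


def _thread(graph: AssemblyGraph, eid: str, pos: int, query: str, budget: int):
    """Thread ``query`` rightward starting at position ``pos`` of edge ``eid``.

    Returns (walk_extension, n_consumed, mismatches, end_pos_on_last_edge).
    """
    k = graph.k
    walk: List[str] = []
    seq = graph.edges[eid].sequence
    j = mism = 0
    p = pos
    while j < len(query):
        if p == len(seq):
            succs = graph.succ_ids(eid)
            base = query[j]
            matching = [s for s in succs if graph.edges[s].sequence[k - 1] == base]
            if len(matching) == 1:
                nxt = matching[0]
            elif len(succs) == 1 and mism < budget:
                nxt = succs[0]
            else:
                break
            eid = nxt
            seq = graph.edges[eid].sequence
            p = k - 1
            walk.append(eid)
            continue
        if seq[p] != query[j]:
            if mism + 1 > budget:
                break
            mism += 1
        j += 1
        p += 1
    if walk and p == k - 1:
        # entered an edge but consumed none of its novel bases: retract
        walk.pop()
        last_seq = graph.edges[walk[-1]].sequence if walk else None
        p = len(last_seq) if walk else -1  # -1: caller keeps original edge end
    return walk, j, mism, p


def _align_oriented(graph: AssemblyGraph, read: str, max_mismatch_rate: float):
    k = graph.k
    if len(read) < k:
        return None
    anchor = None
    for i in range(len(read) - k + 1):
        hit = graph.kmer_index.get(read[i : i + k])
        if hit is not None:
            anchor = (i, hit)
            break
    if anchor is None:
        return None
    i, (eid, pos) = anchor
    budget = math.ceil(max_mismatch_rate * len(read))
    edge_len = len(graph.edges[eid])

    walk_r, n_r, mism_r, p_end = _thread(graph, eid, pos + k, read[i + k:], budget)
    if not walk_r:
        p_end = pos + k + n_r

    rc_eid = graph.edges[eid].rc_id
    walk_l_rc, n_l, mism_l, p_l = _thread(
        graph, rc_eid, edge_len - pos, revcomp(read[:i]), budget - mism_r
    )
    if not walk_l_rc:
        start_offset = pos - n_l
        first_part: List[str] = []
    else:
        first_edge_rc = walk_l_rc[-1]
        start_offset = len(graph.edges[first_edge_rc]) - p_l
        first_part = [graph.edges[x].rc_id for x in reversed(walk_l_rc)]

    walk = tuple(first_part + [eid] + walk_r)
    return {
        "edge_walk": walk,
        "start_offset": start_offset,
        "end_offset": p_end,
        "mismatches": mism_r + mism_l,
        "read_start": i - n_l,
        "read_end": i + k + n_r,
    }


def align_read(
    graph: AssemblyGraph,
    read: str,
    max_mismatch_rate: float = 0.03,
    read_id: str = "read",
    barcode: Optional[str] = None,
    pair_id: Optional[str] = None,
) -> Optional[GraphAlignment]:
    """Align one read to the graph; returns None when no k-mer anchors.

    Both orientations are attempted; the longer alignment wins, ties broken
    by fewer mismatches, then '+' orientation, then the lexicographically
    smallest edge-id walk (determinism contract).
    """
    read = read.upper()
    cands = []
    for orient, seq in (("+", read), ("-", revcomp(read))):
        res = _align_oriented(graph, seq, max_mismatch_rate)
        if res is not None:
            cands.append((res["read_end"] - res["read_start"], -res["mismatches"],
                          orient == "+", tuple(reversed(res["edge_walk"]))[::-1], orient, res))
    if not cands:
        return None
    cands.sort(key=lambda t: (-t[0], t[1] * -1, not t[2], t[3]))
    _, _, _, _, orient, res = cands[0]
    return GraphAlignment(
        read_id=read_id,
        edge_walk=res["edge_walk"],
        start_offset=res["start_offset"],
        end_offset=res["end_offset"],
        mismatches=res["mismatches"],
        orientation=orient,
        read_start=res["read_start"],
        read_end=res["read_end"],
        read_len=len(read),
        barcode=barcode,
        pair_id=pair_id,
    )


def align_cloud(
    graph: AssemblyGraph,
    cloud: ReadCloud,
    max_mismatch_rate: float = 0.03,
) -> List[GraphAlignment]:
    """Align every mate of a cloud independently; pair linkage kept via pair_id."""
    out: List[GraphAlignment] = []
    for pair in cloud.pairs:
        for mate_no, seq in ((1, pair.read1), (2, pair.read2)):
            if len(seq) < graph.k:
                continue
            a = align_read(
                graph,
                seq,
                max_mismatch_rate,
                read_id=f"{pair.pair_id}/{mate_no}",
                barcode=cloud.barcode,
                pair_id=pair.pair_id,
            )
            if a is not None:
                out.append(a)
    return out
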