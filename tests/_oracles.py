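"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own graph machinery: the de Bruijn
oracle works node-centrically on a networkx digraph of (k-1)-mers and
contracts simple paths; the walk oracle enumerates subgraph walks
exhaustively.
"""

from collections import Counter

import networkx as nx

_RC = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(_RC)[::-1]


def naive_debruijn(reads, k):
    """Naive double-stranded de Bruijn graph.

    Returns (unitig sequence multiset canonicalised up to rc,
    junction degree multiset) from a hash-map construction plus naive
    path contraction on a networkx MultiDiGraph.
    """
    kmers = Counter()
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            km = read[i : i + k]
            if set(km) - set("ACGT"):
                continue
            kmers[min(km, rc(km))] += 1

    g = nx.MultiDiGraph()
    oriented = set()
    for c in kmers:
        oriented.add(c)
        oriented.add(rc(c))
    for km in oriented:
        g.add_edge(km[:-1], km[1:], kmer=km)

    def simple(n):
        # palindromic nodes always count as junctions (they would merge a
        # unitig with its own reverse complement)
        return g.in_degree(n) == 1 and g.out_degree(n) == 1 and n != rc(n)

    unitigs = []
    visited = set()
    # edges whose source node is a junction (or start) begin a unitig
    for u, v, key, data in list(g.edges(keys=True, data=True)):
        if simple(u):
            continue
        seq = data["kmer"]
        visited.add(data["kmer"])
        node = v
        while simple(node):
            (_, nxt, d2), = g.out_edges(node, data=True)
            if d2["kmer"] in visited or d2["kmer"] == data["kmer"]:
                break
            seq += d2["kmer"][-1]
            visited.add(d2["kmer"])
            node = nxt
        unitigs.append(seq)
    # perfect cycles: everything not yet visited
    remaining = sorted(km for km in oriented if km not in visited)
    for km in remaining:
        if km in visited:
            continue
        seq = km
        visited.add(km)
        node = km[1:]
        while True:
            outs = [d["kmer"] for _, _, d in g.out_edges(node, data=True)
                    if d["kmer"] not in visited]
            if not outs:
                break
            nxt = sorted(outs)[0]
            seq += nxt[-1]
            visited.add(nxt)
            node = nxt[1:]
        unitigs.append(seq)

    seq_multiset = sorted(Counter(min(s, rc(s)) for s in unitigs).items())
    junctions = sorted(
        (n, g.in_degree(n), g.out_degree(n))
        for n in g.nodes
        if not simple(n)
    )
    return seq_multiset, junctions


def graph_signature(graph):
    """The same (sequence multiset, junction degrees) signature for an AssemblyGraph."""
    seqs = Counter()
    for e in graph.canonical_edges():
        seqs[min(e.sequence, rc(e.sequence))] += 1
        if e.rc_id != e.id:
            seqs[min(e.sequence, rc(e.sequence))] += 1
    k = graph.k
    nodes = {}
    for eid, e in graph.edges.items():
        pre, suf = e.sequence[: k - 1], e.sequence[-(k - 1):]
        nodes.setdefault(pre, [0, 0])
        nodes.setdefault(suf, [0, 0])
        nodes[pre][1] += 1
        nodes[suf][0] += 1
    junctions = sorted(
        (n, i, o) for n, (i, o) in nodes.items()
        if not (i == 1 and o == 1) or n == rc(n)
    )
    return sorted(seqs.items()), junctions


def enumerate_consistent_walks(sub, links, max_len=None):
    """All maximal subgraph walks consistent with every pair link.

    A walk is consistent when, for each link (a, b), it contains an edge of
    a and an edge of b.  Walks never repeat an edge.  Returns the set of
    maximal consistent walks as tuples of oriented edge ids.
    """
    g = sub.parent
    max_len = max_len or 2 * len(sub.stats) + 2
    sources = [o for o in sub.oriented_members() if not sub.pred_in(o)]
    if not sources:
        sources = sub.oriented_members()
    complete = []

    def extend(walk, used):
        succ = [s for s in sub.succ_in(walk[-1]) if g.canonical_id(s) not in used]
        if not succ or len(walk) >= max_len:
            complete.append(tuple(walk))
            return
        for s in succ:
            extend(walk + [s], used | {g.canonical_id(s)})

    for src in sources:
        extend([src], {g.canonical_id(src)})

    def consistent(walk):
        canon = {g.canonical_id(e) for e in walk}
        return all(canon & a and canon & b for a, b in links)

    ok = [w for w in complete if consistent(w)]
    # deduplicate reverse complements
    seen = set()
    out = []
    for w in ok:
        key = min(w, g.rc_walk(w))
        if key not in seen:
            seen.add(key)
            out.append(w)
    return out
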