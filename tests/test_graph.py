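"""Unit and property tests for de Bruijn graph construction and simplification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import isocloud as ic
from isocloud.graph import WalkError, write_gfa

from _oracles import graph_signature, naive_debruijn

dna = st.text(alphabet="ACGT", min_size=12, max_size=60)


class TestBuildGraph:
    def test_single_read_compacts_to_one_unitig(self):
        g = ic.build_graph(["AACCGAGTTT"], 5)
        edges = list(g.canonical_edges())
        assert len(edges) == 1
        e = edges[0]
        assert e.sequence in ("AACCGAGTTT", ic.revcomp("AACCGAGTTT"))
        assert e.coverage == pytest.approx(1.0)
        assert g.edges[e.rc_id].sequence == ic.revcomp(e.sequence)

    def test_empty_input_gives_empty_graph(self):
        with pytest.warns(UserWarning):
            g = ic.build_graph([], 5)
        assert g.n_edges == 0

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            ic.build_graph(["ACGTACGTACGT"], 6)

    def test_reads_with_n_are_split(self):
        g = ic.build_graph(["AACCGAGNAACCGAG"], 5)
        # each N-free fragment contributes its k-mers; N never enters the graph
        for e in g.edges.values():
            assert set(e.sequence) <= set("ACGT")

    def test_bubble_matches_naive_oracle(self, bubble_graph):
        graph, k, transcripts = bubble_graph
        assert graph_signature(graph) == naive_debruijn(transcripts, k)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(dna, min_size=0, max_size=12), st.sampled_from([5, 7, 11]))
    def test_matches_naive_oracle(self, reads, k):
        reads = [r for r in reads if len(r) >= k]
        if not reads:
            return
        g = ic.build_graph(reads, k)
        assert graph_signature(g) == naive_debruijn(reads, k)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(dna, min_size=1, max_size=8), st.sampled_from([5, 9]))
    def test_canonical_invariance_under_revcomp(self, reads, k):
        reads = [r for r in reads if len(r) >= k]
        if not reads:
            return
        g1 = ic.build_graph(reads, k)
        g2 = ic.build_graph([ic.revcomp(r) for r in reads], k)
        s1 = sorted(min(e.sequence, ic.revcomp(e.sequence)) for e in g1.canonical_edges())
        s2 = sorted(min(e.sequence, ic.revcomp(e.sequence)) for e in g2.canonical_edges())
        assert s1 == s2

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(dna, min_size=1, max_size=8))
    def test_coverage_conservation(self, reads):
        k = 7
        reads = [r for r in reads if len(r) >= k]
        if not reads:
            return
        g = ic.build_graph(reads, k)
        total = sum(e.coverage * e.kmer_count for e in g.canonical_edges())
        expected = sum(len(r) - k + 1 for r in reads)
        assert total == pytest.approx(expected)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(dna, min_size=1, max_size=8))
    def test_skew_symmetry_and_maximality(self, reads):
        k = 7
        reads = [r for r in reads if len(r) >= k]
        if not reads:
            return
        g = ic.build_graph(reads, k)
        for e in g.edges.values():
            twin = g.edges[e.rc_id]
            assert twin.rc_id == e.id
            assert twin.sequence == ic.revcomp(e.sequence)
            assert twin.coverage == pytest.approx(e.coverage)
        # maximality: no junction with exactly one in and one out edge
        for node in set(g._out) | set(g._in):
            ins, outs = g._in.get(node, []), g._out.get(node, [])
            if len(ins) == 1 and len(outs) == 1:
                # permissible only when joining them was blocked by a cycle
                assert ins[0] == outs[0] or g.edges[ins[0]].rc_id == outs[0] \
                    or g.edges[ins[0]].sequence[: k - 1] == node


class TestSimplifyGlobal:
    def test_below_min_coverage_removed(self):
        g = ic.build_graph(["AACCGAGTTTAGATA"], 5)
        s = ic.simplify_global(g, min_coverage=2.0)
        assert s.n_edges == 0

    def test_identity_configuration_is_noop(self, bubble_graph):
        graph, k, _ = bubble_graph
        s = ic.simplify_global(graph, min_coverage=0, tip_len=0,
                               bulge_similarity=0, rel_err_frac=0)
        assert graph_signature(s) == graph_signature(graph)

    def test_true_kmers_survive_on_noisy_two_isoform_gene(self):
        gene = ic.simulate_gene(n_exons=4, n_isoforms=2, seed=3, gene_id="g")
        cfg = ic.CloudSimConfig(n_clouds=20, seed=4, error_rate=0.005,
                                fixed_coverage=3.0, barcode_collision_rate=0.0)
        clouds, _ = ic.simulate_clouds([gene], cfg)
        reads = [s for c in clouds for p in c.pairs for s in (p.read1, p.read2)]
        k = 29
        raw = ic.build_graph(reads, k)
        g = ic.simplify_global(raw)
        surviving = set(g.kmer_cov)
        truth_kmers = set()
        for iso_id in gene.isoform_ids:
            t = gene.transcript(iso_id)
            truth_kmers |= {ic.canonical_kmer(t[i : i + k])
                            for i in range(len(t) - k + 1)}
        sequenced = truth_kmers & set(raw.kmer_cov)
        # near-complete sampling (transcript termini are insert-model limited)
        assert len(sequenced) >= 0.99 * len(truth_kmers)
        # simplification never removes a sequenced true k-mer
        assert sequenced <= surviving

    def test_idempotent(self, bubble_graph):
        graph, _, _ = bubble_graph
        s1 = ic.simplify_global(graph)
        s2 = ic.simplify_global(s1)
        assert graph_signature(s1) == graph_signature(s2)


class TestSpellPath:
    def test_single_edge_full_offsets(self, bubble_graph):
        graph, _, _ = bubble_graph
        e = next(graph.canonical_edges())
        assert graph.spell_path([e.id], 0, len(e)) == e.sequence

    def test_adjacent_pair_collapses_overlap(self, bubble_graph):
        graph, k, _ = bubble_graph
        for e in graph.canonical_edges():
            succ = graph.succ_ids(e.id)
            if succ:
                s = graph.edges[succ[0]]
                spelled = graph.spell_path([e.id, s.id], 0, len(s))
                assert spelled == e.sequence + s.sequence[k - 1:]
                assert len(spelled) == e.kmer_count + s.kmer_count + k - 1
                return
        pytest.fail("bubble graph has no junction")

    def test_non_adjacent_edges_raise(self, bubble_graph):
        graph, _, _ = bubble_graph
        ids = [e.id for e in graph.canonical_edges()]
        non_adj = None
        for a in ids:
            for b in ids:
                if b not in graph.succ_ids(a):
                    non_adj = (a, b)
                    break
            if non_adj:
                break
        with pytest.raises(WalkError):
            graph.spell_path(list(non_adj), 0, 1)

    def test_walk_spells_simulated_transcript_substring(self):
        gene = ic.simulate_gene(n_exons=5, n_isoforms=4, seed=9, gene_id="g")
        transcripts = [gene.transcript(i) for i in gene.isoform_ids]
        g = ic.build_graph(transcripts, 21)
        a = ic.align_read(g, transcripts[0], 0.0)
        spelled = g.spell_path(a.edge_walk, a.start_offset, a.end_offset)
        assert spelled == transcripts[0]


class TestGfa:
    def test_roundtrip_structure(self, tmp_path, bubble_graph):
        graph, k, _ = bubble_graph
        path = tmp_path / "g.gfa"
        write_gfa(graph, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("H\t")
        s_lines = [l.split("\t") for l in lines if l.startswith("S\t")]
        l_lines = [l.split("\t") for l in lines if l.startswith("L\t")]
        assert len(s_lines) == graph.n_edges
        seqs = {f[1]: f[2] for f in s_lines}
        for f in s_lines:
            assert f[3].startswith("dp:f:")
        for f in l_lines:
            assert f[5] == f"{k - 1}M"
            a = seqs[f[1]] if f[2] == "+" else ic.revcomp(seqs[f[1]])
            b = seqs[f[3]] if f[4] == "+" else ic.revcomp(seqs[f[3]])
            assert a[-(k - 1):] == b[: k - 1]
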