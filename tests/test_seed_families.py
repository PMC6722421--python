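"""Seed selection, all-vs-all protein scoring, normalization and MCL."""

import math

import networkx as nx
import numpy as np
import pytest

from coretax.genome_io import Gene, Genome
from coretax.seed_families import (mcl_cluster, normalize_and_filter_scores,
                                   score_gene_pairs, select_seed_genomes)

ALPH = list("ACDEFGHIKLMNPQRSTVWY")


def _genomes(n):
    return [Genome(f"G{i:02d}", [Gene(f"G{i:02d}|g", f"G{i:02d}", "ATGTAA", "M")])
            for i in range(n)]


class TestSelectSeedGenomes:
    def test_sample_size(self):
        assert len(select_seed_genomes(_genomes(50), 30, 7)) == 30

    def test_exhaustion_returns_all(self):
        assert select_seed_genomes(_genomes(5), 10, 7) == \
            [f"G{i:02d}" for i in range(5)]

    def test_deterministic_for_fixed_seed(self):
        a = select_seed_genomes(_genomes(40), 10, 123)
        b = select_seed_genomes(_genomes(40), 10, 123)
        assert a == b

    def test_nonpositive_n_errors(self):
        with pytest.raises(ValueError):
            select_seed_genomes(_genomes(3), 0, 1)


def _gene(gid, genome, aa):
    return Gene(gid, genome, "ATG" + "GCT" * len(aa), aa)


class TestScoreGenePairs:
    def test_identical_sequences_edge_with_max_self_score(self):
        rng = np.random.default_rng(3)
        aa = "".join(rng.choice(ALPH, size=100))
        genes = [_gene("A|1", "A", aa), _gene("B|1", "B", aa)]
        g = score_gene_pairs(genes, kmer_prefilter=False)
        assert g.has_edge("A|1", "B|1")
        # identity maximizes the local score: mutated copy scores lower
        mut = aa[:50] + "".join(rng.choice(ALPH, size=50))
        g2 = score_gene_pairs([_gene("A|1", "A", aa), _gene("B|1", "B", mut)],
                              kmer_prefilter=False)
        if g2.has_edge("A|1", "B|1"):
            assert g2["A|1"]["B|1"]["raw_score"] < g["A|1"]["B|1"]["raw_score"]

    def test_random_pairs_rarely_pass_the_bit_floor(self):
        rng = np.random.default_rng(4)
        edges = 0
        for _ in range(100):
            a = _gene("A|1", "A", "".join(rng.choice(ALPH, size=50)))
            b = _gene("B|1", "B", "".join(rng.choice(ALPH, size=50)))
            edges += score_gene_pairs([a, b], kmer_prefilter=False).number_of_edges()
        assert edges < 5

    def test_graph_is_undirected_symmetric(self):
        rng = np.random.default_rng(5)
        aa = "".join(rng.choice(ALPH, size=80))
        g = score_gene_pairs([_gene("A|1", "A", aa), _gene("B|1", "B", aa)],
                             kmer_prefilter=False)
        assert g["A|1"]["B|1"] == g["B|1"]["A|1"]


class TestNormalizeAndFilter:
    def _graph(self, edges, lengths):
        g = nx.Graph()
        for node, (genome, length) in lengths.items():
            g.add_node(node, genome_id=genome, length=length)
        for u, v, s in edges:
            g.add_edge(u, v, raw_score=s)
        return g

    def test_identical_scores_and_lengths_normalize_equally(self):
        lengths = {f"{g}|1": (g, 100) for g in "ABCD"}
        edges = [(a, b, 50.0) for a in lengths for b in lengths if a < b]
        out = normalize_and_filter_scores(self._graph(edges, lengths))
        norms = {d["norm_score"] for _, _, d in out.edges(data=True)}
        assert len(norms) == 1

    def test_stray_edge_below_rbh_cutoff_dropped(self):
        # gene A|1 has reciprocal best hits in B, C, D and one weak extra
        # edge to a second gene of B; cutoff = weakest RBH norm
        lengths = {"A|1": ("A", 100), "B|1": ("B", 100), "C|1": ("C", 100),
                   "D|1": ("D", 100), "B|2": ("B", 100)}
        edges = [("A|1", "B|1", 200.0), ("A|1", "C|1", 150.0),
                 ("A|1", "D|1", 120.0), ("A|1", "B|2", 90.0)]
        out = normalize_and_filter_scores(self._graph(edges, lengths))
        assert out.has_edge("A|1", "B|1")
        assert out.has_edge("A|1", "D|1")
        assert not out.has_edge("A|1", "B|2")

    def test_equal_length_ranking_preserved(self):
        lengths = {"A|1": ("A", 100), "A|2": ("A", 100), "A|3": ("A", 100),
                   "B|1": ("B", 100), "B|2": ("B", 100)}
        edges = [("A|1", "B|1", 100.0), ("A|2", "B|1", 80.0),
                 ("A|3", "B|2", 60.0), ("A|1", "B|2", 40.0), ("A|2", "B|2", 20.0)]
        out = normalize_and_filter_scores(self._graph(edges, lengths))
        kept = {(u, v): d["norm_score"] for u, v, d in out.edges(data=True)}
        raw = {tuple(sorted((u, v))): s for u, v, s in edges}
        common = [tuple(sorted(k)) for k in kept]
        ranked_norm = sorted(common, key=lambda k: kept.get(k, kept.get(k[::-1])))
        ranked_raw = sorted(common, key=lambda k: raw[k])
        assert ranked_norm == ranked_raw


def _clique_graph(cliques, weight=1.0, bridges=()):
    g = nx.Graph()
    for members in cliques:
        for m in members:
            g.add_node(m, genome_id=m.split("|")[0])
        for a in members:
            for b in members:
                if a < b:
                    g.add_edge(a, b, raw_score=weight)
    for u, v, w in bridges:
        g.add_edge(u, v, raw_score=w)
    return g


class TestMclCluster:
    def test_disconnected_cliques_stay_separate(self):
        g = _clique_graph([[f"A|{i}" for i in range(4)],
                           [f"B|{i}" for i in range(4)]])
        fams = mcl_cluster(g, inflation=1.5)
        assert sorted(sorted(f.gene_ids()) for f in fams) == [
            sorted(f"A|{i}" for i in range(4)),
            sorted(f"B|{i}" for i in range(4))]

    def test_single_node_is_singleton_family(self):
        g = nx.Graph()
        g.add_node("A|1", genome_id="A")
        fams = mcl_cluster(g, inflation=1.5)
        assert len(fams) == 1 and fams[0].gene_ids() == ["A|1"]

    def test_weak_bridge_is_cut(self):
        g = _clique_graph(
            [[f"A|{i}" for i in range(4)], [f"B|{i}" for i in range(4)]],
            weight=1.0, bridges=[("A|0", "B|0", 0.01)])
        fams = mcl_cluster(g, inflation=1.5)
        assert len(fams) == 2

    def test_empty_edge_set_gives_all_singletons(self):
        g = nx.Graph()
        for i in range(6):
            g.add_node(f"A|{i}", genome_id="A")
        fams = mcl_cluster(g, inflation=1.5)
        assert len(fams) == 6

    def test_families_partition_the_gene_set(self):
        rng = np.random.default_rng(6)
        g = nx.Graph()
        nodes = [f"G{i % 5}|{i}" for i in range(30)]
        for n in nodes:
            g.add_node(n, genome_id=n.split("|")[0])
        for _ in range(60):
            u, v = rng.choice(nodes, size=2, replace=False)
            g.add_edge(u, v, raw_score=float(rng.uniform(0.1, 2.0)))
        fams = mcl_cluster(g, inflation=1.5)
        covered = sorted(gid for f in fams for gid in f.gene_ids())
        assert covered == sorted(nodes)

    def test_components_never_merge(self):
        g = _clique_graph([[f"A|{i}" for i in range(3)],
                           [f"B|{i}" for i in range(3)],
                           [f"C|{i}" for i in range(5)]])
        fams = mcl_cluster(g, inflation=2.0)
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for n in comp:
                comp_of[n] = ci
        for f in fams:
            assert len({comp_of[g] for g in f.gene_ids()}) == 1

    def test_inflation_monotonicity(self):
        rng = np.random.default_rng(7)
        g = nx.Graph()
        nodes = [f"G{i % 4}|{i}" for i in range(16)]
        for n in nodes:
            g.add_node(n, genome_id=n.split("|")[0])
        for _ in range(40):
            u, v = rng.choice(nodes, size=2, replace=False)
            g.add_edge(u, v, raw_score=float(rng.uniform(0.5, 1.5)))
        counts = [len(mcl_cluster(g, inflation=i)) for i in (1.2, 1.5, 2.0, 3.0)]
        assert counts == sorted(counts)

    def test_inflation_at_most_one_errors(self):
        g = nx.Graph()
        g.add_node("A|1", genome_id="A")
        with pytest.raises(ValueError):
            mcl_cluster(g, inflation=1.0)

    def test_single_copy_presence_counts_genomes_with_one_member(self):
        g = _clique_graph([["A|1", "B|1", "B|2", "C|1"]])
        fams = mcl_cluster(g, inflation=1.5)
        assert len(fams) == 1
        assert fams[0].seed_sc_presence == 2  # A and C once; B twice
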