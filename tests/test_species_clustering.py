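"""Single-linkage species clustering, diagnostics, scans and classification."""

import numpy as np
import pytest

from coretax.supermatrix import CNIMatrix
from coretax.species_clustering import (cluster_single_linkage,
                                        evaluate_exclusivity, scan_cutoffs,
                                        select_representatives)


def _cni(ids, pairs, default=0.5):
    n = len(ids)
    vals = np.full((n, n), default)
    np.fill_diagonal(vals, 1.0)
    idx = {g: i for i, g in enumerate(ids)}
    for a, b, v in pairs:
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = v
    return CNIMatrix(genome_ids=list(ids), values=vals,
                     compared_sites=np.full((n, n), 100, dtype=int))


def _dfs_components(ids, vals, cutoff):
    """Independent oracle: DFS connected components of the thresholded graph."""
    adj = {g: [] for g in ids}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j and not np.isnan(vals[i, j]) and vals[i, j] >= cutoff:
                adj[a].append(b)
                adj[b].append(a)
    seen, comps = set(), []
    for g in ids:
        if g in seen:
            continue
        stack, comp = [g], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x])
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestClusterSingleLinkage:
    def test_chaining_semantics(self):
        cni = _cni(["A", "B", "C"], [("A", "B", 0.95), ("B", "C", 0.95),
                                     ("A", "C", 0.90)])
        clusters = cluster_single_linkage(cni, 0.94)
        assert len(clusters) == 1
        assert clusters[0].members == ["A", "B", "C"]

    def test_all_below_cutoff_all_singletons(self):
        cni = _cni(["A", "B", "C"], [], default=0.5)
        assert len(cluster_single_linkage(cni, 0.94)) == 3

    def test_matches_dfs_oracle_on_random_matrices(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            n = 20
            ids = [f"G{i:02d}" for i in range(n)]
            m = rng.uniform(0.7, 1.0, size=(n, n))
            vals = (m + m.T) / 2
            np.fill_diagonal(vals, 1.0)
            cni = CNIMatrix(ids, vals, np.full((n, n), 10, dtype=int))
            got = {frozenset(c.members)
                   for c in cluster_single_linkage(cni, 0.94)}
            assert got == _dfs_components(ids, vals, 0.94)

    def test_raising_cutoff_refines_partition(self):
        rng = np.random.default_rng(19)
        n = 25
        ids = [f"G{i:02d}" for i in range(n)]
        m = rng.uniform(0.7, 1.0, size=(n, n))
        vals = (m + m.T) / 2
        np.fill_diagonal(vals, 1.0)
        cni = CNIMatrix(ids, vals, np.full((n, n), 10, dtype=int))
        coarse = cluster_single_linkage(cni, 0.85)
        fine = cluster_single_linkage(cni, 0.95)
        coarse_of = {g: c.cluster_id for c in coarse for g in c.members}
        for c in fine:
            assert len({coarse_of[g] for g in c.members}) == 1

    def test_undefined_pairs_contribute_no_edge(self):
        vals = np.array([[1.0, np.nan], [np.nan, 1.0]])
        cni = CNIMatrix(["A", "B"], vals, np.array([[10, 0], [0, 10]]))
        assert len(cluster_single_linkage(cni, 0.5)) == 2


class TestEvaluateExclusivity:
    def _diagnose(self, ids, pairs, cutoff=0.94, default=0.5):
        cni = _cni(ids, pairs, default=default)
        clusters = cluster_single_linkage(cni, cutoff)
        return {c.cluster_id: c
                for c in evaluate_exclusivity(clusters, cni, cutoff)}, clusters

    def test_clean_pair_exclusive_and_transitive(self):
        by_id, clusters = self._diagnose(
            ["A", "B", "X"], [("A", "B", 0.95), ("A", "X", 0.90),
                              ("B", "X", 0.88)])
        pair = next(c for c in clusters if len(c.members) == 2)
        assert pair.min_within_cni == pytest.approx(0.95)
        assert pair.max_between_cni == pytest.approx(0.90)
        assert pair.exclusive and pair.transitive

    def test_chained_cluster_can_be_nonexclusive(self):
        by_id, clusters = self._diagnose(
            ["A", "B", "C", "X"],
            [("A", "B", 0.95), ("B", "C", 0.95), ("A", "C", 0.80),
             ("B", "X", 0.93)])
        trio = next(c for c in clusters if len(c.members) == 3)
        assert trio.min_within_cni == pytest.approx(0.80)
        assert trio.max_between_cni == pytest.approx(0.93)
        assert not trio.exclusive

    def test_chained_cluster_can_be_intransitive(self):
        _, clusters = self._diagnose(
            ["A", "B", "C"],
            [("A", "B", 0.95), ("B", "C", 0.95), ("A", "C", 0.936)])
        trio = clusters[0]
        assert len(trio.members) == 3
        assert trio.exclusive          # no outside competition
        assert not trio.transitive     # 0.936 < 0.94 within

    def test_singletons_are_trivially_exclusive(self):
        by_id, clusters = self._diagnose(["A", "B"], [("A", "B", 0.80)])
        for c in clusters:
            assert c.min_within_cni is None
            assert c.exclusive and c.transitive

    def test_nearest_cluster_identified(self):
        by_id, clusters = self._diagnose(
            ["A", "B", "C", "D"],
            [("A", "B", 0.96), ("C", "D", 0.97), ("B", "C", 0.85),
             ("A", "C", 0.70), ("A", "D", 0.70), ("B", "D", 0.70)])
        ab = next(c for c in clusters if "A" in c.members)
        cd = next(c for c in clusters if "C" in c.members)
        assert ab.nearest_cluster_id == cd.cluster_id
        assert ab.max_between_cni == pytest.approx(0.85)


class TestScanCutoffs:
    def test_high_cutoff_all_singletons_zero_nonexclusive(self):
        rng = np.random.default_rng(20)
        n = 8
        ids = [f"G{i}" for i in range(n)]
        m = rng.uniform(0.7, 0.99, size=(n, n))
        vals = (m + m.T) / 2
        np.fill_diagonal(vals, 1.0)
        cni = CNIMatrix(ids, vals, np.full((n, n), 10, dtype=int))
        df = scan_cutoffs(cni, np.array([0.9999]))
        assert df.iloc[0].n_clusters == n
        assert df.iloc[0].n_nonexclusive == 0

    def test_zero_cutoff_one_cluster_zero_nonexclusive(self):
        cni = _cni(["A", "B", "C"], [("A", "B", 0.6)])
        df = scan_cutoffs(cni, np.array([0.0]))
        assert df.iloc[0].n_clusters == 1
        assert df.iloc[0].n_nonexclusive == 0

    def test_nonexclusive_chain_detected_at_high_cutoff_only(self):
        cni = _cni(["A", "B", "C", "D"],
                   [("A", "B", 0.99), ("B", "C", 0.975), ("A", "C", 0.96),
                    ("C", "D", 0.965), ("A", "D", 0.80), ("B", "D", 0.80)])
        df = scan_cutoffs(cni, np.array([0.90, 0.97]))
        at = df.set_index("cutoff")
        assert at.loc[0.97, "n_nonexclusive"] >= 1
        assert at.loc[0.90, "n_nonexclusive"] == 0


class TestSelectRepresentatives:
    def test_most_complete_member_wins_and_ties_break_by_id(self):
        import pandas as pd
        cni = _cni(["A", "B", "C"], [("A", "B", 0.99), ("A", "C", 0.99),
                                     ("B", "C", 0.99)])
        clusters = cluster_single_linkage(cni, 0.94)
        m = pd.DataFrame({"S1": [1, 1, 1], "S2": [0, 1, 1], "S3": [0, 1, 1]},
                         index=["A", "B", "C"])
        (c,) = select_representatives(clusters, m)
        assert c.representative == "B"   # ties with C on 3 SCGs -> smaller id

    def test_singleton_is_its_own_representative(self):
        import pandas as pd
        cni = _cni(["A", "B"], [("A", "B", 0.5)])
        clusters = cluster_single_linkage(cni, 0.94)
        m = pd.DataFrame({"S1": [1, 1]}, index=["A", "B"])
        for c in select_representatives(clusters, m):
            assert c.representative == c.members[0]
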