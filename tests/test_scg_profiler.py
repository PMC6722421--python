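"""Candidate selection, profiles, search, cutoff training, copy matrix."""

import math

import numpy as np
import pandas as pd
import pytest

from coretax._align import align_protein_set, encode_aa, profile_local_score
from coretax.genome_io import Gene, Genome, translate_cds
from coretax.scg_profiler import (BACKGROUND, Hit, build_copy_matrix,
                                  build_profile, resolve_best_profile,
                                  select_candidate_families,
                                  select_definitive_scgs, train_score_cutoff,
                                  write_profiles, read_profiles)
from coretax.seed_families import GeneFamily

ALPH = list("ACDEFGHIKLMNPQRSTVWY")


def _family(sc_presence):
    return GeneFamily("F1", [("A|1", "A")], seed_sc_presence=sc_presence)


class TestSelectCandidateFamilies:
    @pytest.mark.parametrize("sc,k,kept", [
        (26, 25, True),   # strictly more than k -> kept
        (25, 25, False),  # equal to k -> dropped
        (0, 25, False),   # multi-copy everywhere -> zero single-copy presence
    ])
    def test_strict_threshold(self, sc, k, kept):
        out = select_candidate_families([_family(sc)], k)
        assert (len(out) == 1) == kept


class TestAlignProteinSet:
    def test_single_sequence_unchanged(self):
        assert align_protein_set(["MKVLI"]) == ["MKVLI"]

    def test_identical_pair_gapless(self):
        out = align_protein_set(["MKVLI", "MKVLI"])
        assert out == ["MKVLI", "MKVLI"]

    def test_deletion_gets_one_gap_column(self):
        out = align_protein_set(["MKV", "MV"])
        assert out[0] == "MKV"
        assert out[1] in ("M-V", "-MV")  # one gap, residue order preserved
        assert out[1].replace("-", "") == "MV"

    def test_residue_order_preserved(self):
        seqs = ["MKVADLI", "MKVLI", "MKADLI"]
        out = align_protein_set(seqs)
        assert [r.replace("-", "") for r in out] == seqs

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            align_protein_set([])


class TestBuildProfile:
    def test_length_of_gapless_identical_alignment(self):
        p = build_profile(["MKVLI", "MKVLI"], "P")
        assert p.length == 5

    def test_emission_arithmetic_matches_stated_formula(self):
        # column of four A's with background(A) = 0.08:
        # emission = (4 + 1*0.08) / (4 + 1); score = log2(emission / 0.08)
        bg = np.full(20, (1 - 0.08) / 19)
        bg[ALPH.index("A")] = 0.08
        p = build_profile(["A", "A", "A", "A"], "P", background=bg)
        expected = math.log2(((4 + 0.08) / 5) / 0.08)
        assert p.match_scores[0, ALPH.index("A")] == pytest.approx(expected)

    def test_majority_gap_column_is_not_a_match_column(self):
        aln = ["MA-KV", "MA-KV", "MAWKV", "MA-KV", "MA-KV"]
        p = build_profile(aln, "P")
        assert p.length == 4  # 80%-gap column dropped

    def test_all_gap_columns_error(self):
        with pytest.raises(ValueError):
            build_profile(["-", "-"], "P")

    def test_gap_penalties_are_negative(self, family_profile):
        assert (family_profile.gap_open < 0).all()
        assert (family_profile.gap_extend < 0).all()

    def test_profile_text_round_trip(self, family_profile, tmp_path):
        f = tmp_path / "profiles.txt"
        family_profile.cutoff = 12.5
        write_profiles([family_profile], f)
        (again,) = read_profiles(f)
        assert again.profile_id == family_profile.profile_id
        assert again.cutoff == pytest.approx(12.5)
        assert again.null_score == pytest.approx(family_profile.null_score)
        np.testing.assert_allclose(again.match_scores,
                                   family_profile.match_scores, atol=1e-4)


class TestScoreGenomeGenes:
    def test_family_member_scores_positive_on_own_profile(
            self, diverged_family, family_profile):
        _, members = diverged_family
        aa = translate_cds(members[0])
        raw = profile_local_score(encode_aa(aa), family_profile.match_scores,
                                  family_profile.gap_open,
                                  family_profile.gap_extend)
        assert raw - family_profile.null_at(len(aa)) > 0

    def test_random_sequences_rarely_hit(self, family_profile):
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(200):
            aa = "".join(rng.choice(ALPH, size=100, p=BACKGROUND))
            raw = profile_local_score(encode_aa(aa),
                                      family_profile.match_scores,
                                      family_profile.gap_open,
                                      family_profile.gap_extend)
            if raw - family_profile.null_at(100) > 0:
                hits += 1
        assert hits / 200 < 0.05

    def test_zero_gene_genome_yields_no_hits(self, family_profile):
        from coretax.scg_profiler import score_genome_genes
        assert score_genome_genes([family_profile],
                                  Genome("G1", [])) == []

    def test_best_in_genome_marked_once_per_profile(
            self, diverged_family, family_profile):
        from coretax.scg_profiler import score_genome_genes
        _, members = diverged_family
        genes = [Gene(f"G1|g{i}", "G1", m, translate_cds(m))
                 for i, m in enumerate(members[:3])]
        hits = score_genome_genes([family_profile], Genome("G1", genes))
        assert sum(h.is_best_in_genome for h in hits) == 1


class TestResolveBestProfile:
    def _hit(self, gene, profile, score):
        return Hit(gene, "G1", profile, score, False)

    def test_max_profile_kept(self):
        out = resolve_best_profile([self._hit("g", "P1", 50.0),
                                    self._hit("g", "P2", 30.0)])
        assert [(h.profile_id, h.score) for h in out] == [("P1", 50.0)]

    def test_single_hit_unchanged(self):
        out = resolve_best_profile([self._hit("g", "P2", 10.0)])
        assert len(out) == 1 and out[0].profile_id == "P2"

    def test_tie_breaks_to_smallest_profile_id(self):
        out = resolve_best_profile([self._hit("g", "P2", 40.0),
                                    self._hit("g", "P1", 40.0)])
        assert out[0].profile_id == "P1"

    def test_at_most_one_hit_per_gene(self):
        rng = np.random.default_rng(8)
        hits = [self._hit(f"g{rng.integers(5)}", f"P{rng.integers(4)}",
                          float(rng.uniform(0, 100))) for _ in range(50)]
        out = resolve_best_profile(hits)
        genes = [h.gene_id for h in out]
        assert len(genes) == len(set(genes))


def _oracle_cutoff(scores_by_genome):
    """Independent exhaustive F-measure scan (threshold keeps score >= t)."""
    labeled = []
    for genome_scores in scores_by_genome:
        top = max(genome_scores)
        seen_top = False
        for s in genome_scores:
            is_top = (s == top) and not seen_top
            seen_top = seen_top or is_top
            labeled.append((s, is_top))
    n_true = len(scores_by_genome)
    best = None
    for t in sorted({s for s, _ in labeled}):
        above = [(s, tr) for s, tr in labeled if s >= t]
        ta = sum(tr for _, tr in above)
        p = ta / len(above)
        r = ta / n_true
        f = 2 * p * r / (p + r) if p + r else 0.0
        if best is None or (f, -t) > (best[0], -best[1]):
            best = (f, t, p, r)
    return best


class TestTrainScoreCutoff:
    def _hits(self, scores_by_genome):
        hits = []
        for gi, scores in enumerate(scores_by_genome):
            for si, s in enumerate(scores):
                hits.append(Hit(f"G{gi}|g{si}", f"G{gi}", "P1", float(s), False))
        return hits

    def test_clean_separation_gives_perfect_f(self):
        res = train_score_cutoff("P1", self._hits([[100, 40, 35], [90], [80, 60]]))
        assert (res.cutoff, res.precision, res.recall, res.f_measure) == \
            (80.0, 1.0, 1.0, 1.0)

    def test_all_best_hits_threshold_at_minimum(self):
        res = train_score_cutoff("P1", self._hits([[50], [30], [70]]))
        assert res.cutoff == 30.0 and res.f_measure == 1.0

    def test_inclusive_threshold_wins_on_f(self):
        res = train_score_cutoff("P1", self._hits([[50, 49], [30]]))
        assert res.cutoff == 30.0
        assert res.f_measure == pytest.approx(0.8)

    def test_matches_exhaustive_oracle_on_random_hit_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n_genomes = int(rng.integers(1, 6))
            sets = [list(np.round(rng.uniform(0, 100,
                                              size=rng.integers(1, 5)), 1))
                    for _ in range(n_genomes)]
            res = train_score_cutoff("P1", self._hits(sets))
            f, t, p, r = _oracle_cutoff(sets)
            assert res.cutoff == t
            assert res.f_measure == pytest.approx(f)
            assert res.precision == pytest.approx(p)
            assert res.recall == pytest.approx(r)

    def test_metrics_bounded_and_threshold_locally_optimal(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            sets = [list(rng.uniform(0, 50, size=rng.integers(1, 4)))
                    for _ in range(int(rng.integers(1, 5)))]
            res = train_score_cutoff("P1", self._hits(sets))
            assert 0 <= res.precision <= 1
            assert 0 <= res.recall <= 1
            assert 0 <= res.f_measure <= 1
            # any lower distinct threshold must not beat the returned F
            f, t, _, _ = _oracle_cutoff(sets)
            assert res.f_measure == pytest.approx(f)


class TestCopyMatrixAndFinalScgs:
    def _resolved(self):
        return [Hit("G1|a", "G1", "C1", 50.0, True),
                Hit("G1|b", "G1", "C1", 30.0, False),   # passing paralog
                Hit("G2|a", "G2", "C1", 20.0, True),    # exactly at cutoff
                Hit("G2|b", "G2", "C2", 15.0, True),
                Hit("G3|a", "G3", "C2", 5.0, True)]     # below C2 cutoff

    def test_counts_with_boundary_at_cutoff(self):
        m = build_copy_matrix(self._resolved(), ["G1", "G2", "G3"],
                              {"C1": 20.0, "C2": 10.0})
        assert m.loc["G1", "C1"] == 2
        assert m.loc["G2", "C1"] == 1   # score == cutoff counts
        assert m.loc["G3", "C2"] == 0
        assert m.loc["G3", "C1"] == 0

    @pytest.mark.parametrize("frac,kept", [(0.96, True), (0.94, False),
                                           (0.95, True)])
    def test_definitive_scg_boundaries(self, frac, kept):
        n = 100
        col = [1] * int(round(frac * n)) + [0] * (n - int(round(frac * n)))
        m = pd.DataFrame({"C1": col}, index=[f"G{i}" for i in range(n)])
        out = select_definitive_scgs(m, p_final=95.0)
        assert (out == ["C1"]) == kept
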