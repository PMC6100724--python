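"""Enrichment scoring: fractions, pair scores, matrices, PWMs, statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phosprop.ngs import CountTable
from phosprop.scoring import (
    FractionTable, PairScore, ScoringError, build_pwm, compare_selections,
    delta_delta_g, fold_change, high_confidence_set, kinase_enrichment,
    naive_bias_check, network_edges, normalize_fractions, pair_scores,
    position_matrix, present_fold,
)


def make_counts(per_sample: dict[str, dict[str, int]], samplesheet=None) -> CountTable:
    t = CountTable(samplesheet=samplesheet)
    for sid, d in per_sample.items():
        for eid, c in d.items():
            t.add(sid, eid, c)
        t.reads_in[sid] = sum(d.values())
    return t


class TestNormalizeFractions:
    def test_simple_fractions(self):
        fr = normalize_fractions(make_counts({"s1": {"a": 3, "b": 1}}))
        assert fr.fraction("s1", "a") == 0.75
        assert fr.fraction("s1", "b") == 0.25

    def test_sum_to_one_and_scale_invariance(self):
        base = {"a": 7, "b": 11, "c": 2}
        f1 = normalize_fractions(make_counts({"s": base}))
        f7 = normalize_fractions(make_counts({"s": {k: 7 * v for k, v in base.items()}}))
        assert f1.frame.fraction.sum() == pytest.approx(1.0, abs=1e-12)
        for e in base:
            assert f1.fraction("s", e) == pytest.approx(f7.fraction("s", e))

    def test_zero_total_errors(self):
        t = CountTable()
        t.reads_in["empty"] = 5
        with pytest.raises(ScoringError, match="empty"):
            normalize_fractions(t)


class TestHighConfidenceSet:
    def test_cutoff_and_motif_filter(self, toy_design):
        by_class = {e.entry_id: e for e in toy_design}
        class1 = [e.entry_id for e in toy_design if e.is_wild_type
                  and e.peptide.aa_seq != "NNNNQSNRG"]
        none_id = next(e.entry_id for e in toy_design
                       if e.is_wild_type and e.peptide.aa_seq == "NNNNQSNRG")
        counts = make_counts({"s": {class1[0]: 50, none_id: 49, class1[1]: 3}})
        got = high_confidence_set(counts, "s", min_count=10, require_pdzbm=True,
                                  design=toy_design)
        assert got == {class1[0]}
        got = high_confidence_set(counts, "s", min_count=10, require_pdzbm=False)
        assert got == {class1[0], none_id}
        got = high_confidence_set(counts, "s", min_count=0, require_pdzbm=False)
        assert got == {class1[0], class1[1], none_id}


def _fraction_table(samplesheet, per_sample):
    rows = [{"sample_id": s, "entry_id": e, "fraction": f}
            for s, d in per_sample.items() for e, f in d.items()]
    totals = {s: 1000 for s in per_sample}
    return FractionTable(pd.DataFrame(rows), totals, samplesheet)


class TestPairScores:
    def test_score_extremes_and_arithmetic(self, samplesheet, toy_design):
        # single-site peptides in toy design: KRSFTESNV (-4), RPHTNETSL (-2), NNNNQSNRG (-3)
        per_sample = {}
        for sid in ("s1", "s2", "s3"):
            per_sample[sid] = {
                "KRSFTESNV:wt": 0.0, "KRSFTESNV:-4": 0.02,     # score 1
                "RPHTNETSL:wt": 0.05, "RPHTNETSL:-2": 0.0,     # score 0
                "NNNNQSNRG:wt": 0.03, "NNNNQSNRG:-3": 0.01,    # score 0.25
            }
        fr = _fraction_table(samplesheet, per_sample)
        pairs = {p.peptide_id: p for p in pair_scores(fr, toy_design, "PDZ1")}
        assert pairs["KRSFTESNV"].mean == 1.0
        assert pairs["RPHTNETSL"].mean == 0.0
        assert pairs["NNNNQSNRG"].mean == pytest.approx(0.25)

    def test_multi_site_peptides_excluded(self, samplesheet, toy_design):
        per_sample = {s: {"KKSGNTTSL:wt": 0.1, "KKSGNTTSL:-3": 0.1}
                      for s in ("s1", "s2", "s3")}
        fr = _fraction_table(samplesheet, per_sample)
        assert all(p.peptide_id != "KKSGNTTSL"
                   for p in pair_scores(fr, toy_design, "PDZ1"))

    def test_zero_replicates_contribute_nothing(self, samplesheet, toy_design):
        per_sample = {
            "s1": {"RPHTNETSL:wt": 0.02, "RPHTNETSL:-2": 0.02},
            "s2": {}, "s3": {},
        }
        fr = _fraction_table(samplesheet, per_sample)
        p = next(p for p in pair_scores(fr, toy_design, "PDZ1")
                 if p.peptide_id == "RPHTNETSL")
        assert p.n == 1 and p.scores == (0.5,)

    def test_pair_ttest_flags_consistent_difference(self, samplesheet, toy_design):
        per_sample = {s: {"RPHTNETSL:wt": 0.10 + d, "RPHTNETSL:-2": 0.01}
                      for s, d in zip(("s1", "s2", "s3"), (0.0, 0.005, -0.005))}
        fr = _fraction_table(samplesheet, per_sample)
        p = next(p for p in pair_scores(fr, toy_design, "PDZ1")
                 if p.peptide_id == "RPHTNETSL")
        oracle = sps.ttest_ind([0.10, 0.105, 0.095], [0.01] * 3).pvalue
        assert p.p_value == pytest.approx(float(oracle))
        assert p.significant


def _pair(bait, pid, site, reps, scores, f_wt, f_mim, p=0.5):
    return PairScore(bait=bait, peptide_id=pid, site=site, replicates=reps,
                     scores=scores, f_wt=f_wt, f_mim=f_mim, p_value=p,
                     significant=False)


class TestPositionMatrix:
    def test_one_sample_t_oracle(self):
        """Replicate means {0.8, 0.9, 1.0} vs 0.5: t = 6.928, p ≈ 0.0202 (df 2)."""
        pairs = [_pair("B", "pep", -3, (1, 2, 3), (0.8, 0.9, 1.0),
                       (0.01, 0.01, 0.01), (0.04, 0.09, 0.4))]
        m = position_matrix(pairs)
        row = m.iloc[0]
        # closed-form t statistic
        x = np.array([0.8, 0.9, 1.0])
        t = (x.mean() - 0.5) / (x.std(ddof=1) / math.sqrt(3))
        assert t == pytest.approx(6.928, abs=1e-3)
        assert row.p_value == pytest.approx(0.0202, abs=2e-4)
        assert row.mean_score == pytest.approx(0.9)

    def test_all_score_one_cell(self):
        pairs = [_pair("B", f"p{i}", -3, (1, 2), (1.0, 1.0),
                       (0.0, 0.0), (0.1, 0.1)) for i in range(3)]
        m = position_matrix(pairs)
        assert m.iloc[0].mean_score == 1.0
        # wt never observed -> cannot test against 0.5
        assert not m.iloc[0].testable
        assert m.iloc[0].call == "untestable"

    def test_mean_is_equal_weighted_over_pairs(self):
        pairs = [
            _pair("B", "p1", -2, (1, 2), (0.0, 0.1), (0.1, 0.1), (0.0, 0.01)),
            _pair("B", "p2", -2, (1, 2), (0.2, 0.3), (0.1, 0.1), (0.02, 0.04)),
        ]
        m = position_matrix(pairs)
        assert m.iloc[0].mean_score == pytest.approx((0.05 + 0.25) / 2)

    def test_bh_within_bait(self):
        rng = np.random.default_rng(0)
        pairs = []
        for site in (-1, -2, -3, -4):
            for i in range(4):
                scores = tuple(np.clip(rng.normal(0.5, 0.05, 3), 0, 1))
                pairs.append(_pair("B", f"p{site}{i}", site, (1, 2, 3), scores,
                                   (0.1,) * 3, (0.1,) * 3))
        m = position_matrix(pairs, fdr=0.025)
        assert m.q_value[m.testable].between(0, 1).all()
        assert (m.q_value[m.testable] >= m.p_value[m.testable] - 1e-12).all()


class TestPWM:
    def test_single_sequence_column_ic(self):
        pwm = build_pwm(["AAAAAAAAL"])
        assert pwm.probs.loc[0, "L"] == 1.0
        assert pwm.ic.loc[0] == pytest.approx(math.log2(20))

    def test_two_way_split_column(self):
        pwm = build_pwm(["AAAAAAAAL", "AAAAAAAAV"])
        assert pwm.ic.loc[0] == pytest.approx(math.log2(20) - 1)

    def test_uniform_column_zero_ic(self):
        seqs = [f"AAAAAAAA{aa}" for aa in "ACDEFGHIKLMNPQRSTVWY"]
        pwm = build_pwm(seqs)
        assert pwm.ic.loc[0] == pytest.approx(0.0, abs=1e-12)

    def test_columns_sum_to_one_and_duplication_invariance(self):
        seqs = ["RPHTNETSL", "KRSFTESNV", "KKSGNTTSL"]
        p1 = build_pwm(seqs)
        p2 = build_pwm(seqs * 2)
        assert np.allclose(p1.probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(p1.probs.values, p2.probs.values)
        assert ((p1.ic >= -1e-12) & (p1.ic <= math.log2(20) + 1e-12)).all()

    def test_empty_errors(self):
        with pytest.raises(ScoringError):
            build_pwm([])


class TestCompareSelections:
    def _tables(self, a_vals, b_vals):
        fa = FractionTable(pd.DataFrame(
            [{"sample_id": f"a{i}", "entry_id": "e", "fraction": v}
             for i, v in enumerate(a_vals)]), {}, None)
        fb = FractionTable(pd.DataFrame(
            [{"sample_id": f"b{i}", "entry_id": "e", "fraction": v}
             for i, v in enumerate(b_vals)]), {}, None)
        return fa, fb

    def test_identical_tables_fold_one(self):
        fa, fb = self._tables([0.2, 0.2], [0.2, 0.2])
        df = compare_selections(fa, fb, ["a0", "a1"], ["b0", "b1"])
        assert df.fold.iloc[0] == 1.0
        assert not df.significant.any()

    def test_threefold_shift(self):
        fa, fb = self._tables([0.30, 0.30], [0.10, 0.10])
        df = compare_selections(fa, fb, ["a0", "a1"], ["b0", "b1"])
        assert df.fold.iloc[0] == pytest.approx(3.0)

    def test_absent_entry_flagged(self):
        fa, fb = self._tables([0.3, 0.3], [0.0, 0.0])
        df = compare_selections(fa, fb, ["a0", "a1"], ["b0", "b1"])
        assert not df.fold_defined.iloc[0]
        assert math.isnan(df.fold.iloc[0])


class TestNaiveBiasCheck:
    def test_perfectly_proportional(self):
        naive = {f"e{i}": 10 * (i + 1) for i in range(10)}
        sel = {f"e{i}": 30 * (i + 1) for i in range(10)}
        out = naive_bias_check(sel, naive)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_constant_naive_errors(self):
        naive = {f"e{i}": 5 for i in range(10)}
        sel = {f"e{i}": i + 1 for i in range(10)}
        with pytest.raises(ScoringError, match="variance"):
            naive_bias_check(sel, naive)

    def test_permuted_pairing_uncorrelated(self):
        """Destroying the pairing of a structured fixture kills the correlation."""
        rng = np.random.default_rng(12)
        n = 200
        naive = {f"e{i}": int(c) for i, c in enumerate(rng.integers(1, 500, n))}
        perm = rng.permutation(n)
        sel = {f"e{i}": naive[f"e{perm[i]}"] * 3 for i in range(n)}
        out = naive_bias_check(sel, naive)
        assert abs(out["pearson_r"]) < 0.15
        assert out["pearson_p"] > 0.05

    def test_too_few_pairs(self):
        with pytest.raises(ScoringError, match=">= 3"):
            naive_bias_check({"a": 1}, {"a": 2, "b": 3})


class TestAffinity:
    def test_mcc_fold_presented_as_nine(self):
        """57 µM over 6.4 µM is an 8.9-fold loss, presented as 9×."""
        f = fold_change(57e-6, 6.4e-6)
        assert f == pytest.approx(8.90625)
        assert present_fold(f) == "9×"

    def test_reciprocal_identity(self):
        assert fold_change(3e-6, 7e-6) * fold_change(7e-6, 3e-6) == pytest.approx(1.0)
        assert fold_change(5e-6, 5e-6) == 1.0

    def test_invalid_kd(self):
        with pytest.raises(ScoringError):
            fold_change(0, 1e-6)

    def test_ddg_closed_form(self):
        assert delta_delta_g(1e-6, 1e-6) == 0.0
        assert delta_delta_g(math.e * 1e-6, 1e-6, 298.15) == pytest.approx(0.59248, abs=1e-4)
        assert delta_delta_g(57e-6, 6.4e-6, 298.15) == pytest.approx(1.2955, abs=1e-3)


def hypergeom_tail(a, b, c, d):
    """One-sided P(X >= a) for the 2x2 table's hypergeometric null."""
    n1, n2, k = a + b, c + d, a + c
    total = math.comb(n1 + n2, k)
    return sum(math.comb(n1, x) * math.comb(n2, k - x)
               for x in range(a, min(n1, k) + 1)) / total


class TestKinaseEnrichment:
    def test_fisher_matches_hypergeometric_tail(self):
        kin_map = {}
        binders, background = set(), set()
        # build sets realizing the table [[8,2],[10,40]]
        i = 0
        for (is_binder, has_kin), n in [((1, 1), 8), ((1, 0), 2), ((0, 1), 10), ((0, 0), 40)]:
            for _ in range(n):
                e = f"e{i}"; i += 1
                background.add(e)
                if is_binder:
                    binders.add(e)
                if has_kin:
                    kin_map[e] = {"RSK"}
        df = kinase_enrichment(binders, background, kin_map)
        assert df.p_value.iloc[0] == pytest.approx(hypergeom_tail(8, 2, 10, 40), rel=1e-9)

    def test_oracle_sweep_small_margins(self):
        from scipy.stats import fisher_exact

        for a, b, c, d in itertools.product(range(7), repeat=4):
            p = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert p == pytest.approx(hypergeom_tail(a, b, c, d), rel=1e-9, abs=1e-12)

    def test_binders_equal_background(self):
        kin_map = {"a": {"K1"}, "b": {"K2"}}
        bg = {"a", "b", "c"}
        df = kinase_enrichment(set(bg), set(bg), kin_map)
        assert (df.p_value == 1.0).all()
        assert (df.p_adjusted == 1.0).all()

    def test_binders_not_subset(self):
        with pytest.raises(ScoringError, match="subset"):
            kinase_enrichment({"x"}, {"a"}, {})


class TestNetworkEdges:
    def test_calls_follow_pair_significance(self, toy_design):
        pairs = [
            PairScore("B", "RPHTNETSL", -2, (1, 2, 3), (0.0, 0.0, 0.0),
                      (0.1,) * 3, (0.0,) * 3, p_value=0.001, significant=True),
            PairScore("B", "KRSFTESNV", -4, (1, 2, 3), (0.9, 1.0, 1.0),
                      (0.001,) * 3, (0.1,) * 3, p_value=0.002, significant=True),
            PairScore("B", "NNNNQSNRG", -3, (1, 2, 3), (0.5, 0.5, 0.5),
                      (0.1,) * 3, (0.1,) * 3, p_value=0.9, significant=False),
        ]
        edges = network_edges(pairs, toy_design).set_index("peptide_id")
        assert edges.loc["RPHTNETSL"].call == "disabling"
        assert edges.loc["KRSFTESNV"].call == "enabling"
        assert edges.loc["NNNNQSNRG"].call == "neutral"
        assert edges.loc["RPHTNETSL"].prey == "P2"
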