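import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctriage import (
    ScoredCase,
    fisher_exact_2x2,
    pooled_confusion,
    roc_auc,
    screening_metrics,
    yield_summary,
)
from oracles import fisher_two_sided, pairwise_auc

# The study's published 3-label x 2-truth counts:
# pathological 64/0, inconclusive 15/19, normal 0/13.
STUDY_CASES = (
    [("pathological", True)] * 64
    + [("inconclusive", True)] * 15
    + [("inconclusive", False)] * 19
    + [("normal", False)] * 13
)


class TestPooledConfusion:
    def test_study_counts_as_published(self):
        c = pooled_confusion(STUDY_CASES, mode="as_published")
        assert (c.tp, c.fp, c.tn, c.fn) == (79, 19, 13, 0)
        assert c.n_total == 111

    def test_all_normal_no_disease(self):
        c = pooled_confusion([("normal", False)] * 9)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 9, 0)

    def test_strict_mode_demotes_undetected_inconclusives(self):
        # 8 of the 15 diseased inconclusive cases carry no voxel-level
        # detection: strict pooling counts them as missed
        cases = (
            [("pathological", True, True)] * 64
            + [("inconclusive", True, True)] * 7
            + [("inconclusive", True, False)] * 8
            + [("inconclusive", False, True)] * 19
            + [("normal", False, True)] * 13
        )
        c = pooled_confusion(cases, mode="strict")
        assert (c.tp, c.fp, c.tn, c.fn) == (71, 19, 13, 8)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            pooled_confusion([("maybe", True)])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["pathological", "inconclusive", "normal"]),
                st.booleans(),
            ),
            max_size=40,
        )
    )
    def test_pooling_identity(self, case_list):
        c = pooled_confusion(case_list, mode="as_published")
        t = c.table
        assert c.tp == t[("pathological", True)] + t[("inconclusive", True)]
        assert c.fp == t[("pathological", False)] + t[("inconclusive", False)]
        assert c.tn == t[("normal", False)]
        assert c.fn == t[("normal", True)]
        assert c.n_total == len(case_list)


class TestScreeningMetrics:
    def test_study_counts_reproduce_published_metrics(self):
        m = screening_metrics(pooled_confusion(STUDY_CASES))
        # (64+15)/(64+15+0), 13/(13+0+19), (64+15)/(64+15+19), 13/(13+0)
        assert m.sensitivity == pytest.approx(79 / 79)
        assert m.specificity == pytest.approx(13 / 32)
        assert m.ppv == pytest.approx(79 / 98)
        assert m.npv == pytest.approx(13 / 13)
        pct = m.as_percent()
        assert round(pct["sensitivity"], 1) == 100.0
        assert round(pct["specificity"], 1) == 40.6
        assert round(pct["ppv"], 1) == 80.6
        assert round(pct["npv"], 1) == 100.0

    def test_definite_subgroup_all_perfect(self):
        cases = [("pathological", True)] * 64 + [("normal", False)] * 13
        m = screening_metrics(pooled_confusion(cases))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = screening_metrics(pooled_confusion([("normal", False)] * 3))
        assert m.ppv is None
        assert m.sensitivity is None
        assert m.specificity == 1.0


class TestYieldSummary:
    def test_study_cohort_yields(self):
        cases = (
            [("normal", "normal")] * 8 + [("pathological", "normal")] * 5
            + [("inconclusive", "normal")] * 19
            + [("pathological", "chronic")] * 20 + [("inconclusive", "chronic")] * 2
            + [("pathological", "subacute")] * 20 + [("inconclusive", "subacute")] * 2
            + [("pathological", "hvs")] * 19 + [("inconclusive", "hvs")] * 9
            + [("pathological", "lacunar")] * 5 + [("inconclusive", "lacunar")] * 2
        )
        ys = yield_summary(cases)
        assert ys.n_total == 111
        assert ys.n_definite == 77
        assert ys.n_inconclusive == 34
        assert ys.test_yield == pytest.approx(77 / 111)
        assert round(100 * ys.test_yield, 1) == 69.4
        assert round(100 * ys.per_class_definite_rate["normal"], 1) == 40.6
        assert round(100 * ys.per_class_definite_rate["chronic"], 1) == 90.9
        assert round(100 * ys.per_class_definite_rate["hvs"], 1) == 67.9
        assert round(100 * ys.per_class_definite_rate["lacunar"], 1) == 71.4

    def test_all_definite(self):
        ys = yield_summary([("normal", "normal"), ("pathological", "chronic")])
        assert ys.test_yield == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            yield_summary([])


def scored(norm, path):
    return [ScoredCase(f"n{i}", s, "normal") for i, s in enumerate(norm)] + [
        ScoredCase(f"p{i}", s, "pathological") for i, s in enumerate(path)
    ]


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc(scored([0.1, 0.2], [0.8, 0.9]), n_boot=100)
        assert r.auc == 1.0
        assert r.youden_j == 1.0
        assert 0.2 <= r.youden_cutoff < 0.8

    def test_all_tied_scores_give_half(self):
        r = roc_auc(scored([0.5, 0.5], [0.5, 0.5, 0.5]), n_boot=50)
        assert r.auc == pytest.approx(0.5)

    def test_matches_pairwise_enumeration(self, rng):
        for _ in range(10):
            norm = np.round(rng.random(8), 1)  # coarse grid forces ties
            path = np.round(rng.random(12), 1)
            r = roc_auc(scored(norm, path), n_boot=2)
            assert r.auc == pytest.approx(pairwise_auc(norm, path), abs=1e-12)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        norm, path = rng.random(10), rng.random(10)
        r = roc_auc(scored(norm, path), n_boot=2)
        y = [0] * 10 + [1] * 10
        assert r.auc == pytest.approx(roc_auc_score(y, np.r_[norm, path]))

    def test_invariant_under_monotone_transform(self, rng):
        norm, path = rng.random(10), rng.random(10)
        r1 = roc_auc(scored(norm, path), n_boot=2)
        r2 = roc_auc(scored(norm**3, path**3), n_boot=2)  # strictly monotone on [0,1]
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)

    def test_youden_cutoff_attains_j(self, rng):
        norm, path = rng.random(15), 0.3 + 0.7 * rng.random(15)
        r = roc_auc(scored(norm, path), n_boot=2)
        sens = np.mean(path > r.youden_cutoff)
        spec = np.mean(norm <= r.youden_cutoff)
        assert sens + spec - 1 == pytest.approx(r.youden_j)

    def test_bootstrap_ci_brackets_auc(self, rng):
        norm, path = rng.random(15), 0.4 + 0.6 * rng.random(15)
        r = roc_auc(scored(norm, path), n_boot=500, seed=9)
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1] or r.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_auc(scored([0.1], []))

    def test_deterministic_given_seed(self, rng):
        norm, path = rng.random(10), rng.random(10)
        r1 = roc_auc(scored(norm, path), n_boot=200, seed=4)
        r2 = roc_auc(scored(norm, path), n_boot=200, seed=4)
        assert r1.auc_ci == r2.auc_ci


class TestFisherExact:
    def test_extreme_table_matches_enumeration(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(0.00794, abs=5e-6)
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(
            fisher_two_sided(5, 0, 0, 5)
        )

    def test_identical_proportions_give_one(self):
        assert fisher_exact_2x2(2, 2, 2, 2) == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        assert fisher_exact_2x2(7, 3, 2, 8) == pytest.approx(fisher_exact_2x2(2, 8, 7, 3))

    def test_random_tables_match_enumeration_oracle(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(0, 12, 4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_two_sided(a, b, c, d), rel=1e-9
            )

    def test_study_definite_rate_contrast_significant(self):
        # definite vs inconclusive in pathological (64/15) vs normal (13/19)
        assert fisher_exact_2x2(64, 15, 13, 19) < 0.0001

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)
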