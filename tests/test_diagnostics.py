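import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lmecg import (
    TwoByTwo,
    binormal_auc,
    chi_square_test,
    make_two_by_two,
    metrics,
    one_way_anova,
    percent_round_half_up,
    roc_curve,
    wilson_ci,
)


def pair_counting_auc(scores, labels):
    """Brute-force Mann-Whitney AUC with ties counted one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (pos.size * neg.size)


class TestTwoByTwo:
    def test_cross_tabulation(self):
        t = make_two_by_two([True, False], [True, False])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)
        t = make_two_by_two([False] * 5, [True] * 5)
        assert t.fn == 5 and t.total == 5

    def test_rejects_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            make_two_by_two([True], [True, False])
        with pytest.raises(ValueError):
            make_two_by_two([], [])
        with pytest.raises(ValueError):
            TwoByTwo(tp=-1, fp=0, fn=0, tn=0)


class TestMetrics:
    def test_model1_operating_point(self):
        # 52/84 sensitivity and 445/468 specificity print as 62% / 95%
        m = metrics(TwoByTwo(tp=52, fn=32, fp=23, tn=445))
        assert m.sensitivity.value == pytest.approx(52 / 84)
        assert m.specificity.value == pytest.approx(445 / 468)
        assert m.sensitivity.percent == 62
        assert m.specificity.percent == 95

    def test_bifascicular_operating_point(self):
        m = metrics(TwoByTwo(tp=14, fn=70, fp=0, tn=89))
        assert m.sensitivity.percent == 17
        assert m.specificity.value == 1.0
        assert m.ppv.value == 1.0

    def test_perfect_classifier(self):
        m = metrics(TwoByTwo(tp=10, fn=0, fp=0, tn=10))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert getattr(m, name).value == 1.0

    def test_zero_denominator_reported_not_available(self):
        m = metrics(TwoByTwo(tp=0, fn=0, fp=3, tn=7))
        assert not m.sensitivity.available
        assert m.sensitivity.percent is None
        assert m.specificity.available

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_label_symmetry(self, tp, fp, fn, tn):
        t = TwoByTwo(tp, fp, fn, tn)
        if t.total == 0:
            return
        m, ms = metrics(t), metrics(t.swapped())
        assert ms.sensitivity.value == m.specificity.value
        assert ms.specificity.value == m.sensitivity.value

    def test_point_estimate_inside_interval(self):
        m = metrics(TwoByTwo(tp=52, fn=32, fp=23, tn=445))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            est = getattr(m, name)
            assert est.ci.lo <= est.value <= est.ci.hi


class TestWilson:
    def test_boundaries(self):
        assert wilson_ci(0, 10).lo == 0.0
        assert wilson_ci(10, 10).hi == 1.0
        ci = wilson_ci(52, 84)
        assert ci.lo < 52 / 84 < ci.hi

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(0, 10), (3, 17), (52, 84), (89, 89)]:
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            ci = wilson_ci(k, n)
            assert ci.lo == pytest.approx(lo, abs=1e-10)
            assert ci.hi == pytest.approx(hi, abs=1e-10)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            wilson_ci(5, 4)
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(1, 10, confidence=1.0)


class TestChiSquare:
    def test_independence_gives_p_one(self):
        r = chi_square_test([[10, 10], [10, 10]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.df == 1

    def test_mortality_contrast_matches_textbook_formula(self):
        # in-hospital mortality 37/84 LM occlusion vs 10/89 subocclusion
        table = np.array([[37, 47], [10, 79]], float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        manual = (((table - expected) ** 2) / expected).sum()
        r = chi_square_test(table)
        assert r.test_name == "pearson_chi_square"
        assert r.statistic == pytest.approx(manual)
        assert r.p_value < 0.001

    def test_sparse_2x2_falls_back_to_fisher(self):
        r = chi_square_test([[2, 8], [1, 20]])
        assert r.test_name == "fisher_exact"
        assert 0 <= r.p_value <= 1

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            chi_square_test([[1, 2]])


class TestAnova:
    def test_identical_groups(self):
        r = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_qrs_groups_significant(self, rng):
        params = [(117, 23, 84), (93, 13, 89), (96, 18, 85),
                  (98, 18, 98), (99, 17, 91), (99, 15, 105)]
        significant = 0
        n_rep = 200
        for _ in range(n_rep):
            groups = [rng.normal(m, s, n) for m, s, n in params]
            if one_way_anova(groups).p_value < 0.001:
                significant += 1
        assert significant >= 0.95 * n_rep

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestROC:
    def test_perfect_separation(self):
        res = roc_curve([3, 4, 5, 0, 1, 2], [True] * 3 + [False] * 3)
        assert res.auc == pytest.approx(1.0)
        assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0

    def test_all_ties_give_half(self):
        res = roc_curve([1.0] * 10, [True] * 5 + [False] * 5)
        assert res.auc == pytest.approx(0.5)

    def test_uninformative_scores_near_half(self, rng):
        scores = rng.normal(size=20000)
        labels = rng.random(20000) < 0.5
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_curve_monotone_and_single_class_rejected(self, rng):
        res = roc_curve(rng.normal(size=50), rng.random(50) < 0.4)
        assert np.all(np.diff(res.tpr) >= 0)
        assert np.all(np.diff(res.fpr) >= 0)
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])

    def test_youden_tie_breaks_toward_lower_threshold(self):
        # thresholds 3 and 1 both achieve J = 0.5; pick the lower (1),
        # which maximises sensitivity at equal Youden index
        res = roc_curve([3.0, 1.0, 2.0, 0.0], [True, True, False, False])
        assert res.youden_cutoff == 1.0
        assert res.sens_at_cutoff == 1.0
        assert res.spec_at_cutoff == 0.5

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 500))
    def test_trapezoid_equals_pair_counting(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, size=n).astype(float)  # many ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        assert roc_curve(scores, labels).auc == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=400)
        labels = rng.random(400) < 0.3
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestBinormal:
    def test_limits(self):
        assert binormal_auc(0, 1, 0, 1) == pytest.approx(0.5)
        assert binormal_auc(1000, 1, 0, 1) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            binormal_auc(0, 0, 0, 1)

    def test_pooled_control_contrast(self):
        # pooled non-LM QRS mean 97.1 ms / SD ~16.5 against LM 117 +- 23
        assert binormal_auc(117, 23, 97.1, 16.5) == pytest.approx(0.759, abs=2e-3)

    def test_empirical_auc_converges_to_binormal(self):
        rng = np.random.default_rng(42)
        n = 50_000
        scores = np.r_[rng.normal(117, 23, n), rng.normal(97.1, 16.5, n)]
        labels = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        assert roc_curve(scores, labels).auc == pytest.approx(
            binormal_auc(117, 23, 97.1, 16.5), abs=0.01
        )


@pytest.mark.parametrize(
    "proportion, expected",
    [(52 / 84, 62), (445 / 468, 95), (0.125, 13), (0.615, 62), (0.5049, 50)],
)
def test_percent_rounding_half_up(proportion, expected):
    assert percent_round_half_up(proportion) == expected


def test_wilson_coverage_on_grid():
    """Exact-enumeration coverage stays within 3 points of nominal."""
    for p in np.arange(0.1, 0.91, 0.1):
        for n in (10, 25, 50, 100):
            k = np.arange(n + 1)
            pmf = stats.binom.pmf(k, n, p)
            cover = sum(
                pmf[i]
                for i in k
                if wilson_ci(int(i), n).lo <= p <= wilson_ci(int(i), n).hi
            )
            assert cover >= 0.95 - 0.03, (p, n, cover)
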