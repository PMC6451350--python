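import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hoxtempo.qpcr import (
    StandardCurve,
    background_subtract,
    compare_rt,
    fit_standard_curve,
    quantify_copies,
    tukey_kramer,
)


def two_fold_series():
    # perfect doubling: one Cq per log2, i.e. slope -1/log10(2)
    copies = np.array([10.0, 100.0, 1e3, 1e4, 1e5])
    cq = 38.0 - np.log10(copies) / np.log10(2.0)
    return pd.DataFrame({"copies": copies, "cq": cq})


class TestStandardCurve:
    def test_perfect_doubling_efficiency_one(self):
        curve = fit_standard_curve(two_fold_series())
        np.testing.assert_allclose(curve.slope, -1.0 / np.log10(2.0), rtol=1e-12)
        np.testing.assert_allclose(curve.efficiency, 1.0, atol=1e-12)
        assert curve.copies_min == 10.0 and curve.copies_max == 1e5

    def test_replicated_input_gives_identical_fit(self):
        df = two_fold_series()
        a = fit_standard_curve(df)
        b = fit_standard_curve(pd.concat([df, df], ignore_index=True))
        np.testing.assert_allclose((a.slope, a.intercept), (b.slope, b.intercept), rtol=1e-12)

    def test_noisy_recovery_of_generating_slope(self):
        rng = np.random.default_rng(5)
        copies = np.array([10.0, 100.0, 1e3, 1e4, 1e5])
        cq = 37.0 - 3.4 * np.log10(copies) + rng.normal(0, 0.15, copies.size)
        curve = fit_standard_curve(pd.DataFrame({"copies": copies, "cq": cq}))
        assert abs(curve.slope - (-3.4)) < 0.1

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_standard_curve(pd.DataFrame({"copies": [10.0, 1e4], "cq": [33.0, 23.0]}))

    def test_narrow_span_rejected(self):
        with pytest.raises(ValueError, match="orders of magnitude"):
            fit_standard_curve(pd.DataFrame({"copies": [10.0, 20.0, 40.0], "cq": [33, 32, 31]}))

    def test_swapped_axes_rejected(self):
        df = two_fold_series()
        with pytest.raises(ValueError, match="slope"):
            fit_standard_curve(pd.DataFrame({"copies": df.copies, "cq": -df.cq}))

    def test_positive_slope_type_rejected(self):
        with pytest.raises(ValueError):
            StandardCurve(slope=3.3, intercept=37, r_squared=1.0, copies_min=1, copies_max=1e6)


class TestQuantify:
    @pytest.fixture()
    def curve(self):
        return StandardCurve(slope=-1 / np.log10(2.0), intercept=37.0, r_squared=1.0,
                             copies_min=1.0, copies_max=1e6)

    def test_intercept_maps_to_one_copy(self, curve):
        est = quantify_copies(37.0, curve)
        assert est.status == "ok"
        np.testing.assert_allclose(est.copies, 1.0)

    def test_below_range_marked(self, curve):
        est = quantify_copies(39.0, curve)  # fewer copies than the lowest standard
        assert est.status == "below_range" and not est.usable

    def test_above_range_marked(self, curve):
        est = quantify_copies(10.0, curve)
        assert est.status == "above_range" and not est.usable

    def test_censored_maps_to_zero(self, curve):
        est = quantify_copies(np.nan, curve, censored=True)
        assert est.status == "censored" and est.copies == 0.0 and est.usable

    def test_round_trip_identity_in_range(self, curve):
        for copies in (1.0, 42.0, 9.9e5):
            est = quantify_copies(curve.cq_of(copies), curve)
            assert est.status == "ok"
            np.testing.assert_allclose(est.copies, copies, rtol=1e-12)


class TestCompareRt:
    def test_identical_replicates_not_significant(self):
        call = compare_rt([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert not call.significant and call.test_used == "degenerate"

    def test_clear_signal_detected_with_welch(self):
        # frozen oracle: F-test p=6.67e-5 forces Welch; one-sided Welch
        # t=17.31 on ~2 df gives p=1.659e-3
        call = compare_rt([1000.0, 1100.0, 900.0], [0.0, 1.0, 0.0])
        assert call.significant and call.test_used == "welch_t"
        np.testing.assert_allclose(call.p_value, 1.6590475432e-3, rtol=1e-6)

    def test_no_effect_with_huge_variance_not_significant(self):
        call = compare_rt([0.0, 2000.0, 1000.0], [900.0, 1050.0, 1050.0])
        assert not call.significant

    def test_all_censored_rt_plus_flagged(self):
        call = compare_rt([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        assert not call.significant and "rt_plus_all_censored" in call.flags

    def test_insufficient_replicates_flagged(self):
        call = compare_rt([5.0], [0.0, 0.0])
        assert not call.significant and "insufficient_replicates" in call.flags

    def test_type_one_error_near_alpha_under_null(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(1000):
            a = rng.normal(100.0, 10.0, 3)
            b = rng.normal(100.0, 10.0, 3)
            rejections += compare_rt(a, b, alpha=0.05).significant
        # one-sided test at alpha=0.05: 3-sigma binomial envelope
        assert rejections / 1000 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 1000)


class TestBackgroundSubtract:
    def frame(self, plus, minus, statuses=None):
        rows = []
        for i, v in enumerate(plus, 1):
            rows.append({"gene_id": "g", "hpf": 9.5, "rt": "plus", "replicate": i,
                         "copies": v, "status": "ok"})
        for i, v in enumerate(minus, 1):
            rows.append({"gene_id": "g", "hpf": 9.5, "rt": "minus", "replicate": i,
                         "copies": v, "status": statuses[i - 1] if statuses else "ok"})
        return pd.DataFrame(rows)

    def test_subtracts_rt_minus_mean(self):
        out = background_subtract(self.frame([10.0, 12.0, 11.0], [1.0, 1.0, 1.0]))
        np.testing.assert_allclose(sorted(out["denovo"]), [9.0, 10.0, 11.0])
        assert not out["clamped"].any()

    def test_clamps_negatives_to_zero(self):
        out = background_subtract(self.frame([1.0, 2.0, 1.5], [10.0, 10.0, 10.0]))
        assert np.all(out["denovo"] == 0.0) and out["clamped"].all()

    def test_censored_background_is_zero(self):
        df = self.frame([10.0, 12.0, 11.0], [0.0, 0.0, 0.0],
                        statuses=["censored"] * 3)
        out = background_subtract(df)
        np.testing.assert_allclose(sorted(out["denovo"]), [10.0, 11.0, 12.0])

    def test_missing_rt_minus_is_an_error(self):
        df = self.frame([10.0], [])
        with pytest.raises(ValueError, match="g.*9.5"):
            background_subtract(df)

    def test_never_negative_property(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            out = background_subtract(
                self.frame(rng.uniform(0, 50, 3).tolist(), rng.uniform(0, 50, 3).tolist())
            )
            assert (out["denovo"] >= 0).all()


class TestTukeyKramer:
    def test_identical_groups_nothing_significant(self):
        res = tukey_kramer({1: [5.0, 5.0, 5.0], 2: [5.0, 5.0, 5.0], 3: [5.0, 5.0, 5.0]})
        assert not res.significant.any()

    def test_one_distinct_group(self):
        res = tukey_kramer(
            {"a": [0.0, 0.0, 0.0], "b": [0.0, 0.0, 0.0], "c": [100.0, 101.0, 99.0]},
        )
        assert not res.pair("a", "b")
        assert res.pair("a", "c") and res.pair("b", "c")

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 5.0, n) for m, n in ((0, 4), (3, 6), (9, 3), (9.5, 5))]
        res = tukey_kramer(groups, compute_pvalues=True)
        ref = stats.tukey_hsd(*groups)
        k = len(groups)
        for i in range(k):
            for j in range(i + 1, k):
                np.testing.assert_allclose(res.p_values[i, j], ref.pvalue[i, j],
                                           rtol=1e-6, atol=1e-9)
                assert res.significant[i, j] == (ref.pvalue[i, j] < 0.05)

    def test_k2_equals_pooled_t(self):
        # q = t*sqrt(2): the two-group Tukey decision is the pooled t decision
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 5), rng.normal(1.2, 1, 4)
        res = tukey_kramer({"a": a, "b": b}, compute_pvalues=True)
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        np.testing.assert_allclose(res.p_values[0, 1], t_p, rtol=1e-5)

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = tukey_kramer({1: [1.0, 2.0], 2: [5.0], 3: [9.0, 10.0]})
        assert res.labels == (1, 3)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            tukey_kramer({1: [1.0, 2.0]})
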