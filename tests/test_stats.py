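"""Agreement metrics, Bland-Altman, intervals, and paired comparisons,
cross-checked against independent implementations and hand arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from cardiofuse.stats import (
    AgreementReport, PairedSeries, agreement_metrics, bland_altman,
    bootstrap_ci, bootstrap_diff_test, build_report, paired_error_test,
    paired_permutation_pcc, pcc_ci_fisher, percent_ba,
)


def _random_series(seed, n=40, noise=0.4):
    rng = np.random.default_rng(seed)
    y = rng.uniform(2.0, 6.0, n)
    return PairedSeries(y, y + rng.normal(0, noise, n))


class TestAgreementMetrics:
    def test_perfect_predictions(self):
        s = PairedSeries(np.array([2.0, 3, 4, 5]), np.array([2.0, 3, 4, 5]))
        m = agreement_metrics(s)
        assert m["pcc"] == pytest.approx(1.0)
        assert m["ccc"] == pytest.approx(1.0)
        assert m["r2"] == pytest.approx(1.0)
        assert m["mae"] == m["rmse"] == 0.0
        assert m["pe"] == 0.0

    def test_mean_baseline_r2_zero(self):
        y = np.array([2.0, 3.0, 4.0, 7.0])
        s = PairedSeries(y, np.full(4, y.mean()))
        m = agreement_metrics(s)
        assert m["r2"] == pytest.approx(0.0)
        assert m["pe"] == pytest.approx(100 * np.std(y, ddof=1) / y.mean())

    def test_hand_worked_two_point_series(self):
        s = PairedSeries(np.array([2.0, 4.0]), np.array([2.2, 3.6]))
        m = agreement_metrics(s)
        ba = bland_altman(s)
        assert ba["bias"] == pytest.approx(-0.1)
        assert m["mae"] == pytest.approx(0.3)
        assert m["rmse"] == pytest.approx(np.sqrt(0.1), abs=1e-9)
        assert m["pe"] == pytest.approx(100 * 0.42426 / 3.0, abs=1e-3)

    def test_against_reference_implementations(self):
        """PCC/R2/MAE/RMSE agree with scipy/sklearn on random series."""
        for seed in range(5):
            s = _random_series(seed)
            m = agreement_metrics(s)
            assert m["pcc"] == pytest.approx(
                sps.pearsonr(s.y_ref, s.y_hat).statistic, abs=1e-12)
            assert m["r2"] == pytest.approx(
                r2_score(s.y_ref, s.y_hat), abs=1e-12)
            assert m["mae"] == pytest.approx(
                mean_absolute_error(s.y_ref, s.y_hat), abs=1e-12)
            assert m["rmse"] == pytest.approx(
                np.sqrt(mean_squared_error(s.y_ref, s.y_hat)), abs=1e-12)

    def test_ccc_brute_force(self):
        """CCC matches an explicit population-moment recomputation."""
        for seed in range(5):
            s = _random_series(seed, n=25)
            x, y = s.y_ref, s.y_hat
            num = 2 * np.mean((x - x.mean()) * (y - y.mean()))
            den = x.var() + y.var() + (x.mean() - y.mean()) ** 2
            assert agreement_metrics(s)["ccc"] == pytest.approx(num / den,
                                                                abs=1e-12)

    @settings(deadline=None, max_examples=150)
    @given(st.integers(0, 10_000))
    def test_ccc_bounded_by_abs_pcc(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(3, 1, 20)
        yh = rng.normal(3, 1, 20) + 0.5 * y
        m = agreement_metrics(PairedSeries(y, yh))
        assert m["ccc"] <= abs(m["pcc"]) + 1e-12

    def test_scale_behavior(self):
        s = _random_series(3)
        m1 = agreement_metrics(s)
        s2 = PairedSeries(2 * s.y_ref, 2 * s.y_hat)
        m2 = agreement_metrics(s2)
        assert m2["pe"] == pytest.approx(m1["pe"])            # scale-free
        assert m2["mae"] == pytest.approx(2 * m1["mae"])      # linear
        assert m2["rmse"] == pytest.approx(2 * m1["rmse"])


class TestBlandAltman:
    def test_zero_differences(self):
        y = np.array([2.0, 3.0, 4.0])
        ba = bland_altman(PairedSeries(y, y))
        assert ba["bias"] == 0.0
        assert ba["loa_lower"] == ba["loa_upper"] == 0.0

    def test_two_point_hand_value(self):
        ba = bland_altman(PairedSeries(np.array([2.0, 4.0]),
                                       np.array([2.2, 3.6])))
        assert ba["bias"] == pytest.approx(-0.1)
        assert ba["loa_lower"] == pytest.approx(-0.93, abs=0.005)
        assert ba["loa_upper"] == pytest.approx(0.73, abs=0.005)

    def test_translation_equivariance(self):
        s = _random_series(7)
        ba1 = bland_altman(s)
        ba2 = bland_altman(PairedSeries(s.y_ref, s.y_hat + 0.7))
        assert ba2["bias"] == pytest.approx(ba1["bias"] + 0.7)
        assert ba2["loa_lower"] == pytest.approx(ba1["loa_lower"] + 0.7)
        assert ba2["loa_upper"] == pytest.approx(ba1["loa_upper"] + 0.7)

    def test_percent_normalization(self):
        y = np.full(10, 4.0)
        s = PairedSeries(y, y + 0.17)
        pb = percent_ba(s)
        assert pb["percent_bias"] == pytest.approx(100 * 0.17 / 4.0)
        s0 = PairedSeries(y, y)
        assert percent_ba(s0)["percent_bias"] == 0.0
        # doubling both leaves percent bias unchanged
        s2 = PairedSeries(2 * s.y_ref, 2 * s.y_hat)
        assert percent_ba(s2)["percent_bias"] == pytest.approx(
            pb["percent_bias"])


class TestPccFisher:
    def test_null_correlation_interval(self):
        rng = np.random.default_rng(1)
        # engineer r ~ 0 at n = 103: interval ~ +-tanh(1.96/10) ~ +-0.193
        x = rng.normal(size=103)
        e = rng.normal(size=103)
        y = e - x * np.corrcoef(x, e)[0, 1] * np.std(e) / np.std(x)
        s = PairedSeries(x, y)
        lo, hi = pcc_ci_fisher(s)
        assert lo == pytest.approx(-0.193, abs=0.01)
        assert hi == pytest.approx(0.193, abs=0.01)

    def test_interval_contains_r(self):
        for seed in range(5):
            s = _random_series(seed)
            r = agreement_metrics(s)["pcc"]
            lo, hi = pcc_ci_fisher(s)
            assert lo < r < hi

    def test_strong_correlation_upper_near_one(self):
        s = _random_series(2, noise=0.05)
        lo, hi = pcc_ci_fisher(s)
        assert hi > 0.99

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pcc_ci_fisher(PairedSeries(np.array([1.0, 2, 3]),
                                       np.array([1.0, 2, 4])))


class TestBootstrap:
    def test_perfect_predictions_zero_width(self):
        y = np.linspace(2, 5, 20)
        s = PairedSeries(y, y)
        lo, hi = bootstrap_ci(s, "mae", iters=200, seed=0)
        assert lo == hi == 0.0

    def test_deterministic_per_seed(self):
        s = _random_series(4)
        a = bootstrap_ci(s, "rmse", iters=300, seed=11)
        b = bootstrap_ci(s, "rmse", iters=300, seed=11)
        assert a == b
        c = bootstrap_ci(s, "rmse", iters=300, seed=12)
        assert a != c

    def test_interval_brackets_point_estimate(self):
        for seed in range(8):
            s = _random_series(seed)
            m = agreement_metrics(s)
            for metric in ("mae", "rmse", "pe"):
                lo, hi = bootstrap_ci(s, metric, iters=400, seed=seed)
                assert lo <= m[metric] <= hi

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(_random_series(0), "auc")


class TestPairedPermutation:
    def test_identical_predictions_p_one(self):
        s = _random_series(0)
        p = paired_permutation_pcc(s, PairedSeries(s.y_ref, s.y_hat.copy()),
                                   perms=500, seed=0)
        assert p == pytest.approx(1.0)

    def test_perfect_vs_noise_significant(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(2, 6, 91)
        a = PairedSeries(y, y + rng.normal(0, 0.05, 91))
        b = PairedSeries(y, rng.normal(4, 1, 91))
        p = paired_permutation_pcc(a, b, perms=999, seed=1)
        assert p < 0.01

    def test_p_in_unit_interval(self):
        for seed in range(4):
            a = _random_series(seed)
            b = PairedSeries(a.y_ref, np.roll(a.y_hat, 1))
            p = paired_permutation_pcc(a, b, perms=200, seed=seed)
            assert 0.0 < p <= 1.0

    def test_mismatched_reference_rejected(self):
        a = _random_series(0)
        b = _random_series(1)
        with pytest.raises(ValueError):
            paired_permutation_pcc(a, b)


class TestBootstrapDiff:
    def test_identical_models_p_near_one(self):
        s = _random_series(2)
        out = bootstrap_diff_test(s, PairedSeries(s.y_ref, s.y_hat.copy()),
                                  "ccc", iters=300, seed=0)
        assert out["p_value"] == pytest.approx(1.0)
        assert out["diff"] == 0.0

    def test_separated_models_small_p(self):
        rng = np.random.default_rng(9)
        y = rng.uniform(2, 6, 80)
        good = PairedSeries(y, y + rng.normal(0, 0.1, 80))
        bad = PairedSeries(y, y.mean() + rng.normal(0, 1.2, 80))
        out = bootstrap_diff_test(good, bad, "ccc", iters=500, seed=3)
        assert out["p_value"] < 0.05
        assert out["diff"] > 0

    def test_deterministic(self):
        a = _random_series(3)
        b = PairedSeries(a.y_ref, np.roll(a.y_hat, 2))
        r1 = bootstrap_diff_test(a, b, "r2", iters=200, seed=7)
        r2 = bootstrap_diff_test(a, b, "r2", iters=200, seed=7)
        assert r1 == r2


class TestPairedErrorTest:
    def test_identical_errors_p_one(self):
        s = _random_series(0)
        out = paired_error_test(s, PairedSeries(s.y_ref, s.y_hat.copy()),
                                "mae")
        assert out["p_value"] == 1.0

    def test_constant_shift_highly_significant(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(2, 6, 50)
        a = PairedSeries(y, y + rng.normal(0, 0.1, 50))
        b = PairedSeries(y, a.y_hat + 2.5)  # errors shifted by a constant
        out = paired_error_test(a, b, "mae")
        assert out["p_value"] < 1e-4

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(2, 6, 30)
        a = PairedSeries(y, y + rng.normal(0, 0.3, 30))
        b = PairedSeries(y, y + rng.normal(0, 0.5, 30))
        p1 = paired_error_test(a, b, "rmse")["p_value"]
        perm = rng.permutation(30)
        p2 = paired_error_test(
            PairedSeries(y[perm], a.y_hat[perm]),
            PairedSeries(y[perm], b.y_hat[perm]), "rmse")["p_value"]
        assert p1 == pytest.approx(p2)

    def test_bad_metric_rejected(self):
        s = _random_series(0)
        with pytest.raises(ValueError):
            paired_error_test(s, s, "pe")


class TestReport:
    def test_full_panel_and_roundtrip(self):
        s = _random_series(6)
        rep = build_report(s, label="demo", boot_iters=200, seed=0)
        assert rep.loa_lower <= rep.bias <= rep.loa_upper
        assert rep.rmse >= rep.mae >= 0
        assert rep.pe_pass == (rep.pe < 30.0)
        again = AgreementReport.from_json(rep.to_json())
        assert again == rep
        assert "PCC" in rep.to_markdown()

    def test_constant_offset_predictions(self):
        y = np.linspace(2, 5, 30)
        rep = build_report(PairedSeries(y, y + 0.4), boot_iters=100, seed=1)
        assert rep.pcc == pytest.approx(1.0)
        assert rep.ccc < 1.0
        assert rep.bias == pytest.approx(0.4)
        # CCC closed form under a pure mean shift
        v = y.var()
        assert rep.ccc == pytest.approx(2 * v / (2 * v + 0.16), abs=1e-9)
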