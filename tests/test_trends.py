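import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import biogapfill as bg
from biogapfill.trends import DegenerateDesignError


def _normal_equations_cubic(days, values):
    """Independent oracle: solve the cubic normal equations directly."""
    A = np.vander(days, 4)  # columns x^3, x^2, x, 1
    coef = np.linalg.solve(A.T @ A, A.T @ values)
    resid = A @ coef - values
    return coef, float(np.sqrt(np.mean(resid**2)))


def _grid_oracle_log_rms(days, values):
    """Coarse brute-force grid over (a, b, c, d) for the log model."""
    best = np.inf
    a_grid = [-30, -10, -3, -1, 1, 3, 10, 30]
    b_grid = [0.1, 0.3, 1, 3, 10]
    c_grid = [0.3, 1, 3, 10]
    d_grid = [-30, -10, 0, 10, 30, 100]
    for a in a_grid:
        for b in b_grid:
            for c in c_grid:
                arg = b * days + c
                if np.any(arg <= 0):
                    continue
                la = np.log(arg)
                for d in d_grid:
                    rms = np.sqrt(np.mean((a * la + d - values) ** 2))
                    best = min(best, rms)
    return best


class TestConstantFit:
    def test_hand_example(self):
        fit = bg.fit_constant([0, 1, 2], [1, 2, 3])
        assert fit.d == 2.0
        assert fit.rms_residual == pytest.approx(np.sqrt(2 / 3))

    def test_flat_series(self):
        fit = bg.fit_constant([0, 1, 2], [5, 5, 5])
        assert fit.d == 5.0 and fit.rms_residual == 0.0

    def test_single_point(self):
        assert bg.fit_constant([3], [7]).d == 7.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bg.fit_constant([], [])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_d_equals_mean_property(self, values):
        fit = bg.fit_constant(np.arange(len(values)), values)
        assert fit.d == pytest.approx(np.mean(values), rel=1e-12, abs=1e-9)


class TestCubicFit:
    def test_exact_cubic_recovered(self):
        days = np.arange(14.0)
        fit = bg.fit_cubic(days, days**3)
        assert fit.a == pytest.approx(1.0, abs=1e-8)
        assert abs(fit.b) < 1e-7 and abs(fit.c) < 1e-7 and abs(fit.d) < 1e-7
        assert fit.rms_residual < 1e-8

    def test_constant_data(self):
        days = np.arange(14.0)
        fit = bg.fit_cubic(days, np.full(14, 3.5))
        assert fit.d == pytest.approx(3.5, abs=1e-8)
        assert max(abs(fit.a), abs(fit.b), abs(fit.c)) < 1e-9

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            days = np.arange(14.0)
            values = rng.normal(size=14) * 10
            fit = bg.fit_cubic(days, values)
            coef, rms = _normal_equations_cubic(days, values)
            np.testing.assert_allclose(fit.coefficients, coef, rtol=1e-6, atol=1e-9)
            assert fit.rms_residual == pytest.approx(rms, rel=1e-6)

    def test_too_few_distinct_days_rejected(self):
        with pytest.raises(DegenerateDesignError):
            bg.fit_cubic([0, 0, 1, 2, 1], [1, 2, 3, 4, 5])

    def test_nesting_never_beats_constant(self, rng):
        days = np.arange(14.0)
        for _ in range(20):
            values = rng.normal(size=14)
            assert (
                bg.fit_cubic(days, values).rms_residual
                <= bg.fit_constant(days, values).rms_residual + 1e-9
            )


class TestLogarithmicFit:
    def test_noiseless_curve_recovery(self):
        days = np.arange(14.0)
        y = np.log(days + 1)
        fit = bg.fit_logarithmic(days, y)
        np.testing.assert_allclose(fit.predict(days), y, atol=1e-6)

    def test_reparameterisation_invariance_of_curve(self):
        # (b, c) -> (lam*b, lam*c) with d -> d - a ln(lam) is the same curve
        days = np.arange(14.0)
        y = 2.0 * np.log(3 * days + 2) + 1.0
        fit = bg.fit_logarithmic(days, y)
        np.testing.assert_allclose(fit.predict(days), y, atol=1e-6)

    def test_constant_data_near_zero_rms(self):
        days = np.arange(14.0)
        fit = bg.fit_logarithmic(days, np.full(14, 4.0))
        assert fit.rms_residual < 1e-6

    def test_beats_grid_oracle(self, rng):
        days = np.arange(14.0)
        for _ in range(5):
            y = rng.uniform(1, 5) * np.log(days + rng.uniform(0.5, 3)) + rng.normal(
                scale=0.2, size=14
            )
            fit = bg.fit_logarithmic(days, y)
            assert fit.rms_residual <= _grid_oracle_log_rms(days, y) + 1e-6


class TestRobustFTest:
    def test_identical_fits_give_zero(self):
        days = np.arange(14.0)
        values = np.full(14, 2.0)
        cubic = bg.fit_cubic(days, values)
        const = bg.fit_constant(days, values)
        res = bg.robust_f_test(cubic, const)
        assert res.f_stat == 0.0 and not res.significant

    def test_critical_value_rounds_to_seven_at_large_df(self):
        rng = np.random.default_rng(1)
        days = np.linspace(0, 13, 10004)
        values = np.log(days + 1) + rng.normal(scale=0.1, size=days.size)
        res = bg.robust_f_test(bg.fit_cubic(days, values), bg.fit_constant(days, values))
        assert res.df_num == 3 and res.df_den == 10000
        assert round(res.critical_value) == 7

    def test_perfect_model_infinite_f(self):
        days = np.arange(14.0)
        y = days**3
        res = bg.robust_f_test(bg.fit_cubic(days, y), bg.fit_constant(days, y))
        assert np.isinf(res.f_stat) and res.significant

    def test_strong_log_trend_detected(self):
        rng = np.random.default_rng(7)
        days = np.tile(np.arange(14.0), 10)
        hits = 0
        for _ in range(50):
            y = 3 * np.log(days + 1) + rng.normal(scale=0.05, size=days.size)
            res = bg.robust_f_test(bg.fit_logarithmic(days, y), bg.fit_constant(days, y))
            hits += res.significant
        assert hits >= 48  # power well above 95% at this noise level

    def test_mismatched_points_rejected(self):
        f1 = bg.fit_constant([0, 1, 2], [1, 2, 3])
        f2 = bg.fit_constant([0, 1], [1, 2])
        with pytest.raises(ValueError):
            bg.robust_f_test(f1, f2)


class TestModelSelection:
    def test_pure_noise_selects_constant(self):
        rng = np.random.default_rng(3)
        days = np.tile(np.arange(14.0), 5)
        sel = bg.select_trend_model(days, 5 + rng.normal(scale=0.5, size=days.size))
        assert sel.selected.kind == "constant"

    def test_log_policy_prefers_logarithmic(self):
        days = np.tile(np.arange(14.0), 5)
        rng = np.random.default_rng(4)
        y = 2 * np.log(days + 1) + rng.normal(scale=0.05, size=days.size)
        sel = bg.select_trend_model(days, y, policy="log")
        assert sel.selected.kind == "logarithmic"

    def test_best_rms_policy_picks_cubic_on_s_shape(self):
        days = np.tile(np.arange(14.0), 5)
        rng = np.random.default_rng(5)
        y = 0.05 * days**3 - 1.0 * days**2 + 5 * days + rng.normal(scale=0.1, size=days.size)
        sel = bg.select_trend_model(days, y, policy="best-rms")
        assert sel.selected.kind == "cubic"
        assert (
            sel.fits["cubic"].rms_residual < sel.fits["logarithmic"].rms_residual
        )

    def test_summary_flags_selected_model(self):
        days = np.tile(np.arange(14.0), 3)
        rng = np.random.default_rng(6)
        y = np.log(days + 1) + rng.normal(scale=0.05, size=days.size)
        table = bg.select_trend_model(days, y).summary()
        assert table.loc[table["selected"], "model"].tolist() == ["logarithmic"]


class TestTrendModelFrontEnd:
    def test_fit_and_select(self, noiseless_ts):
        days, values, _ = noiseless_ts.parameter_series("A")
        model = bg.TrendModel(days, values)
        assert model.fit("constant").d == pytest.approx(values.mean())
        sel = model.fit_select()
        assert sel.selected.kind == "logarithmic"

    def test_report_mirrors_study_structure(self, noiseless_ts):
        report = bg.model_selection_report(noiseless_ts)
        assert list(report["parameter"]) == list("ABCDE")
        # constant-only parameter stays constant; log trends are detected
        assert report.set_index("parameter").loc["E", "selected"] == "constant"
        assert (report.set_index("parameter").loc[list("ABCD"), "selected"] == "logarithmic").all()
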