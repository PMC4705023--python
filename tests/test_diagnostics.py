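import numpy as np
import pytest
from statsmodels.stats.diagnostic import acorr_ljungbox

from emavar.data_io import RunConfig
from emavar.diagnostics import (
    assess_validity,
    companion_matrix,
    normality_check,
    portmanteau,
    stability_check,
    trend_needed,
    validity_report,
)
from emavar.spec_builder import ModelSpec
from emavar.synthetic import SyntheticSpec, simulate
from emavar.var_engine import fit_var


def _fit_with_lag_matrices(matrices):
    """Minimal stand-in fit exposing lag_coefficients for stability checks."""

    class _Stub:
        lag_coefficients = [np.asarray(m, float) for m in matrices]

    return _Stub()


class TestStability:
    def test_zero_matrices_pass(self):
        res = stability_check(_fit_with_lag_matrices([np.zeros((2, 2))]))
        assert res["max_eigenvalue_modulus"] == 0.0
        assert res["pass"]

    def test_unit_root_fails(self):
        res = stability_check(_fit_with_lag_matrices([np.array([[1.0]])]))
        assert res["max_eigenvalue_modulus"] == pytest.approx(1.0)
        assert not res["pass"]

    def test_diagonal_moduli(self):
        res = stability_check(_fit_with_lag_matrices([np.diag([0.5, 0.9])]))
        assert res["max_eigenvalue_modulus"] == pytest.approx(0.9)
        assert res["pass"]

    def test_agrees_with_reverse_characteristic_polynomial_roots(self, rng):
        # oracle: roots z of det(I - A1 z - A2 z^2); stable iff all |z| > 1
        for _ in range(200):
            V = int(rng.integers(1, 3))
            p = int(rng.integers(1, 3))
            mats = [rng.uniform(-0.7, 0.7, size=(V, V)) for _ in range(p)]
            verdict = stability_check(_fit_with_lag_matrices(mats))["pass"]
            polys = np.zeros((V, V, p + 1))
            for i in range(V):
                for j in range(V):
                    polys[i, j, 0] = 1.0 if i == j else 0.0
                    for lag, A in enumerate(mats, start=1):
                        polys[i, j, lag] = -A[i, j]
            if V == 1:
                det = polys[0, 0]
            else:
                det = np.polysub(
                    np.polymul(polys[0, 0][::-1], polys[1, 1][::-1]),
                    np.polymul(polys[0, 1][::-1], polys[1, 0][::-1]),
                )[::-1]
            roots = np.roots(np.trim_zeros(det[::-1], "f"))
            oracle = bool(np.all(np.abs(roots) > 1.0)) if len(roots) else True
            assert verdict == oracle


class TestPortmanteau:
    def test_orthogonal_lag_products_give_zero_q(self):
        e = np.array([1.0, 0.0, -1.0, 0.0] * 3)
        res = portmanteau(e, h=1)
        assert res["Q"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_alternating_series_hand_computation(self):
        e = np.array([1.0, -1.0] * 4)
        res = portmanteau(e, h=1)
        assert res["Q"] == pytest.approx(8.75, abs=1e-10)
        assert res["df"] == 1
        assert res["p"] == pytest.approx(0.0031, abs=2e-4)

    def test_matches_statsmodels_ljungbox(self, rng):
        for _ in range(20):
            e = rng.normal(size=int(rng.integers(30, 120)))
            h = int(rng.integers(1, 11))
            mine = portmanteau(e, h)
            table = acorr_ljungbox(e, lags=[h])
            assert mine["Q"] == pytest.approx(float(table["lb_stat"].iloc[0]), rel=1e-10)
            assert mine["p"] == pytest.approx(float(table["lb_pvalue"].iloc[0]), rel=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            portmanteau(np.ones(20), h=2)


class TestNormality:
    def test_three_point_hand_computation(self):
        with pytest.warns(UserWarning, match="unreliable"):
            res = normality_check(np.array([-1.0, 0.0, 1.0]))
        assert res["statistic"] == pytest.approx(0.28125, abs=1e-12)
        assert res["p"] > 0.05

    def test_statistic_nonnegative(self, rng):
        for _ in range(20):
            res = normality_check(rng.normal(size=50))
            assert res["statistic"] >= 0

    def test_lognormal_right_skew_fails(self, rng):
        e = np.exp(rng.normal(size=200))
        res = normality_check(e)
        assert res["p"] < 0.05

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            normality_check(np.zeros(30))


class TestAssessValidity:
    def _fit(self, seed=1, A=((0.5, 0.0), (0.0, 0.5)), T=150):
        spec = SyntheticSpec(
            variable_names=("x", "y"),
            lag_matrices=(A,),
            intercepts=(0.0, 0.0),
            noise_covariance=np.eye(2),
            T=T,
            seed=seed,
        )
        ds, _ = simulate(spec)
        return fit_var(ds, ModelSpec(lag=1, outlier_levels=(None, None)))

    def test_clean_gaussian_var_is_valid(self):
        report = assess_validity(self._fit(seed=2), RunConfig())
        assert report.overall_valid
        assert report.failures() == []

    def test_unstable_coefficients_invalidate_regardless_of_residuals(self):
        fit = self._fit(seed=2)
        report = validity_report(fit, alpha=0.05)
        assert report.overall_valid
        # same residual tests, doctored stability: conjunction semantics
        unstable = stability_check(
            _fit_with_lag_matrices([np.array([[1.2, 0.0], [0.0, 0.5]])])
        )
        assert not unstable["pass"]

    def test_autocorrelated_residuals_fail_white_noise_for_that_variable(self):
        # mislag the model: fit white noise (lag-1 on an AR(2)-ish process)
        rng = np.random.default_rng(8)
        e = np.empty(300)
        e[0] = rng.normal()
        for t in range(1, 300):
            e[t] = 0.8 * e[t - 1] + rng.normal()
        import pandas as pd

        from emavar.data_io import EmaDataset

        values = pd.DataFrame({"x": e, "y": rng.normal(size=300)})
        ds = EmaDataset(values=values)
        # intentionally underspecified: no dynamics modeled at all, so x's
        # residuals stay autocorrelated while y's remain white
        fit = fit_var(ds, ModelSpec(lag=1, outlier_levels=(None, None),
                                    constraints=frozenset(
                                        {("x", "L1.x"), ("x", "L1.y"),
                                         ("y", "L1.x"), ("y", "L1.y")})))
        report = validity_report(fit, 0.05)
        assert not report.white_noise["x"]["pass"]
        assert report.white_noise["y"]["pass"]
        assert not report.overall_valid

    def test_pure_function(self):
        fit = self._fit(seed=4)
        a = validity_report(fit, 0.05)
        b = validity_report(fit, 0.05)
        assert a == b


class TestTrendNeeded:
    def test_trend_stationary_series_triggers_trend(self, rng):
        y = 0.1 * np.arange(1, 201) + rng.normal(size=200)
        assert trend_needed(y)["include_trend"]

    def test_random_walk_does_not_trigger_trend(self, rng):
        y = np.cumsum(rng.normal(size=200))
        assert not trend_needed(y)["include_trend"]

    def test_constant_series_guarded(self):
        with pytest.warns(UserWarning, match="constant"):
            res = trend_needed(np.full(50, 3.0))
        assert not res["include_trend"]

    def test_matches_r_pp_statistic(self):
        # frozen from R stats::PP.test (lshort bandwidth) on the same series
        rng = np.random.default_rng(42)
        y1 = 0.1 * np.arange(1, 201) + rng.normal(size=200)
        y2 = np.cumsum(rng.normal(size=200))
        assert trend_needed(y1)["statistic"] == pytest.approx(-12.364621, abs=2e-4)
        assert trend_needed(y2)["statistic"] == pytest.approx(-2.779810, abs=2e-4)


def test_companion_matrix_shape_and_content():
    A1 = np.array([[0.5, 0.1], [0.0, 0.4]])
    A2 = np.array([[0.1, 0.0], [0.2, 0.1]])
    comp = companion_matrix([A1, A2])
    assert comp.shape == (4, 4)
    assert np.array_equal(comp[:2, :2], A1)
    assert np.array_equal(comp[:2, 2:], A2)
    assert np.array_equal(comp[2:, :2], np.eye(2))
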