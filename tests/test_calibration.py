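"""Calibration line, confidence band, method LoD/LoQ, inverse prediction."""

import numpy as np
import pytest

from libsquant import (
    CalibrationPoint,
    confidence_band,
    fit_calibration,
    fit_calibration_xy,
    method_lod_loq,
    predict_concentration,
    sigma_cc,
    simulate_calibration_points,
)
from scipy import stats as sps


def _points(x, y):
    return [CalibrationPoint(f"s{i}", xi, yi) for i, (xi, yi) in enumerate(zip(x, y))]


def normal_equation_fit(x, y):
    """Hand-coded normal equations: independent OLS oracle."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sigma = np.sqrt(resid @ resid / (len(x) - 2))
    return beta[1], beta[0], sigma


def test_exact_collinear_fit():
    m = fit_calibration(_points([0, 1, 2], [0, 10, 20]))
    assert m.m == pytest.approx(10.0)
    assert m.b == pytest.approx(0.0, abs=1e-10)
    assert m.r2 == pytest.approx(1.0)
    assert m.sigma_fit == pytest.approx(0.0, abs=1e-9)
    assert m.lod_conc == pytest.approx(0.0, abs=1e-9)


def test_ols_matches_normal_equations():
    rng = np.random.default_rng(31)
    x = np.repeat([0.0, 1.0, 3.0, 9.0], 3)
    y = 5e5 * x + 1e4 + rng.normal(0, 2e4, x.size)
    model = fit_calibration_xy(x, y)
    m_o, b_o, s_o = normal_equation_fit(x, y)
    assert model.m == pytest.approx(m_o, rel=1e-9)
    assert model.b == pytest.approx(b_o, rel=1e-9)
    assert model.sigma_fit == pytest.approx(s_o, rel=1e-9)


def test_degenerate_design_rejected():
    with pytest.raises(ValueError, match="degenerate design"):
        fit_calibration(_points([2, 2, 2], [1, 2, 3]))
    with pytest.raises(ValueError, match="at least 3"):
        fit_calibration(_points([0, 1], [0, 1]))


def test_method_lod_loq_arithmetic():
    model = fit_calibration(_points([0, 1, 2], [0, 10, 20]))
    model.sigma_fit = 1.0
    lod, loq = method_lod_loq(model)
    assert lod == pytest.approx(0.33)  # 3.3·1/10
    assert loq == pytest.approx(1.0)
    assert loq / lod == pytest.approx(10 / 3.3, rel=1e-12)


def test_method_lod_loq_zero_sigma():
    model = fit_calibration(_points([0, 1, 2], [0, 10, 20]))
    model.sigma_fit = 0.0
    assert method_lod_loq(model) == (0.0, 0.0)


def test_method_lod_loq_requires_positive_slope():
    model = fit_calibration(_points([0, 1, 2], [20, 10, 0]))
    with pytest.raises(ValueError, match="slope"):
        method_lod_loq(model)


def test_zero_sigma_band_has_zero_width():
    model = fit_calibration(_points([0, 1, 2], [0, 10, 20]))
    lower, upper = confidence_band(model, np.linspace(0, 2, 5))
    np.testing.assert_allclose(upper - lower, 0.0, atol=1e-8)


def test_band_halfwidth_at_centroid():
    """At x = x̄ the half-width reduces to t·σ_fit/√n."""
    rng = np.random.default_rng(6)
    x = np.repeat([0.0, 1.0, 3.0, 9.0], 3)
    y = 2.0 * x + rng.normal(0, 0.5, x.size)
    model = fit_calibration_xy(x, y, level=0.70)
    lower, upper = confidence_band(model, model.x_mean)
    half = (upper - lower) / 2
    t = sps.t.ppf(0.85, model.n - 2)
    assert half == pytest.approx(t * model.sigma_fit / np.sqrt(model.n), rel=1e-12)


def test_band_close_to_bootstrap():
    """The analytic 70% mean-response band agrees with a case-resampling
    bootstrap percentile band (n = 12, 10 000 resamples) within 15% of the
    half-width over the design range (the case bootstrap runs slightly
    narrow at the design edges for small n)."""
    rng = np.random.default_rng(44)
    x = np.repeat([0.0, 1.0, 3.0, 9.0], 3)
    y = 3.0 * x + 1.0 + rng.normal(0, 0.8, x.size)
    model = fit_calibration_xy(x, y, level=0.70)
    grid = np.linspace(0.5, 8.5, 9)

    boots = np.empty((10_000, grid.size))
    for i in range(10_000):
        idx = rng.integers(0, x.size, x.size)
        if np.unique(x[idx]).size < 2:
            boots[i] = np.nan
            continue
        X = np.column_stack([np.ones(x.size), x[idx]])
        beta = np.linalg.lstsq(X, y[idx], rcond=None)[0]
        boots[i] = beta[0] + beta[1] * grid
    lo_b = np.nanpercentile(boots, 15, axis=0)
    hi_b = np.nanpercentile(boots, 85, axis=0)
    lower, upper = confidence_band(model, grid)
    half = (upper - lower) / 2
    half_b = (hi_b - lo_b) / 2
    assert np.all(np.abs(half - half_b) <= 0.15 * half)


def test_sigma_cc_matches_band_at_median():
    rng = np.random.default_rng(2)
    x = np.repeat([0.0, 1.0, 3.0, 9.0], 3)
    y = 4.0 * x + 0.5 + rng.normal(0, 0.6, x.size)
    pts = _points(x, y)
    model = fit_calibration(pts)
    x_med = np.median(x)
    lower, upper = confidence_band(model, x_med)
    expected = (upper - lower) / 2 / model.predict_response(x_med) * 100.0
    assert sigma_cc(model, pts) == pytest.approx(float(expected), rel=1e-12)


def test_sigma_cc_zero_for_perfect_fit():
    pts = _points([1, 2, 3], [10, 20, 30])
    model = fit_calibration(pts)
    assert sigma_cc(model, pts) == pytest.approx(0.0, abs=1e-9)


def test_predict_concentration_round_trip():
    model = fit_calibration(_points([0, 1, 2], [0, 10, 20]))
    assert predict_concentration(model, 100.0).concentration == pytest.approx(10.0)
    assert predict_concentration(model, model.b).concentration == 0.0
    for x in np.linspace(0.5, 50, 7):
        pred = predict_concentration(model, model.m * x + model.b)
        assert pred.concentration == pytest.approx(x, rel=1e-12)


def test_prediction_flags():
    rng = np.random.default_rng(77)
    x = np.repeat([0.0, 1.0, 3.0, 9.0], 3)
    y = 10.0 * x + rng.normal(0, 1.0, x.size)
    model = fit_calibration_xy(x, y)
    assert model.lod_conc > 0
    below_lod = predict_concentration(model, model.b + model.m * model.lod_conc / 2)
    assert any("not detected" in f for f in below_lod.flags)
    between = predict_concentration(
        model, model.b + model.m * (model.lod_conc + model.loq_conc) / 2
    )
    assert any("below method LoQ" in f for f in between.flags)
    negative = predict_concentration(model, model.b - 5 * model.m)
    assert negative.concentration == 0.0
    assert any("clipped" in f for f in negative.flags)


def test_r2_unity_iff_zero_residuals():
    exact = fit_calibration(_points([0, 1, 2, 3], [1, 3, 5, 7]))
    assert exact.r2 == pytest.approx(1.0)
    noisy = fit_calibration(_points([0, 1, 2, 3], [1, 3.2, 5, 7]))
    assert noisy.r2 < 1.0


def test_origin_consistency_recorded():
    rng = np.random.default_rng(10)
    df = simulate_calibration_points([0.2, 209, 554, 1477], 1e6, seed=rng)
    model = fit_calibration_xy(df["concentration_ug_g"], df["svalue_counts_cm2"])
    assert isinstance(model.origin_in_intercept_ci, bool)
    lo, hi = model.intercept_ci
    assert lo < hi
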