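"""Noise sampling, noise fitting, and the LoD/LoQ closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from libsquant import (
    NoiseStats,
    SpectralCube,
    compute_thresholds,
    fit_noise,
    sample_noise,
    ti_line,
)

finite = st.floats(min_value=-1e6, max_value=1e6)
nonneg = st.floats(min_value=0, max_value=1e6)


@pytest.mark.parametrize(
    "mean,sigma,k_lod,k_loq,lod,loq",
    [
        (100.0, 10.0, 3, 10, 130.0, 200.0),
        (0.0, 1.0, 3, 10, 3.0, 10.0),
        (42.0, 5.0, 0, 0, 42.0, 42.0),
    ],
)
def test_threshold_arithmetic(mean, sigma, k_lod, k_loq, lod, loq):
    thr = compute_thresholds(NoiseStats(mean, sigma, 10), k_lod, k_loq)
    assert thr.lod == pytest.approx(lod)
    assert thr.loq == pytest.approx(loq)


def test_negative_k_rejected():
    with pytest.raises(ValueError):
        compute_thresholds(NoiseStats(0.0, 1.0, 10), k_lod=-1)


@settings(deadline=None, max_examples=100)
@given(mean=finite, sigma=nonneg, k_lod=st.floats(0, 50), k_loq=st.floats(0, 50))
def test_threshold_closed_form_property(mean, sigma, k_lod, k_loq):
    """lod = x̄ + k_lod·σ and loq − lod = (k_loq − k_lod)·σ exactly."""
    thr = compute_thresholds(NoiseStats(mean, sigma, 10), k_lod, k_loq)
    assert thr.lod == mean + k_lod * sigma
    assert thr.loq - thr.lod == pytest.approx((k_loq - k_lod) * sigma, rel=1e-12, abs=1e-9)


def test_moments_estimator_is_sample_moments():
    rng = np.random.default_rng(5)
    x = rng.normal(50, 7, 1000)
    stats = fit_noise(x, method="moments")
    assert stats.mean == np.mean(x)
    assert stats.sigma == np.std(x, ddof=1)


def test_constant_samples_moments():
    stats = fit_noise(np.full(200, 7.0), method="moments")
    assert stats.mean == 7.0 and stats.sigma == 0.0


def test_histogram_gauss_requires_spread():
    with pytest.raises(ValueError, match="moments"):
        fit_noise(np.full(200, 7.0), method="histogram_gauss")


def test_histogram_gauss_matches_moments_on_gaussian_draw():
    """On a clean Gaussian sample (n = 32 000) the histogram fit agrees with
    the sample moments within 1%."""
    rng = np.random.default_rng(42)
    x = rng.normal(100, 10, 32_000)
    hg = fit_noise(x, method="histogram_gauss")
    mo = fit_noise(x, method="moments")
    assert hg.mean == pytest.approx(mo.mean, rel=0.01)
    assert hg.sigma == pytest.approx(mo.sigma, rel=0.01)


def test_histogram_gauss_discounts_right_tail():
    """With 5% of samples shifted +5σ (weak analyte lines leaking into the
    noise window) the histogram fit reports a smaller σ than the moments."""
    rng = np.random.default_rng(7)
    x = rng.normal(100, 10, 32_000)
    x[: x.size // 20] += 50.0
    hg = fit_noise(x, method="histogram_gauss")
    mo = fit_noise(x, method="moments")
    assert hg.sigma < mo.sigma


def test_robust_estimator_on_gaussian():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 10, 32_000)
    rb = fit_noise(x, method="robust")
    assert rb.sigma == pytest.approx(10.0, rel=0.05)
    assert rb.mean == pytest.approx(0.0, abs=0.3)


def _noise_cube(ny, nx, sigma, seed):
    wl = 318.0 + 0.15 * np.arange(45)  # 318.0–324.6 nm, covers the noise window
    rng = np.random.default_rng(seed)
    data = 100.0 + rng.normal(0, sigma, (ny, nx, wl.size))
    return SpectralCube(wl, data, step=20.0)


def test_sample_noise_zero_cube():
    wl = 318.0 + 0.15 * np.arange(45)
    cube = SpectralCube(wl, np.zeros((4, 4, wl.size)), step=20.0)
    out = sample_noise(cube)
    np.testing.assert_allclose(out, 0.0, atol=1e-9)
    assert out.size == 16


def test_sample_noise_variance_matches_propagation():
    """The summed-noise statistic over ~32 000 spectra has the variance
    predicted by direct propagation through the summation operator."""
    sigma = 5.0
    cube = _noise_cube(160, 200, sigma, seed=21)
    out = sample_noise(cube, line_template=ti_line())
    assert out.size == 32_000

    # independent propagation: I = 1ᵀy_fit − 1ᵀ X_fit (X_bᵀX_b)⁻¹ X_bᵀ y_b
    wl = cube.wavelengths
    center = 321.0
    fit = (wl >= center - 0.3) & (wl <= center + 0.3)
    base = ((wl >= center - 0.95) & (wl <= center - 0.35)) | (
        (wl >= center + 0.35) & (wl <= center + 0.95)
    )
    Xb = np.column_stack([np.ones(base.sum()), wl[base]])
    Xf = np.column_stack([np.ones(fit.sum()), wl[fit]])
    proj = Xf.sum(axis=0) @ np.linalg.inv(Xb.T @ Xb) @ Xb.T
    var_oracle = sigma**2 * (fit.sum() + proj @ proj)
    assert np.var(out, ddof=1) == pytest.approx(var_oracle, rel=0.05)
    assert np.mean(out) == pytest.approx(0.0, abs=3 * np.sqrt(var_oracle / out.size))


def test_sample_noise_restriction_and_errors():
    cube = _noise_cube(6, 6, 1.0, seed=1)
    m = np.zeros((6, 6), bool)
    m[0, :3] = True
    assert sample_noise(cube, restrict_to=m).size == 3
    with pytest.raises(ValueError, match="no spectra selected"):
        sample_noise(cube, restrict_to=np.zeros((6, 6), bool))
    with pytest.raises(ValueError, match="shape"):
        sample_noise(cube, restrict_to=np.zeros((3, 3), bool))


def test_per_sample_metric_returns_raw_window():
    cube = _noise_cube(2, 2, 1.0, seed=2)
    wl = cube.wavelengths
    sel = (wl >= 320.0) & (wl <= 322.0)
    out = sample_noise(cube, metric="per_sample")
    assert out.size == 4 * sel.sum()
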