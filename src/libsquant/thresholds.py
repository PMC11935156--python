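"""Noise characterization and LoD/LoQ thresholds.

Detector noise is sampled in a line-free spectral window (320–322 nm by
default, just short of the Ti 323.65 nm line) and summarized by its mean
x̄_c and standard deviation σ.  The limit of detection LoD = x̄_c + 3σ acts
as the tissue threshold on the phosphorus map; the limit of quantification
LoQ = x̄_c + 10σ acts as the signal threshold on the analyte map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .spectral import (
    DEFAULT_BASELINE_OFFSETS_NM,
    DEFAULT_FIT_HALFWIDTH_NM,
    EmissionLine,
    SpectralCube,
    _sum_intensity_stack,
)

DEFAULT_NOISE_WINDOW_NM = (320.0, 322.0)


@dataclass(frozen=True)
class NoiseStats:
    """Mean and spread of the detector noise in a signal-free window."""

    mean: float
    sigma: float
    n: int
    window: tuple[float, float] = DEFAULT_NOISE_WINDOW_NM
    method: str = "moments"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n < 2:
            raise ValueError("need at least 2 noise samples")


@dataclass(frozen=True)
class Thresholds:
    """Detection (LoD) and quantification (LoQ) thresholds in counts."""

    lod: float
    loq: float
    k_lod: float = 3.0
    k_loq: float = 10.0


def _pseudo_line(window: tuple[float, float], template: EmissionLine | None) -> EmissionLine:
    """An artificial line centered in the noise window, mirroring the analyte
    line's window geometry so noise and signal share units."""
    center = 0.5 * (window[0] + window[1])
    if template is not None:
        fit_w = template.fit_window
        offsets = (
            template.baseline_windows[1][0] - template.center,
            template.baseline_windows[1][1] - template.center,
        )
    else:
        fit_w = DEFAULT_FIT_HALFWIDTH_NM
        offsets = DEFAULT_BASELINE_OFFSETS_NM
    return EmissionLine(
        "noise",
        center,
        fit_window=fit_w,
        baseline_windows=(
            (center - offsets[1], center - offsets[0]),
            (center + offsets[0], center + offsets[1]),
        ),
    )


def sample_noise(
    cube: SpectralCube,
    window: tuple[float, float] = DEFAULT_NOISE_WINDOW_NM,
    restrict_to: np.ndarray | None = None,
    metric: Literal["per_spectrum_sum", "per_sample"] = "per_spectrum_sum",
    line_template: EmissionLine | None = None,
) -> np.ndarray:
    """One noise statistic per selected pixel, from a line-free window.

    ``per_spectrum_sum`` (default) applies the same background-free summation
    operator used for analyte lines to a pseudo-line centered in the window,
    without clipping, so the noise distribution is directly comparable with
    extracted line intensities.  ``per_sample`` returns the raw spectral
    samples inside the window.  ``restrict_to`` limits sampling to a boolean
    pixel mask (e.g. a provisional tissue mask).
    """
    wl = cube.wavelengths
    if window[0] < wl[0] or window[1] > wl[-1]:
        raise ValueError(f"noise window {window} outside spectral range")
    if restrict_to is not None:
        restrict_to = np.asarray(restrict_to, dtype=bool)
        if restrict_to.shape != cube.shape:
            raise ValueError("restrict_to mask shape does not match cube grid")
        spectra = cube.intensities[restrict_to]
    else:
        spectra = cube.intensities.reshape(-1, wl.size)
    if spectra.shape[0] == 0:
        raise ValueError("no spectra selected")

    if metric == "per_sample":
        sel = (wl >= window[0]) & (wl <= window[1])
        return np.asarray(spectra[:, sel], dtype=float).ravel()
    if metric == "per_spectrum_sum":
        line = _pseudo_line(window, line_template)
        return _sum_intensity_stack(wl, spectra, line, clip=False)
    raise ValueError(f"unknown metric {metric!r}")


def _gaussian(x, amp, mu, sig):
    return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)


def fit_noise(
    samples: Sequence[float],
    method: Literal["histogram_gauss", "moments", "robust"] = "histogram_gauss",
    window: tuple[float, float] = DEFAULT_NOISE_WINDOW_NM,
) -> NoiseStats:
    """Estimate the noise mean and σ from sampled noise statistics.

    ``histogram_gauss`` least-squares fits a Gaussian to the Freedman–Diaconis
    histogram, which discounts a contaminated right tail (weak analyte lines
    leaking into the window); ``moments`` uses the sample mean/SD; ``robust``
    uses the median and 1.4826×MAD.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if method == "moments":
        return NoiseStats(float(np.mean(x)), float(np.std(x, ddof=1)), n, window, method)
    if method == "robust":
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        return NoiseStats(med, 1.4826 * mad, n, window, method)
    if method == "histogram_gauss":
        if n < 100:
            raise ValueError("histogram_gauss needs at least 100 samples")
        if np.ptp(x) == 0:
            raise ValueError(
                "samples have zero spread; use method='moments' instead"
            )
        counts, edges = np.histogram(x, bins="fd")
        centers = 0.5 * (edges[:-1] + edges[1:])
        p0 = [counts.max(), float(np.mean(x)), max(float(np.std(x)), 1e-12)]
        popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=10000)
        return NoiseStats(float(popt[1]), abs(float(popt[2])), n, window, method)
    raise ValueError(f"unknown method {method!r}")


def compute_thresholds(stats: NoiseStats, k_lod: float = 3.0, k_loq: float = 10.0) -> Thresholds:
    """LoD = x̄_c + k_lod·σ and LoQ = x̄_c + k_loq·σ."""
    if k_lod < 0 or k_loq < 0:
        raise ValueError("k multipliers must be non-negative")
    return Thresholds(
        lod=stats.mean + k_lod * stats.sigma,
        loq=stats.mean + k_loq * stats.sigma,
        k_lod=k_lod,
        k_loq=k_loq,
    )
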