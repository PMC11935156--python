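"""Synthetic LIBS phantoms with ground truth.

No public LIBS hyperspectral cubes of embedded lung tissue exist, so every
stage of the pipeline is exercised against procedurally generated phantoms:

* a porous tissue geometry (union of random ellipses minus random holes),
  mimicking lung parenchyma inside a paraffin block;
* a phosphorus emission line of fixed amplitude on tissue pixels — the
  tissue proxy used for masking;
* a titanium signal carried by sparse "particles": each tissue pixel is hit
  with a small probability and a hit draws a right-skewed (log-normal)
  intensity whose mean is proportional to the nominal concentration, so the
  expected Svalue is linear in concentration by construction (a homogeneous
  Gaussian alternative is available);
* additive i.i.d. Gaussian detector noise on every spectral sample.

Amplitudes are parameterized as signal-to-noise ratios of the *extracted*
summed intensity, using the exact noise propagation through the summation
operator, so phantoms remain meaningful when windows or noise levels change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .spectral import (
    ElementMap,
    EmissionLine,
    SpectralCube,
    p_line,
    propagated_sum_noise_sd,
    ti_line,
)
from .thresholds import DEFAULT_NOISE_WINDOW_NM, NoiseStats

GAUSS_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic acquisition; reproducible given ``seed``."""

    ny: int = 64
    nx: int = 64
    step_um: float = 20.0
    wl_min: float = 249.0
    wl_max: float = 333.0
    wl_step: float = 0.15
    line_fwhm_nm: float = 0.15
    baseline: float = 100.0  # counts, flat spectral background
    noise_sigma: float = 5.0  # counts per spectral sample
    p_snr: float = 10.0  # extracted P intensity / extracted-noise SD
    concentration: float = 0.0  # μg g⁻¹ of the exogenous element
    hit_prob: float = 0.05  # per-tissue-pixel particle probability
    particle_snr_per_conc: float = 30.0  # mean particle intensity, σ_I units per μg g⁻¹
    lognormal_sigma: float = 0.8  # shape of the particle-intensity distribution
    particle_model: Literal["lognormal", "gaussian"] = "lognormal"
    tissue_model: Literal["porous", "full"] = "porous"
    n_blobs: int = 3
    n_holes: int = 8
    seed: int = 0
    p_emission: EmissionLine = field(default_factory=p_line)
    ti_emission: EmissionLine = field(default_factory=ti_line)

    def __post_init__(self) -> None:
        if not 0.0 <= self.hit_prob <= 1.0:
            raise ValueError("hit_prob must be in [0, 1]")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        for line in (self.p_emission, self.ti_emission):
            if not (self.wl_min < line.center < self.wl_max):
                raise ValueError(
                    f"{line.element} line at {line.center} nm outside the "
                    f"[{self.wl_min}, {self.wl_max}] nm range"
                )

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wl_max - self.wl_min) / self.wl_step)) + 1
        return self.wl_min + self.wl_step * np.arange(n)


@dataclass
class PhantomTruth:
    """Ground truth stored alongside a generated cube."""

    tissue_mask: np.ndarray
    ti_intensity: np.ndarray  # noise-free per-pixel extracted-intensity scale
    p_intensity: np.ndarray
    concentration: float
    noise_sd_p: float  # propagated SD of the summed P-line extraction
    noise_sd_ti: float
    spec: PhantomSpec


def _tissue_geometry(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Porous mask: union of random ellipses minus random elliptical holes."""
    yy, xx = np.mgrid[0 : spec.ny, 0 : spec.nx]
    scale = min(spec.ny, spec.nx)

    def ellipse(cy, cx, ay, ax, theta):
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0

    mask = np.zeros((spec.ny, spec.nx), dtype=bool)
    for _ in range(spec.n_blobs):
        mask |= ellipse(
            rng.uniform(0.25 * spec.ny, 0.75 * spec.ny),
            rng.uniform(0.25 * spec.nx, 0.75 * spec.nx),
            rng.uniform(0.18, 0.38) * scale,
            rng.uniform(0.18, 0.38) * scale,
            rng.uniform(0, np.pi),
        )
    for _ in range(spec.n_holes):
        mask &= ~ellipse(
            rng.uniform(0, spec.ny),
            rng.uniform(0, spec.nx),
            rng.uniform(0.02, 0.07) * scale,
            rng.uniform(0.02, 0.07) * scale,
            rng.uniform(0, np.pi),
        )
    return mask


def _intensity_fields(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Tissue mask plus noise-free P and Ti per-pixel extracted intensities."""
    if spec.tissue_model == "full":
        tissue = np.ones((spec.ny, spec.nx), dtype=bool)
    else:
        tissue = _tissue_geometry(spec, rng)
    wl = spec.wavelengths
    sd_p = propagated_sum_noise_sd(wl, spec.p_emission, spec.noise_sigma)
    sd_ti = propagated_sum_noise_sd(wl, spec.ti_emission, spec.noise_sigma)
    # noiseless phantom: SNR-style amplitudes fall back to absolute counts
    unit_p = sd_p if sd_p > 0 else 1.0
    unit_ti = sd_ti if sd_ti > 0 else 1.0

    p_int = np.where(tissue, spec.p_snr * unit_p, 0.0)

    ti_int = np.zeros_like(p_int)
    mean_particle = spec.particle_snr_per_conc * unit_ti * spec.concentration
    if mean_particle > 0 and tissue.any():
        if spec.particle_model == "lognormal":
            hits = tissue & (rng.random(tissue.shape) < spec.hit_prob)
            s = spec.lognormal_sigma
            mu = np.log(mean_particle) - 0.5 * s * s
            ti_int[hits] = rng.lognormal(mu, s, size=int(hits.sum()))
        elif spec.particle_model == "gaussian":
            level = spec.hit_prob * mean_particle
            draw = rng.normal(level, 0.2 * level, size=int(tissue.sum()))
            ti_int[tissue] = np.maximum(draw, 0.0)
        else:
            raise ValueError(f"unknown particle model {spec.particle_model!r}")
    return tissue, p_int, ti_int, sd_p, sd_ti


def _peak_profile(wl: np.ndarray, line: EmissionLine, fwhm: float) -> np.ndarray:
    """Unit-extracted-intensity spectral profile of a Gaussian line.

    Normalized by its discrete sum so that summing the sampled profile
    (after baseline removal) yields exactly 1.0, letting per-pixel
    intensities be injected directly on the extracted scale; the discrete
    normalization avoids the grid-alignment aliasing of the analytic area
    when the line width is comparable to the sampling step."""
    s = fwhm / GAUSS_FWHM_TO_SIGMA
    prof = np.exp(-0.5 * ((wl - line.center) / s) ** 2)
    return prof / prof.sum()


def generate_cube(spec: PhantomSpec) -> tuple[SpectralCube, PhantomTruth]:
    """Emit a full hyperspectral cube plus its ground truth.

    The cube is flat baseline + P peaks on tissue + Ti particle peaks +
    i.i.d. Gaussian noise; identical specs (including seed) yield bitwise
    identical cubes.
    """
    rng = np.random.default_rng(spec.seed)
    tissue, p_int, ti_int, sd_p, sd_ti = _intensity_fields(spec, rng)
    wl = spec.wavelengths

    prof_p = _peak_profile(wl, spec.p_emission, spec.line_fwhm_nm)
    prof_ti = _peak_profile(wl, spec.ti_emission, spec.line_fwhm_nm)
    cube = (
        spec.baseline
        + p_int[..., None] * prof_p[None, None, :]
        + ti_int[..., None] * prof_ti[None, None, :]
    )
    if spec.noise_sigma > 0:
        cube = cube + rng.normal(0.0, spec.noise_sigma, size=cube.shape)

    truth = PhantomTruth(
        tissue_mask=tissue,
        ti_intensity=ti_int,
        p_intensity=p_int,
        concentration=spec.concentration,
        noise_sd_p=sd_p,
        noise_sd_ti=sd_ti,
        spec=spec,
    )
    return (
        SpectralCube(
            wavelengths=wl,
            intensities=cube,
            step=spec.step_um,
            meta={"phantom_seed": spec.seed, "concentration_ug_g": spec.concentration},
        ),
        truth,
    )


def generate_maps(spec: PhantomSpec) -> tuple[ElementMap, ElementMap, PhantomTruth]:
    """Map-level shortcut: extracted-intensity P and Ti maps without spectra.

    Adds Gaussian noise with the exact propagated SD of the summation
    operator directly on the extracted scale and clips at zero, matching
    what ``build_element_map`` produces on a full cube — useful for large
    grids where materializing the cube is wasteful.
    """
    rng = np.random.default_rng(spec.seed)
    tissue, p_int, ti_int, sd_p, sd_ti = _intensity_fields(spec, rng)
    p_vals = np.maximum(p_int + rng.normal(0.0, sd_p, p_int.shape), 0.0)
    ti_vals = np.maximum(ti_int + rng.normal(0.0, sd_ti, ti_int.shape), 0.0)
    truth = PhantomTruth(tissue, ti_int, p_int, spec.concentration, sd_p, sd_ti, spec)
    pm = ElementMap(p_vals, "P", spec.p_emission, spec.step_um)
    tm = ElementMap(ti_vals, "Ti", spec.ti_emission, spec.step_um)
    return pm, tm, truth


def noise_stats_for(spec: PhantomSpec, line: EmissionLine | None = None) -> NoiseStats:
    """Analytic noise statistics of a phantom on the extracted scale.

    After baseline subtraction the extracted noise has mean 0 and the
    propagated SD of the summation operator; ``n`` is the pixel count."""
    line = line or spec.ti_emission
    sd = propagated_sum_noise_sd(spec.wavelengths, line, spec.noise_sigma)
    return NoiseStats(0.0, sd, max(spec.ny * spec.nx, 2), DEFAULT_NOISE_WINDOW_NM, "analytic")


def _subseed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)).generate_state(1)[0] % (2**31))


def generate_calibration_series(
    concentrations: Sequence[float],
    template: PhantomSpec = PhantomSpec(),
    n_replicates: int = 3,
    seed: int = 0,
) -> list[tuple[float, int, PhantomSpec]]:
    """Specs for a calibration design: each (concentration, replicate) pair
    gets its own deterministic sub-seed.  Mirrors a 4-group × 3-replicate
    exposure layout when given four concentration levels."""
    if len(set(concentrations)) < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    out = []
    for i, conc in enumerate(concentrations):
        for r in range(n_replicates):
            out.append(
                (
                    float(conc),
                    r,
                    replace(template, concentration=float(conc), seed=_subseed(seed, i, r)),
                )
            )
    return out


def simulate_calibration_points(
    concentrations: Sequence[float],
    slope: float,
    intercept: float = 0.0,
    rel_noise: float = 0.067,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
    noise_mode: Literal["relative", "uniform"] = "uniform",
) -> pd.DataFrame:
    """Direct (Svalue, concentration) samples around a known line.

    ``rel_noise`` is the relative measurement uncertainty of each Svalue.
    ``uniform`` (default) applies one homoscedastic SD equal to ``rel_noise``
    times the mean design response, the setting under which the t-based OLS
    confidence interval is exact; ``relative`` scales the SD with each
    point's own response.  Simulated responses are not truncated at zero —
    truncation would bias the fit near the control level; use
    :func:`libsquant.calibration.fit_calibration_xy` on these frames.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.repeat(np.asarray(concentrations, dtype=float), n_replicates)
    y_true = slope * x + intercept
    if noise_mode == "uniform":
        sd = np.full_like(y_true, rel_noise * float(np.mean(y_true)))
    elif noise_mode == "relative":
        sd = rel_noise * y_true
    else:
        raise ValueError(f"unknown noise mode {noise_mode!r}")
    y = y_true + rng.normal(0.0, 1.0, size=x.size) * sd
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:02d}" for i in range(x.size)],
            "concentration_ug_g": x,
            "svalue_counts_cm2": y,
        }
    )
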