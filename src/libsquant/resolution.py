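"""Resolution degradation study: Svalue stability under coarser pixel pitch.

Acquisition time scales with shot count, i.e. inversely with the square of
the step size.  To ask how much precision a coarser step costs, the
full-resolution acquisition is degraded in silico: within every k×k pixel
block one pixel is drawn uniformly at random (the same position in the P and
analyte maps — both spectra come from the same laser shot), emulating an
acquisition at k times the step.  Repeating the draw gives a Monte-Carlo
distribution of the Svalue at each step size; its relative SD versus the
full-resolution reference is the σ_Δx component of the uncertainty budget.

Degraded Svalues are extrapolated to the full sampled area — mean analyte
intensity per sampled tissue pixel divided by the *native* pixel area — so
values are comparable across step sizes (raw summed counts drop as 1/k²).
Block sampling is uniform, which makes the extrapolated Svalue an unbiased
estimator of the reference when the mask is stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectral import ElementMap
from .thresholds import NoiseStats, Thresholds, compute_thresholds


def _block_pick(ny: int, nx: int, k: int, rng: np.random.Generator):
    """Row/column indices of one uniformly drawn pixel per k×k block.

    Partial edge blocks draw uniformly over their actual extent.  Row offsets
    are drawn before column offsets, fixing the stream order.
    """
    nby = -(-ny // k)
    nbx = -(-nx // k)
    heights = np.minimum(k, ny - k * np.arange(nby))
    widths = np.minimum(k, nx - k * np.arange(nbx))
    offy = np.floor(rng.random((nby, nbx)) * heights[:, None]).astype(int)
    offx = np.floor(rng.random((nby, nbx)) * widths[None, :]).astype(int)
    rows = k * np.arange(nby)[:, None] + offy
    cols = k * np.arange(nbx)[None, :] + offx
    return rows, cols


def degrade_maps(
    p_map: ElementMap,
    element_map: ElementMap,
    k: int,
    seed: int | np.random.Generator = 0,
) -> tuple[ElementMap, ElementMap]:
    """Subsample both maps to a k-fold coarser grid by per-block random picks.

    The same pixel position is taken from both maps, since both intensities
    originate from the same physical laser shot.  The output grid is
    ⌈ny/k⌉ × ⌈nx/k⌉ with step k·step.  k = 1 is the identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if p_map.shape != element_map.shape:
        raise ValueError("maps must share the pixel grid")
    ny, nx = p_map.shape
    if k > ny and k > nx:
        raise ValueError(f"k = {k} exceeds both grid dimensions {ny}×{nx}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = _block_pick(ny, nx, k, rng)
    step = p_map.step * k
    p_sub = ElementMap(p_map.values[rows, cols], p_map.element, p_map.line, step)
    e_sub = ElementMap(
        element_map.values[rows, cols], element_map.element, element_map.line, step
    )
    return p_sub, e_sub


@dataclass
class DegradationResult:
    factor: int
    step_um: float  # k × native step
    replicates: int
    svalues: np.ndarray  # extrapolated counts/cm², one per replicate
    mean: float
    sd_pct: float  # SD relative to the full-resolution reference, percent
    reference: float
    n_dropped: int = 0


def _extrapolated_svalue(
    p_sub: ElementMap,
    e_sub: ElementMap,
    thresholds: Thresholds,
    native_pixel_cm2: float,
) -> float | None:
    """Mean in-mask above-LoQ intensity per sampled tissue pixel, divided by
    the native pixel area.  None when the degraded mask is empty."""
    tissue = p_sub.values > thresholds.lod
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        return None
    vals = e_sub.values[tissue]
    total = float(vals[vals >= thresholds.loq].sum())
    return total / n_tissue / native_pixel_cm2


def resolution_sensitivity(
    p_map: ElementMap,
    element_map: ElementMap,
    stats: NoiseStats,
    factors: Sequence[int] = (2, 3, 4, 5, 10),
    n_reps: int = 100,
    seed: int = 0,
    k_lod: float = 3.0,
    k_loq: float = 10.0,
    operating_step_um: float = 50.0,
    max_drop_frac: float = 0.2,
) -> tuple[list[DegradationResult], float]:
    """Monte-Carlo Svalue distribution at each degradation factor.

    The reference acquisition's thresholds apply unchanged to every degraded
    replicate (degradation emulates fewer shots, not a different instrument
    state); the tissue mask is re-derived on each degraded P map.  Replicate
    r of factor k uses the deterministic substream (seed, k, r).  Replicates
    with an empty degraded mask are dropped with a warning; more than
    ``max_drop_frac`` dropped at any factor is an error.

    Returns the per-factor results plus σ_Δx: the relative SD at the factor
    whose effective step is closest to ``operating_step_um``.
    """
    thresholds = compute_thresholds(stats, k_lod=k_lod, k_loq=k_loq)
    native_pixel_cm2 = (p_map.step * 1e-4) ** 2

    ref = _extrapolated_svalue(p_map, element_map, thresholds, native_pixel_cm2)
    if ref is None or ref <= 0:
        raise ValueError("reference Svalue is not positive")

    results: list[DegradationResult] = []
    for k in factors:
        svals = []
        dropped = 0
        for r in range(n_reps):
            rng = np.random.default_rng([int(seed), int(k), int(r)])
            p_sub, e_sub = degrade_maps(p_map, element_map, int(k), rng)
            s = _extrapolated_svalue(p_sub, e_sub, thresholds, native_pixel_cm2)
            if s is None:
                dropped += 1
                warnings.warn(
                    f"factor {k}, replicate {r}: empty degraded mask, dropped",
                    stacklevel=2,
                )
                continue
            svals.append(s)
        if dropped > max_drop_frac * n_reps:
            raise ValueError(f"factor {k}: {dropped}/{n_reps} replicates dropped")
        svals = np.asarray(svals)
        results.append(
            DegradationResult(
                factor=int(k),
                step_um=p_map.step * k,
                replicates=len(svals),
                svalues=svals,
                mean=float(svals.mean()),
                sd_pct=float(svals.std(ddof=1) / ref * 100.0),
                reference=ref,
                n_dropped=dropped,
            )
        )

    steps = np.array([res.step_um for res in results])
    operating = results[int(np.argmin(np.abs(steps - operating_step_um)))]
    return results, operating.sd_pct


def shot_count_ratio(step_from_um: float, step_to_um: float) -> float:
    """Shot-count (hence acquisition-time) ratio when the step changes over a
    fixed area: (step_to / step_from)²."""
    if step_from_um <= 0 or step_to_um <= 0:
        raise ValueError("steps must be positive")
    return (step_to_um / step_from_um) ** 2
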