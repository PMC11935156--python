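"""Phosphorus-based tissue mask and its threshold sensitivity.

Phosphorus is abundant in tissue but essentially absent from the embedding
paraffin, so thresholding the P element map at the noise LoD segments tissue
from background.  The masked area A_tissue (cm²) is the normalization of the
Svalue metric; its sensitivity to the σ-multiplier of the threshold is one
component (σ_surf) of the total uncertainty budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spectral import ElementMap
from .thresholds import NoiseStats, Thresholds


@dataclass
class TissueMask:
    """Boolean tissue map plus the threshold and pixel pitch that made it."""

    mask: np.ndarray
    threshold: float
    step: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def n_tissue(self) -> int:
        return int(self.mask.sum())

    @property
    def area_cm2(self) -> float:
        """Tissue area: true-pixel count × (step in cm)²."""
        return self.n_tissue * (self.step * 1e-4) ** 2


def build_tissue_mask(
    p_map: ElementMap,
    thresholds: Thresholds,
    closing_radius: int = 0,
) -> TissueMask:
    """Classify pixels as tissue where the P intensity exceeds the LoD.

    The comparison is strict (``>``): a value exactly at the LoD is
    indistinguishable from noise and is excluded.  No morphological cleanup
    is applied by default — lung tissue is genuinely porous — but a binary
    closing of the given radius can be requested.
    """
    if p_map.element != "P":
        raise ValueError(f"tissue mask requires a P map, got {p_map.element!r}")
    mask = p_map.values > thresholds.lod
    if closing_radius > 0:
        from skimage.morphology import binary_closing, disk

        mask = binary_closing(mask, disk(closing_radius))
    if not mask.any():
        warnings.warn("tissue mask is empty (no P pixel above LoD)", stacklevel=2)
    return TissueMask(mask=mask, threshold=thresholds.lod, step=p_map.step)


@dataclass
class MaskSensitivity:
    """Tissue-area deviation as the LoD σ-multiplier is varied."""

    table: pd.DataFrame  # columns: k, threshold, area_cm2, deviation_pct
    k_ref: float
    sigma_surf_pct: float  # max deviation over the non-reference k values


def mask_threshold_sensitivity(
    p_map: ElementMap,
    stats: NoiseStats,
    k_values: Sequence[float] = (2.0, 3.0, 4.0),
    k_ref: float = 3.0,
) -> MaskSensitivity:
    """Relative tissue-area deviation |A(k) − A(k_ref)| / A(k_ref).

    The summary value σ_surf is the maximum deviation over the non-reference
    multipliers (default 2σ and 4σ around the 3σ reference), in percent — a
    conservative single-number reading of the threshold sensitivity.
    """
    thr_ref = stats.mean + k_ref * stats.sigma
    area_ref = float((p_map.values > thr_ref).sum()) * (p_map.step * 1e-4) ** 2
    if area_ref == 0:
        raise ValueError("reference tissue area is zero; cannot normalize deviations")
    rows = []
    for k in k_values:
        thr = stats.mean + k * stats.sigma
        area = float((p_map.values > thr).sum()) * (p_map.step * 1e-4) ** 2
        rows.append(
            {
                "k": float(k),
                "threshold": thr,
                "area_cm2": area,
                "deviation_pct": abs(area - area_ref) / area_ref * 100.0,
            }
        )
    table = pd.DataFrame(rows)
    off_ref = table.loc[table["k"] != float(k_ref), "deviation_pct"]
    sigma_surf = float(off_ref.max()) if len(off_ref) else 0.0
    return MaskSensitivity(table=table, k_ref=float(k_ref), sigma_surf_pct=sigma_surf)
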