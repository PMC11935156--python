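"""Quadrature uncertainty budget for the Svalue.

Four relative uncertainty components — lateral resolution (σ_Δx), tissue
thresholding (σ_surf), signal thresholding (σ_ΣI) and the calibration
confidence band at the median concentration (σ_CC) — are treated as
independent and combined in quadrature:

    σ_tot = √(σ_Δx² + σ_surf² + σ_ΣI² + σ_CC²)

All components are in percent.  No intermediate rounding is applied; the
report rounds the total to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ErrorBudget:
    sigma_dx: float
    sigma_surf: float
    sigma_sum_i: float
    sigma_cc: float
    sigma_tot: float
    provenance: dict = field(default_factory=dict)

    def as_report(self) -> dict:
        return {
            "sigma_dx_pct": self.sigma_dx,
            "sigma_surf_pct": self.sigma_surf,
            "sigma_sum_i_pct": self.sigma_sum_i,
            "sigma_cc_pct": self.sigma_cc,
            "sigma_tot_pct": round(self.sigma_tot, 1),
            "provenance": dict(self.provenance),
        }


def total_uncertainty(
    sigma_dx: float,
    sigma_surf: float,
    sigma_sum_i: float,
    sigma_cc: float,
    provenance: dict | None = None,
) -> ErrorBudget:
    """Combine the four percent-scale components into σ_tot by quadrature."""
    comps = (sigma_dx, sigma_surf, sigma_sum_i, sigma_cc)
    if any(c < 0 for c in comps):
        raise ValueError("uncertainty components must be non-negative")
    total = float(np.sqrt(sum(c * c for c in comps)))
    return ErrorBudget(
        sigma_dx=sigma_dx,
        sigma_surf=sigma_surf,
        sigma_sum_i=sigma_sum_i,
        sigma_cc=sigma_cc,
        sigma_tot=total,
        provenance=provenance or {},
    )
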