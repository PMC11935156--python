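"""End-to-end driver: extract → noise/thresholds → mask → Svalue → calibrate.

The pipeline reproduces the automated per-sample workflow: build P and
analyte maps from each cube, characterize noise in the line-free window
(two-pass by default: a provisional all-pixel noise fit yields a provisional
tissue mask, then the fit is repeated on tissue spectra only), derive LoD and
LoQ, build the tissue mask, compute the Svalue and the two threshold
sensitivities, and — when a calibration table or model is supplied — fit the
calibration line and invert it for each sample.  Every quantity needed to
recompute the Svalue by hand (ΣI, A_tissue, thresholds) lands in the JSON
report, and identical config + seed reproduce all numbers exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import calibration as cal
from .io import (
    RunConfig,
    dump_config,
    read_calibration_csv,
    read_cube,
    write_element_map,
    write_mask_tiff,
)
from .mask import TissueMask, build_tissue_mask, mask_threshold_sensitivity
from .spectral import ElementMap, SpectralCube, build_element_map
from .svalue import SValueResult, compute_svalue, signal_threshold_sensitivity
from .thresholds import NoiseStats, Thresholds, compute_thresholds, fit_noise, sample_noise

log = logging.getLogger("libsquant")


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage and sample id."""

    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r}, sample {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample
        self.cause = cause


@dataclass
class SampleAnalysis:
    """All per-sample intermediates, for callers that want more than JSON."""

    sample_id: str
    p_map: ElementMap
    analyte_map: ElementMap
    noise: NoiseStats
    thresholds: Thresholds
    mask: TissueMask
    svalue: SValueResult
    sigma_surf_pct: float | None = None
    sigma_sum_pct: float | None = None


def _fit_noise_with_fallback(samples, method: str, window) -> NoiseStats:
    try:
        return fit_noise(samples, method=method, window=window)  # type: ignore[arg-type]
    except (ValueError, RuntimeError) as exc:
        if method != "moments":
            log.warning("noise fit %r failed (%s); falling back to moments", method, exc)
            return fit_noise(samples, method="moments", window=window)
        raise


def analyze_cube(cube: SpectralCube, config: RunConfig, sample_id: str = "sample") -> SampleAnalysis:
    """Run the per-sample chain on an in-memory cube."""
    p_line = config.line_for(config.tissue_element)
    a_line = config.line_for(config.analyte)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise StageError(name, sample_id, exc) from exc

    p_map = stage(
        "extract",
        lambda: build_element_map(cube, p_line, config.method_for(config.tissue_element)),
    )
    a_map = stage(
        "extract",
        lambda: build_element_map(cube, a_line, config.method_for(config.analyte)),
    )

    window = tuple(config.noise.window_nm)

    def run_noise() -> NoiseStats:
        samples = sample_noise(cube, window, line_template=a_line)
        stats = _fit_noise_with_fallback(samples, config.noise.method, window)
        if config.noise.two_pass:
            provisional = build_tissue_mask(
                p_map, compute_thresholds(stats, config.thresholds.k_lod, config.thresholds.k_loq)
            )
            if provisional.mask.any():
                samples = sample_noise(
                    cube, window, restrict_to=provisional.mask, line_template=a_line
                )
                stats = _fit_noise_with_fallback(samples, config.noise.method, window)
        return stats

    noise = stage("noise", run_noise)
    thresholds = stage(
        "thresholds",
        lambda: compute_thresholds(noise, config.thresholds.k_lod, config.thresholds.k_loq),
    )
    mask = stage("mask", lambda: build_tissue_mask(p_map, thresholds))
    sval = stage("svalue", lambda: compute_svalue(a_map, mask, thresholds))

    sigma_surf = sigma_sum = None
    if config.run_sensitivity:
        try:
            sigma_surf = mask_threshold_sensitivity(p_map, noise).sigma_surf_pct
        except ValueError as exc:
            log.warning("%s: mask sensitivity skipped (%s)", sample_id, exc)
        try:
            sigma_sum = signal_threshold_sensitivity(a_map, mask, noise).sigma_sum_pct
        except ValueError as exc:
            log.warning("%s: signal sensitivity skipped (%s)", sample_id, exc)

    return SampleAnalysis(
        sample_id=sample_id,
        p_map=p_map,
        analyte_map=a_map,
        noise=noise,
        thresholds=thresholds,
        mask=mask,
        svalue=sval,
        sigma_surf_pct=sigma_surf,
        sigma_sum_pct=sigma_sum,
    )


def _sample_report(a: SampleAnalysis, k_loq: float) -> dict:
    return {
        "sample_id": a.sample_id,
        "element": a.svalue.element,
        "svalue_counts_per_cm2": a.svalue.svalue,
        "sum_intensity": a.svalue.sum_intensity,
        "area_cm2": a.svalue.area_cm2,
        "n_tissue": a.svalue.n_tissue,
        "n_positive": a.svalue.n_positive,
        "loq": a.svalue.loq_used,
        "k_loq": k_loq,
        "noise": {
            "mean": a.noise.mean,
            "sigma": a.noise.sigma,
            "n": a.noise.n,
            "window_nm": list(a.noise.window),
            "method": a.noise.method,
        },
        "thresholds": {"lod": a.thresholds.lod, "loq": a.thresholds.loq},
        "sigma_surf_pct": a.sigma_surf_pct,
        "sigma_sum_i_pct": a.sigma_sum_pct,
    }


def run_pipeline(config: RunConfig, model: cal.CalibrationModel | None = None) -> dict:
    """Execute the full workflow described by ``config`` and return the report.

    When ``config.outdir`` is set, element maps (TIFF + CSV), the tissue
    mask, the resolved config and the JSON report are written there.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        dump_config(config, outdir / "resolved_config.yaml")

    analyses: list[SampleAnalysis] = []
    for path in config.cube_paths():
        sample_id = Path(path).stem
        cube = read_cube(path)
        a = analyze_cube(cube, config, sample_id)
        analyses.append(a)
        if outdir:
            write_element_map(outdir / f"{sample_id}_{config.tissue_element}", a.p_map)
            write_element_map(outdir / f"{sample_id}_{config.analyte}", a.analyte_map)
            write_mask_tiff(outdir / f"{sample_id}_mask.tiff", a.mask.mask)

    report: dict = {
        "samples": [_sample_report(a, config.thresholds.k_loq) for a in analyses],
        "seed": config.seed,
    }

    if config.calibration_csv:
        df = read_calibration_csv(config.calibration_csv)
        points = cal.points_from_frame(df)
        model = cal.fit_calibration(
            points, level=config.calibration.level, weighted=config.calibration.weighted
        )
        report["calibration"] = {
            "slope": model.m,
            "intercept": model.b,
            "sigma_fit": model.sigma_fit,
            "r2": model.r2,
            "n": model.n,
            "level": model.level,
            "lod_ug_g": model.lod_conc,
            "loq_ug_g": model.loq_conc,
            "origin_in_intercept_ci": model.origin_in_intercept_ci,
            "sigma_cc_pct": cal.sigma_cc(model, points),
        }

    if model is not None:
        for entry, a in zip(report["samples"], analyses):
            pred = cal.predict_concentration(model, a.svalue.svalue)
            entry["predicted_concentration_ug_g"] = pred.concentration
            entry["predicted_sd_ug_g"] = pred.sd
            entry["prediction_flags"] = list(pred.flags)

    if outdir:
        with open(outdir / "report.json", "w") as f:
            json.dump(report, f, indent=2)
    return report
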