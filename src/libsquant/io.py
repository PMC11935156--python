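"""File formats and run configuration.

The cube container is plain HDF5: dataset ``wavelengths`` (nm), dataset
``intensity`` (ny × nx × nλ counts), root attribute ``step_um`` and an
optional ``meta`` attribute holding a JSON string.  Element maps are
exported both as float TIFF and CSV; reports are pretty-printed JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .spectral import ElementMap, EmissionLine, SpectralCube


class FormatError(ValueError):
    """A file does not conform to the expected container layout."""


def write_cube(path: str | Path, cube: SpectralCube) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("wavelengths", data=cube.wavelengths)
        f.create_dataset("intensity", data=cube.intensities)
        f.attrs["step_um"] = float(cube.step)
        if cube.meta:
            f.attrs["meta"] = json.dumps(cube.meta)


def read_cube(path: str | Path) -> SpectralCube:
    """Load and validate a cube container; errors name the missing field."""
    with h5py.File(path, "r") as f:
        for name in ("wavelengths", "intensity"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset {name!r}")
        if "step_um" not in f.attrs:
            raise FormatError(f"{path}: missing attribute 'step_um'")
        wavelengths = f["wavelengths"][()]
        intensities = f["intensity"][()]
        step = float(f.attrs["step_um"])
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
    if not np.all(np.diff(wavelengths) > 0):
        raise FormatError(f"{path}: wavelengths are not strictly ascending")
    try:
        return SpectralCube(wavelengths, intensities, step, meta)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_element_map(stem: str | Path, emap: ElementMap) -> None:
    """Export one map as float32 TIFF plus CSV next to each other."""
    import tifffile

    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".tiff"), emap.values.astype(np.float32))
    pd.DataFrame(emap.values).to_csv(stem.with_suffix(".csv"), header=False, index=False)


def write_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


class LineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    element: str
    center_nm: float
    fit_window_nm: float = 0.3
    baseline_nm: tuple[float, float] = (0.35, 0.95)  # flank offsets from center
    method: str | None = None  # per-line override of the global extraction method

    def to_line(self) -> EmissionLine:
        lo, hi = self.baseline_nm
        return EmissionLine(
            self.element,
            self.center_nm,
            fit_window=self.fit_window_nm,
            baseline_windows=(
                (self.center_nm - hi, self.center_nm - lo),
                (self.center_nm + lo, self.center_nm + hi),
            ),
        )


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_nm: tuple[float, float] = (320.0, 322.0)
    method: str = "histogram_gauss"
    two_pass: bool = True  # refine on a provisional tissue mask


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_lod: float = 3.0
    k_loq: float = 10.0


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    level: float = 0.70
    weighted: bool = False


class DegradationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    factors: list[int] = Field(default_factory=lambda: [2, 3, 4, 5, 10])
    reps: int = 100
    operating_step_um: float = 50.0


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    cube: str | None = None
    cubes: list[str] = Field(default_factory=list)
    calibration_csv: str | None = None
    outdir: str | None = None
    lines: list[LineConfig] = Field(
        default_factory=lambda: [
            LineConfig(element="P", center_nm=253.56),
            LineConfig(element="Ti", center_nm=323.65),
        ]
    )
    analyte: str = "Ti"
    tissue_element: str = "P"
    method: str = "sum"
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    degradation: DegradationConfig = Field(default_factory=DegradationConfig)
    run_sensitivity: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def line_for(self, element: str) -> EmissionLine:
        for lc in self.lines:
            if lc.element == element:
                return lc.to_line()
        raise KeyError(f"no line configured for element {element!r}")

    def method_for(self, element: str) -> str:
        for lc in self.lines:
            if lc.element == element and lc.method:
                return lc.method
        return self.method

    def cube_paths(self) -> list[str]:
        paths = list(self.cubes)
        if self.cube:
            paths.insert(0, self.cube)
        return paths


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig(**raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.model_dump(mode="json"), f, sort_keys=False)


def read_calibration_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "concentration_ug_g", "svalue_counts_cm2"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
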