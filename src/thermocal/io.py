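"""Domain types and file I/O for thermal-camera calibration data.

A TEC-less microbolometer reports a raw digital level (DL, counts) per
pixel, and the reading drifts with the temperature of the sensor itself
(TC, degrees Celsius).  Calibration therefore pairs each observation of a
blackbody reference at a known temperature (TBB) with both the mean digital
level of a region of interest on the blackbody and the sensor temperature
at acquisition time.

This module defines the shared containers — calibration records and
datasets, raw frames, calibrated temperature maps — and readers/writers
for the tabular (CSV) and raster (TIFF) formats the toolkit touches.
Frames travel as 16-bit single-channel TIFFs with a JSON sidecar carrying
``sensor_temperature_c``; calibrated maps are written as 32-bit float TIFFs
in degrees Celsius.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, MetadataError

#: Plausible blackbody/object temperature range (degrees C) used to validate
#: calibration records.
TBB_PLAUSIBLE_RANGE = (-20.0, 100.0)

CALIBRATION_COLUMNS = ("frame_id", "dl_mean", "sensor_temp_c", "blackbody_temp_c")

CAL_LABEL = "calibration"
VAL_LABEL = "validation"


@dataclass(frozen=True)
class CalibrationRecord:
    """One blackbody observation: (DL, TC) with reference truth TBB."""

    frame_id: str
    dl: float  # mean digital level of the blackbody ROI (counts)
    tc: float  # sensor temperature (degrees C)
    tbb: float  # blackbody reference temperature (degrees C)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dl) and 0.0 <= self.dl <= 65535.0):
            raise ValueError(f"dl must be finite and in [0, 65535], got {self.dl}")
        if not math.isfinite(self.tc):
            raise ValueError(f"tc must be finite, got {self.tc}")
        lo, hi = TBB_PLAUSIBLE_RANGE
        if not (math.isfinite(self.tbb) and lo <= self.tbb <= hi):
            raise ValueError(
                f"tbb must be finite and within the plausible range {TBB_PLAUSIBLE_RANGE}, "
                f"got {self.tbb}"
            )


@dataclass(frozen=True)
class CalibrationDataset:
    """An ordered collection of calibration records, optionally split.

    ``split_labels``, when present, assigns every record to either the
    calibration or the validation subset.
    """

    records: tuple[CalibrationRecord, ...]
    split_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.split_labels is not None:
            labels = tuple(self.split_labels)
            object.__setattr__(self, "split_labels", labels)
            if len(labels) != len(self.records):
                raise ValueError("split_labels must cover all records")
            bad = set(labels) - {CAL_LABEL, VAL_LABEL}
            if bad:
                raise ValueError(f"unknown split labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def dl(self) -> np.ndarray:
        return np.array([r.dl for r in self.records], dtype=float)

    @property
    def tc(self) -> np.ndarray:
        return np.array([r.tc for r in self.records], dtype=float)

    @property
    def tbb(self) -> np.ndarray:
        return np.array([r.tbb for r in self.records], dtype=float)

    def subset(self, label: str) -> "CalibrationDataset":
        """Records carrying ``label`` ('calibration' or 'validation')."""
        if self.split_labels is None:
            raise ValueError("dataset has no split labels")
        recs = tuple(
            r for r, lab in zip(self.records, self.split_labels) if lab == label
        )
        return CalibrationDataset(recs)


@dataclass(frozen=True)
class ThermalFrame:
    """A raw thermal image: digital levels plus the sensor temperature."""

    pixels: np.ndarray  # 2-D, values in [0, 65535], 16-bit container
    sensor_temp: float  # degrees C
    frame_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("pixels must be a 2-D array of at least 2x2")
        if px.min() < 0 or px.max() > 65535:
            raise ValueError("pixel values must lie in [0, 65535]")
        object.__setattr__(self, "pixels", px.astype(np.uint16, copy=False))
        if not math.isfinite(self.sensor_temp):
            raise ValueError("sensor_temp must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class TemperatureMap:
    """A calibrated per-pixel temperature image (degrees C)."""

    temps: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temps, dtype=np.float64)
        if t.ndim != 2:
            raise ValueError("temps must be 2-D")
        if not np.all(np.isfinite(t)):
            raise ValueError("all temperatures must be finite")
        object.__setattr__(self, "temps", t)


@dataclass(frozen=True)
class RoiSelection:
    """A rectangular region of interest, 0-based and half-open."""

    rmin: int
    rmax: int
    cmin: int
    cmax: int

    def __post_init__(self) -> None:
        if self.rmin < 0 or self.cmin < 0:
            raise ValueError("ROI bounds must be non-negative")
        if self.rmax <= self.rmin or self.cmax <= self.cmin:
            raise ValueError("ROI must be non-empty (half-open bounds)")


# ---------------------------------------------------------------------------
# Tabular I/O


def read_calibration_csv(path: str | Path) -> CalibrationDataset:
    """Read a calibration CSV (frame_id, dl_mean, sensor_temp_c, blackbody_temp_c).

    Extra columns are ignored; row order is preserved.  Raises
    :class:`FormatError` naming the missing column, or a parse error with the
    offending row number for non-numeric cells.
    """
    df = pd.read_csv(path, dtype=str)
    for col in CALIBRATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"calibration CSV is missing required column {col!r}")
    records = []
    for i, row in df.iterrows():
        vals = {}
        for col in CALIBRATION_COLUMNS[1:]:
            try:
                vals[col] = float(row[col])
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric value {row[col]!r} in column {col!r} at data row {i + 1}"
                ) from None
        records.append(
            CalibrationRecord(
                frame_id=str(row["frame_id"]),
                dl=vals["dl_mean"],
                tc=vals["sensor_temp_c"],
                tbb=vals["blackbody_temp_c"],
            )
        )
    return CalibrationDataset(tuple(records))


def write_calibration_csv(dataset: CalibrationDataset, path: str | Path) -> None:
    """Write a dataset in the schema read_calibration_csv understands."""
    df = pd.DataFrame(
        {
            "frame_id": [r.frame_id for r in dataset.records],
            "dl_mean": [r.dl for r in dataset.records],
            "sensor_temp_c": [r.tc for r in dataset.records],
            "blackbody_temp_c": [r.tbb for r in dataset.records],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Raster I/O


def read_thermal_frame(image_path: str | Path, sidecar_path: str | Path) -> ThermalFrame:
    """Read a raw frame: single-channel 8/16-bit TIFF plus a JSON sidecar.

    The sidecar must contain the key ``sensor_temperature_c``.  8-bit pixels
    are widened to the 16-bit container with values unchanged.
    """
    px = tifffile.imread(str(image_path))
    if px.ndim != 2:
        raise FormatError(
            f"{image_path}: expected a single-channel image, got shape {px.shape}"
        )
    if px.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"{image_path}: expected 8- or 16-bit pixels, got {px.dtype}")
    try:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise MetadataError(f"{sidecar_path}: invalid sidecar JSON: {exc}") from exc
    if not isinstance(meta, dict) or "sensor_temperature_c" not in meta:
        raise MetadataError(f"{sidecar_path}: sidecar lacks key 'sensor_temperature_c'")
    return ThermalFrame(
        pixels=px.astype(np.uint16),
        sensor_temp=float(meta["sensor_temperature_c"]),
        frame_id=Path(image_path).stem,
    )


def write_thermal_frame(
    frame: ThermalFrame, image_path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """Write a frame as 16-bit TIFF plus (optionally) its JSON sidecar."""
    tifffile.imwrite(str(image_path), frame.pixels)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"sensor_temperature_c": frame.sensor_temp}, fh)


def extract_roi_mean(frame: ThermalFrame, roi: RoiSelection) -> float:
    """Arithmetic mean of the digital levels inside the half-open ROI.

    This is the per-frame "DL" of a blackbody observation: the user selects
    a representative area of the blackbody target and the mean count inside
    it becomes the digital response paired with the setpoint temperature.
    """
    h, w = frame.shape
    if roi.rmax > h or roi.cmax > w:
        raise ValueError(f"ROI {roi} exceeds frame bounds {frame.shape}")
    block = frame.pixels[roi.rmin : roi.rmax, roi.cmin : roi.cmax]
    return float(block.astype(np.float64).mean())


def write_temperature_map(tmap: TemperatureMap, path: str | Path) -> None:
    """Write a calibrated map as 32-bit float single-channel TIFF (degrees C)."""
    tifffile.imwrite(str(path), tmap.temps.astype(np.float32))


def read_temperature_map(path: str | Path, provenance: str = "") -> TemperatureMap:
    """Read back a 32-bit float temperature TIFF."""
    t = tifffile.imread(str(path))
    if t.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel image, got shape {t.shape}")
    return TemperatureMap(temps=np.asarray(t, dtype=np.float64), provenance=provenance)
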