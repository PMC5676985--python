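"""Ground-control-point accuracy summaries and field validation statistics.

Positional accuracy of a photogrammetric block is summarized from the
signed per-GCP coordinate errors (estimated minus surveyed, meters).  The
per-axis figure is the root mean square over control points, and the 3-D
total error is

    total = sqrt( mean_i [ ex_i^2 + ey_i^2 + ez_i^2 ] ),

which decomposes exactly as total^2 = rms_x^2 + rms_y^2 + rms_z^2.

``validation_compare`` handles the vicarious-calibration side: paired
reference (field) vs product (orthoimage) temperatures per sample point,
reduced to RMSE, bias, the sample SD of the differences, and a full
agreement report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import FitReport, fit_report
from .errors import FormatError

GCP_COLUMNS = ("gcp_id", "error_x_m", "error_y_m", "error_z_m")
VALIDATION_COLUMNS = ("label", "surface", "ref_mean_c", "ref_sd_c", "prod_mean_c", "prod_sd_c")


def read_gcp_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-GCP error table (gcp_id, error_x_m, error_y_m, error_z_m[, image_residual_px])."""
    df = pd.read_csv(path)
    for col in GCP_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"GCP CSV is missing required column {col!r}")
    return df


def read_validation_csv(path: str | Path) -> pd.DataFrame:
    """Read a field-vs-product temperature pair table."""
    df = pd.read_csv(path)
    for col in VALIDATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"validation CSV is missing required column {col!r}")
    return df


def per_gcp_total(error_x: float, error_y: float, error_z: float) -> float:
    """Euclidean norm of one control point's axis errors (meters)."""
    e = np.asarray([error_x, error_y, error_z], dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("errors must be finite")
    return float(np.sqrt((e**2).sum()))


@dataclass(frozen=True)
class GcpSummary:
    """Per-axis RMS and 3-D total positioning error over a control-point set."""

    rms_x: float
    rms_y: float
    rms_z: float
    total_3d: float
    per_gcp: np.ndarray  # per-point 3-D error (m)
    n: int

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "rms_x": self.rms_x,
            "rms_y": self.rms_y,
            "rms_z": self.rms_z,
            "total_3d": self.total_3d,
        }


def gcp_summary(table: pd.DataFrame) -> GcpSummary:
    """RMS per axis and the 3-D total error over all control points."""
    if len(table) == 0:
        raise ValueError("empty GCP table")
    ex = table["error_x_m"].to_numpy(dtype=float)
    ey = table["error_y_m"].to_numpy(dtype=float)
    ez = table["error_z_m"].to_numpy(dtype=float)
    if not np.all(np.isfinite(np.concatenate([ex, ey, ez]))):
        raise ValueError("errors must be finite")
    per = np.sqrt(ex**2 + ey**2 + ez**2)
    return GcpSummary(
        rms_x=float(np.sqrt(np.mean(ex**2))),
        rms_y=float(np.sqrt(np.mean(ey**2))),
        rms_z=float(np.sqrt(np.mean(ez**2))),
        total_3d=float(np.sqrt(np.mean(per**2))),
        per_gcp=per,
        n=len(table),
    )


@dataclass(frozen=True)
class ValidationStats:
    """Paired statistics of product vs reference temperatures."""

    rmse: float  # degrees C
    max_abs_diff: float
    sd_diff: float  # sample SD (n-1) of the paired differences
    mean_bias: float  # mean(product - reference)
    report: FitReport

    def as_dict(self) -> dict:
        d = {
            "rmse": self.rmse,
            "max_abs_diff": self.max_abs_diff,
            "sd_diff": self.sd_diff,
            "mean_bias": self.mean_bias,
        }
        d["agreement"] = self.report.as_dict()
        return d


def validation_compare(table: pd.DataFrame) -> ValidationStats:
    """Compare product temperature means against field reference means.

    The reference column plays the role of the observed series and the
    product column the simulated one in the embedded agreement report.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 validation rows")
    ref = table["ref_mean_c"].to_numpy(dtype=float)
    prod = table["prod_mean_c"].to_numpy(dtype=float)
    diff = prod - ref
    return ValidationStats(
        rmse=float(np.sqrt(np.mean(diff**2))),
        max_abs_diff=float(np.max(np.abs(diff))),
        sd_diff=float(np.std(diff, ddof=1)),
        mean_bias=float(np.mean(diff)),
        report=fit_report(ref, prod),
    )
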