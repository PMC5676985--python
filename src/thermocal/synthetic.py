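"""Synthetic data generators emulating a TEC-less thermal survey.

Three generators cover the toolkit's inputs end to end:

* :func:`simulate_blackbody_campaign` — a laboratory calibration campaign.
  The forward model for the mean digital level of the blackbody ROI is

      DL = offset + k1 * (TBB + 273.15)^4 * 1e-8
                  + k2 * (TC - t0) + k3 * (TC - t0)^2 + N(0, noise_sd),

  a fourth-power radiance proxy for the long-wave band plus a quadratic
  sensor-temperature drift — the nonlinearity that motivates calibrating
  with both DL and TC.  Default gains put counts in a 14-bit-like band
  (~5300-9900) with a mid-range sensitivity near 70 counts per degree, so
  the default noise of 35 counts corresponds to roughly 0.5 degC.

* :func:`simulate_scene_pair` — two overlapping low-contrast frames of the
  same scene (smooth thermal field + sparse texture blobs + optical
  vignetting + per-frame noise), translated by a known integer offset.

* :func:`simulate_gcp_table` — zero-mean Gaussian per-axis GCP errors.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CalibrationDataset, CalibrationRecord, ThermalFrame

#: Blackbody setpoints: 5..65 degC in 5-degree steps (13 levels).
DEFAULT_TBB_SETPOINTS = tuple(float(t) for t in range(5, 66, 5))

#: Sensor temperatures spanning 5-31 degC, sampled more densely above 20
#: (cold-room acquisitions are harder to run, so real campaigns are sparser
#: there).
DEFAULT_TC_VALUES = (
    5.0, 7.0, 9.0, 11.0, 13.0, 15.0, 17.0, 19.0,
    20.5, 21.5, 22.5, 23.5, 24.5, 25.5, 26.5, 27.5, 28.5, 29.5, 30.5, 31.0,
)


@dataclass(frozen=True)
class SensorSimConfig:
    """Forward model of the synthetic TEC-less sensor."""

    k1: float = 60.0  # counts per 1e-8 * K^4 radiance unit
    k2: float = -15.0  # linear sensor-temperature drift (counts/degC)
    k3: float = -0.8  # quadratic drift (counts/degC^2)
    offset: float = 2000.0  # counts
    noise_sd: float = 35.0  # counts (~0.5 degC at mid-range sensitivity)
    t0: float = 20.0  # reference sensor temperature (degC)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _clean_dl(cfg: SensorSimConfig, tbb: np.ndarray, tc: np.ndarray) -> np.ndarray:
    dt = tc - cfg.t0
    return (
        cfg.offset
        + cfg.k1 * (tbb + 273.15) ** 4 * 1e-8
        + cfg.k2 * dt
        + cfg.k3 * dt**2
    )


def simulate_blackbody_campaign(
    config: SensorSimConfig | None = None,
    tbb_setpoints: Sequence[float] | None = None,
    tc_values: Sequence[float] | None = None,
) -> CalibrationDataset:
    """Generate one record per (setpoint, sensor temperature) combination.

    Raises a configuration error if the noise-free counts overflow the
    16-bit container at the given gains.  Deterministic given the seed.
    """
    cfg = config or SensorSimConfig()
    tbbs = np.asarray(tbb_setpoints if tbb_setpoints is not None else DEFAULT_TBB_SETPOINTS, float)
    tcs = np.asarray(tc_values if tc_values is not None else DEFAULT_TC_VALUES, float)
    if len(tbbs) == 0 or len(tcs) == 0:
        raise ValueError("setpoint and sensor-temperature lists must be non-empty")
    tbb_grid, tc_grid = [a.ravel() for a in np.meshgrid(tbbs, tcs, indexing="ij")]
    clean = _clean_dl(cfg, tbb_grid, tc_grid)
    if clean.min() < 0 or clean.max() > 65535:
        raise ValueError(
            f"forward model overflows the 16-bit container "
            f"(counts span {clean.min():.0f}..{clean.max():.0f}); adjust gains"
        )
    rng = np.random.default_rng(cfg.seed)
    dl = np.clip(clean + rng.normal(0.0, cfg.noise_sd, clean.shape), 0, 65535)
    records = tuple(
        CalibrationRecord(frame_id=f"bb_{i:04d}", dl=float(d), tc=float(c), tbb=float(b))
        for i, (d, c, b) in enumerate(zip(dl, tc_grid, tbb_grid))
    )
    return CalibrationDataset(records)


@dataclass(frozen=True)
class SceneSimConfig:
    """Configuration of the low-contrast overlapping scene generator.

    Texture blobs carry heavy-tailed (Pareto) peak amplitudes: a handful of
    strong features dominate the stretched working image while most sit a
    small factor above the noise floor — the regime where an adaptive
    contrast filter reveals features that a global stretch leaves below the
    detector's relative threshold.
    """

    size: tuple[int, int] = (256, 256)  # rows, cols
    smooth_amplitude: float = 3.0  # SD of the large-scale thermal field (counts)
    smooth_scale: float = 60.0  # Gaussian correlation length (pixels)
    texture_amplitude: float = 60.0  # Pareto scale of blob peak heights (counts)
    n_blobs: int = 80
    vignetting: float = 40.0  # corner falloff (counts)
    translation: tuple[int, int] = (4, -3)  # (rows, cols) offset of frame B
    noise_sd: float = 1.0  # per-frame read noise (counts)
    base_counts: float = 7000.0  # scene mean digital level
    sensor_temp: float = 25.0  # degC, carried on the frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smooth_amplitude < 0 or self.texture_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        dy, dx = self.translation
        h, w = self.size
        if abs(dy) >= h or abs(dx) >= w:
            raise ValueError("translation must be smaller than the image size")


def simulate_scene_pair(
    config: SceneSimConfig | None = None,
) -> tuple[ThermalFrame, ThermalFrame, tuple[int, int]]:
    """Generate two overlapping frames and the true (rows, cols) offset.

    The scene content at (r, c) in frame A appears at (r + dy, c + dx) in
    frame B, where (dy, dx) is the configured translation.
    The vignetting pattern is fixed in frame coordinates (it belongs to the
    optics, not the scene) and each frame gets fresh read noise.
    """
    cfg = config or SceneSimConfig()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.size
    dy, dx = cfg.translation
    H, W = h + abs(dy), w + abs(dx)

    canvas = np.zeros((H, W))
    if cfg.smooth_amplitude > 0:
        smooth = ndimage.gaussian_filter(rng.standard_normal((H, W)), cfg.smooth_scale)
        sd = smooth.std()
        if sd > 0:
            canvas += smooth * (cfg.smooth_amplitude / sd)
    for _ in range(cfg.n_blobs):
        r = rng.uniform(0, H)
        c = rng.uniform(0, W)
        sig = rng.uniform(1.5, 3.5)
        amp = (
            cfg.texture_amplitude
            * min(rng.pareto(2.5), 10.0)
            * rng.choice([-1.0, 1.0])
        )
        r0, r1 = int(max(0, r - 4 * sig)), int(min(H, r + 4 * sig + 1))
        c0, c1 = int(max(0, c - 4 * sig)), int(min(W, c + 4 * sig + 1))
        rr, cc = np.mgrid[r0:r1, c0:c1]
        canvas[r0:r1, c0:c1] += amp * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sig**2)
        )

    oy, ox = max(dy, 0), max(dx, 0)
    view_a = canvas[oy : oy + h, ox : ox + w]
    view_b = canvas[oy - dy : oy - dy + h, ox - dx : ox - dx + w]

    rr, cc = np.mgrid[0:h, 0:w]
    r2 = ((rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2)
    vignette = -cfg.vignetting * r2 / r2.max()

    frames = []
    for tag, view in (("a", view_a), ("b", view_b)):
        px = cfg.base_counts + view + vignette
        px = px + rng.normal(0.0, cfg.noise_sd, view.shape)
        px = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
        frames.append(
            ThermalFrame(pixels=px, sensor_temp=cfg.sensor_temp, frame_id=f"scene_{cfg.seed}_{tag}")
        )
    return frames[0], frames[1], (dy, dx)


def simulate_gcp_table(
    n_points: int, axis_sds: tuple[float, float, float], seed: int = 0
) -> pd.DataFrame:
    """Zero-mean Gaussian per-axis GCP errors; deterministic given seed."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    sx, sy, sz = axis_sds
    if min(sx, sy, sz) < 0:
        raise ValueError("axis SDs must be >= 0")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "gcp_id": [f"gcp_{i + 1}" for i in range(n_points)],
            "error_x_m": rng.normal(0, sx, n_points),
            "error_y_m": rng.normal(0, sy, n_points),
            "error_z_m": rng.normal(0, sz, n_points),
        }
    )
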