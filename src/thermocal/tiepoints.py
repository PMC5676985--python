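"""Harris corner detection and NCC matching: a tie-point surrogate.

Production photogrammetry suites use proprietary detectors/matchers, so
the effect of contrast filtering on tie-point extraction is measured here
with a transparent stand-in: Harris corner response (structure tensor
smoothed with a Gaussian window, response = det - k*trace^2), 3x3
non-maximum suppression, and mutual-best normalized cross-correlation of
image patches.  Counts are comparable across pipelines run with identical
settings — the interesting quantity is the relative gain from filtering,
not the absolute number of matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import ThermalFrame
from .wallis import WallisParams, percentile_stretch, wallis


@dataclass(frozen=True)
class KeypointSet:
    """Detected interest points for one image, strongest first."""

    rows: np.ndarray
    cols: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.rows)


def harris_response(
    image: np.ndarray, sigma: float = 1.5, k: float = 0.05
) -> np.ndarray:
    """Harris corner response map.

    Gradients by central differences; structure-tensor entries smoothed with
    a Gaussian of scale ``sigma``; response = det(M) - k * trace(M)^2.
    """
    img = np.asarray(image, dtype=np.float64)
    gy, gx = np.gradient(img)
    a = ndimage.gaussian_filter(gx * gx, sigma, mode="reflect")
    b = ndimage.gaussian_filter(gx * gy, sigma, mode="reflect")
    c = ndimage.gaussian_filter(gy * gy, sigma, mode="reflect")
    return a * c - b * b - k * (a + c) ** 2


def detect_keypoints(
    image: np.ndarray,
    threshold: float = 0.05,
    max_points: int = 500,
    sigma: float = 1.5,
    k: float = 0.05,
) -> KeypointSet:
    """Detect Harris corners with 3x3 non-maximum suppression.

    Keeps local maxima whose response is at least ``threshold`` times the
    global maximum response, capped at ``max_points`` by descending score
    (ties broken by row, then column).  Deterministic.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape[0] < 16 or img.shape[1] < 16:
        raise ValueError("image must be at least 16x16")
    resp = harris_response(img, sigma=sigma, k=k)
    rmax = resp.max()
    if rmax <= 0:
        return KeypointSet(np.empty(0, int), np.empty(0, int), np.empty(0))
    peak = ndimage.maximum_filter(resp, size=3, mode="reflect")
    mask = (resp >= peak) & (resp >= threshold * rmax)
    rows, cols = np.nonzero(mask)
    scores = resp[rows, cols]
    order = np.lexsort((cols, rows, -scores))[:max_points]
    return KeypointSet(rows[order], cols[order], scores[order])


def _patches(image: np.ndarray, kps: KeypointSet, patch: int):
    """Extract normalized (zero-mean, unit-norm) patch vectors; drops
    keypoints within half a patch of the border or with zero variance."""
    img = np.asarray(image, dtype=np.float64)
    half = patch // 2
    h, w = img.shape
    keep, vecs = [], []
    for i, (r, c) in enumerate(zip(kps.rows, kps.cols)):
        if r - half < 0 or r + half >= h or c - half < 0 or c + half >= w:
            continue
        p = img[r - half : r + half + 1, c - half : c + half + 1].ravel()
        p = p - p.mean()
        norm = np.linalg.norm(p)
        if norm == 0:
            continue
        keep.append(i)
        vecs.append(p / norm)
    if not keep:
        return np.empty(0, int), np.empty((0, patch * patch))
    return np.array(keep), np.array(vecs)


def match_keypoints(
    image_a: np.ndarray,
    kps_a: KeypointSet,
    image_b: np.ndarray,
    kps_b: KeypointSet,
    patch: int = 11,
    min_ncc: float = 0.8,
) -> list[tuple[int, int, float]]:
    """Mutual-best NCC matching of centered patches.

    Returns (index_in_a, index_in_b, ncc) triples for pairs that are each
    other's best correlation and exceed ``min_ncc``.  Ties resolve to the
    first (smallest row, then column) candidate.
    """
    if patch % 2 == 0 or patch < 3:
        raise ValueError("patch must be odd and >= 3")
    if not 0.0 < min_ncc < 1.0:
        raise ValueError("min_ncc must be in (0, 1)")
    ia, va = _patches(image_a, kps_a, patch)
    ib, vb = _patches(image_b, kps_b, patch)
    if len(ia) == 0 or len(ib) == 0:
        return []
    # stable tie-breaking: order candidates by (row, col) so argmax picks
    # the smaller row-then-col point on exact NCC ties
    order_a = np.lexsort((kps_a.cols[ia], kps_a.rows[ia]))
    order_b = np.lexsort((kps_b.cols[ib], kps_b.rows[ib]))
    ia, va = ia[order_a], va[order_a]
    ib, vb = ib[order_b], vb[order_b]
    ncc = va @ vb.T
    best_b = np.argmax(ncc, axis=1)
    best_a = np.argmax(ncc, axis=0)
    matches = []
    for i, j in enumerate(best_b):
        if best_a[j] == i and ncc[i, j] >= min_ncc:
            matches.append((int(ia[i]), int(ib[j]), float(ncc[i, j])))
    return matches


def percent_increase(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after`` (100*(after-before)/before)."""
    if before == 0:
        raise ValueError("percent increase undefined for zero baseline")
    return 100.0 * (after - before) / before


@dataclass(frozen=True)
class MatchReport:
    """Per-pair and aggregate tie-point counts, filtered vs unfiltered."""

    pairs: list[dict]
    total_unfiltered: int
    total_filtered: int

    @property
    def percent_change(self) -> float:
        return percent_increase(self.total_unfiltered, self.total_filtered)

    def as_dict(self) -> dict:
        return {
            "pairs": self.pairs,
            "total_unfiltered": self.total_unfiltered,
            "total_filtered": self.total_filtered,
            "percent_change": self.percent_change,
        }


def compare_pipelines(
    pairs: Sequence[tuple[ThermalFrame, ThermalFrame]],
    wallis_params: WallisParams | None = None,
    threshold: float = 0.05,
    max_points: int = 500,
    patch: int = 11,
    min_ncc: float = 0.8,
) -> MatchReport:
    """Count accepted matches on raw-stretched vs Wallis-filtered pairs.

    Each overlapping frame pair is processed twice with identical detector
    and matcher settings: once on the percentile-stretched working images
    and once after Wallis filtering.  The report carries per-pair keypoint
    and match counts plus aggregate totals and the percent change.
    """
    if not pairs:
        raise ValueError("empty pair list")
    wallis_params = wallis_params or WallisParams()
    lo, hi = wallis_params.stretch_percentiles
    rows = []
    tot_u = tot_f = 0
    for idx, (fa, fb) in enumerate(pairs):
        wa, wb = percentile_stretch(fa, lo, hi), percentile_stretch(fb, lo, hi)
        ga, gb = wallis(wa, wallis_params), wallis(wb, wallis_params)
        entry = {"pair": idx}
        for tag, (img_a, img_b) in (("unfiltered", (wa, wb)), ("filtered", (ga, gb))):
            ka = detect_keypoints(img_a, threshold, max_points)
            kb = detect_keypoints(img_b, threshold, max_points)
            m = match_keypoints(img_a, ka, img_b, kb, patch, min_ncc)
            entry[f"{tag}_keypoints_a"] = len(ka)
            entry[f"{tag}_keypoints_b"] = len(kb)
            entry[f"{tag}_matches"] = len(m)
        tot_u += entry["unfiltered_matches"]
        tot_f += entry["filtered_matches"]
        rows.append(entry)
    return MatchReport(pairs=rows, total_unfiltered=tot_u, total_filtered=tot_f)
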