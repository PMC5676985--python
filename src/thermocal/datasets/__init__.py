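"""Bundled example data from a UAV thermal survey of a semi-arid vineyard.

Small CSV tables shipped with the package so the accuracy summaries can be
exercised on real survey numbers without any downloads:

* per-GCP positional errors of the photogrammetric block built from raw
  (unfiltered) images and from Wallis-filtered, geometrically calibrated
  images (eight surveyed control points each);
* paired field-vs-orthoimage canopy/soil temperatures at twenty sample
  points (rain-fed vines RV, vines irrigated the night before IV, vines
  irrigated seven days before 7d-IV, and bare soil), for both the camera's
  original configuration and the radiometrically corrected product;
* block-level structure-from-motion statistics (tie-point and projection
  counts, re-projection error) for the unfiltered and filtered pipelines.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_gcp_errors",
    "load_field_validation",
    "load_sfm_block_stats",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_gcp_errors(filtered: bool = False) -> pd.DataFrame:
    """Per-GCP error table (meters) for the unfiltered or filtered block."""
    return _read("gcp_errors_filtered.csv" if filtered else "gcp_errors_unfiltered.csv")


def load_field_validation(product: str = "corrected") -> pd.DataFrame:
    """Field reference vs orthoimage product temperature pairs.

    ``product`` selects which orthoimage column becomes ``prod_mean_c`` /
    ``prod_sd_c``: "corrected" (radiometrically calibrated) or "original"
    (manufacturer configuration).
    """
    df = _read("field_validation.csv")
    prefix = {"corrected": "corr", "original": "orig"}.get(product)
    if prefix is None:
        raise ValueError("product must be 'corrected' or 'original'")
    return pd.DataFrame(
        {
            "label": df["label"],
            "surface": df["surface"],
            "ref_mean_c": df["ref_mean_c"],
            "ref_sd_c": df["ref_sd_c"],
            "prod_mean_c": df[f"{prefix}_mean_c"],
            "prod_sd_c": df[f"{prefix}_sd_c"],
        }
    )


def load_sfm_block_stats() -> pd.DataFrame:
    """Block-level SfM statistics for the unfiltered vs filtered pipelines."""
    return _read("sfm_block_stats.csv")
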