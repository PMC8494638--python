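"""Scaled-depth normalization and binned density / soma-area profiling.

Scaled depth maps the L1/2 boundary to 0 and the L3/4 boundary to -1.  The
L2-3 band is split into ``n_bins`` (default 20) evenly sized bins; per-donor
densities are fractions of that donor's total count (summing to 1 over all
bins), and the reported cross-donor series drops the first and last bins,
which carry boundary effects.  Cells falling exactly on a bin edge go to the
deeper bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "scaled_depth",
    "bin_index",
    "bin_centers",
    "density_profile",
    "soma_area_profile",
    "find_nadir",
]

REQUIRED_COLUMNS = ["donor", "soma_depth_um", "soma_area_um2", "l12_um", "l34_um"]


def scaled_depth(soma_depth, l12, l34):
    """Scaled L2/3 depth in [-1, 0]: 0 at the L1/2 boundary, -1 at L3/4."""
    soma_depth = np.asarray(soma_depth, dtype=float)
    l12 = np.asarray(l12, dtype=float)
    l34 = np.asarray(l34, dtype=float)
    if np.any(l12 >= l34):
        raise ValueError("l12 boundary must be shallower than l34")
    if np.any((soma_depth < l12) | (soma_depth > l34)):
        raise ValueError("soma depth outside the [l12, l34] band")
    out = -(soma_depth - l12) / (l34 - l12)
    return float(out) if out.ndim == 0 else out


def bin_index(scaled, n_bins: int = 20) -> np.ndarray:
    """Bin index (0 = most superficial); edge cells go to the deeper bin.

    Bins are half-open and closed at their shallow edge, so a cell exactly on
    the boundary between bins k and k+1 lands in the deeper bin k+1.
    """
    u = -np.asarray(scaled, dtype=float)  # in [0, 1], increasing with depth
    idx = np.floor(u * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def bin_centers(n_bins: int = 20) -> np.ndarray:
    return -(np.arange(n_bins) + 0.5) / n_bins


@dataclass
class DepthProfile:
    per_donor: pd.DataFrame  # donors x bins (all n_bins columns)
    mean: pd.Series  # inner bins only
    sd: pd.Series  # inner bins only
    centers: np.ndarray  # all bin centers (scaled depth)


def _scaled_depths(table: pd.DataFrame) -> pd.Series:
    return pd.Series(
        scaled_depth(table["soma_depth_um"], table["l12_um"], table["l34_um"]),
        index=table.index,
    )


def density_profile(table: pd.DataFrame, n_bins: int = 20) -> DepthProfile:
    """Per-donor scaled density per bin plus the cross-donor inner-bin series."""
    if len(table) == 0:
        raise ValueError("empty histology table")
    sc = _scaled_depths(table)
    idx = pd.Series(bin_index(sc, n_bins), index=table.index)
    rows = {}
    for donor, sub in table.groupby("donor"):
        if len(sub) < n_bins:
            warnings.warn(f"donor {donor}: fewer cells than bins")
        counts = np.bincount(idx.loc[sub.index], minlength=n_bins).astype(float)
        rows[donor] = counts / counts.sum()
    per_donor = pd.DataFrame.from_dict(rows, orient="index")
    inner = per_donor.iloc[:, 1:-1]
    return DepthProfile(
        per_donor=per_donor,
        mean=inner.mean(axis=0),
        sd=inner.std(axis=0, ddof=1),
        centers=bin_centers(n_bins),
    )


def soma_area_profile(table: pd.DataFrame, n_bins: int = 20):
    """Per-bin soma-area mean and sd per donor, then cross-donor aggregate.

    Bin statistics are computed independently per donor and averaged across
    donors; the sd of an empty or singleton bin is missing (NaN), not 0.
    """
    if len(table) == 0:
        raise ValueError("empty histology table")
    sc = _scaled_depths(table)
    idx = pd.Series(bin_index(sc, n_bins), index=table.index)
    means, sds = {}, {}
    for donor, sub in table.groupby("donor"):
        m = np.full(n_bins, np.nan)
        s = np.full(n_bins, np.nan)
        sub_idx = idx.loc[sub.index].to_numpy()
        for b in range(n_bins):
            vals = sub["soma_area_um2"].to_numpy()[sub_idx == b]
            if len(vals) >= 1:
                m[b] = vals.mean()
            if len(vals) >= 2:
                s[b] = vals.std(ddof=1)
        means[donor] = m
        sds[donor] = s
    mean_df = pd.DataFrame.from_dict(means, orient="index")
    sd_df = pd.DataFrame.from_dict(sds, orient="index")
    return {
        "per_donor_mean": mean_df,
        "per_donor_sd": sd_df,
        "mean": mean_df.mean(axis=0),
        "sd": sd_df.mean(axis=0),
        "centers": bin_centers(n_bins),
    }


def find_nadir(
    mean_profile: pd.Series | np.ndarray,
    centers: np.ndarray,
    search_max_depth: float = -0.25,
    smooth_bins: int = 3,
    flat_tolerance: float = 1e-9,
) -> tuple[float, bool]:
    """Depth of the density minimum in the L3 interior.

    Applies a ``smooth_bins`` moving average, restricts the search to scaled
    depths below ``search_max_depth`` (avoiding the L2 edge), and returns the
    bin-center depth of the minimum together with a low-confidence flag that
    is set for flat or monotone (edge-minimum) profiles.
    """
    y = np.asarray(mean_profile, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if y.shape != centers.shape:
        raise ValueError("profile and centers must align")
    k = smooth_bins // 2
    smooth = np.array(
        [y[max(0, i - k) : i + k + 1].mean() for i in range(len(y))]
    )
    mask = centers < search_max_depth
    if not mask.any():
        raise ValueError("no bins below the search boundary")
    sub = smooth[mask]
    sub_centers = centers[mask]
    order = np.argsort(sub_centers)  # deep -> shallow
    sub, sub_centers = sub[order], sub_centers[order]
    i_min = int(np.argmin(sub))
    low_confidence = (
        i_min in (0, len(sub) - 1)
        or (sub.max() - sub.min()) <= flat_tolerance * max(abs(sub).max(), 1.0)
    )
    return float(sub_centers[i_min]), bool(low_confidence)
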