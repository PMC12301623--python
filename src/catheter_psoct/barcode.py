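"""Tissue barcodes: 1-D profiles, 2-means clustering, midpoint threshold.

A carpet (or unfolded MRI ROI) collapses to a 1-D longitudinal profile by
averaging across image rows; 2-means clustering splits the profile into a
high (WM-like) and a low (GM-like) cluster, and the midpoint between the two
cluster centers thresholds the profile into a binary tissue barcode.  The
same statistic applied to both modalities gives comparable WM/GM sequences
along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Profile1D",
    "TissueBarcode",
    "longitudinal_profile",
    "kmeans_1d",
    "binarize",
    "compare_barcodes",
    "barcode_transitions_mm",
]


@dataclass
class Profile1D:
    """Row-mean profile along the trajectory (one value per image row)."""

    values: np.ndarray
    spacing_mm: float
    source: str = ""
    flagged: np.ndarray | None = None  # rows with < min fraction of unmasked columns

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.size < 4:
            raise ValueError("profile needs at least 4 rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite values")


def longitudinal_profile(
    image,
    mask=None,
    spacing_mm: float = 0.2,
    source: str = "",
    min_valid_fraction: float = 0.25,
) -> Profile1D:
    """Per-row mean over unmasked columns; empty rows interpolated and flagged."""
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image (rows = longitudinal positions)")
    m = np.ones_like(img, bool) if mask is None else np.asarray(mask, bool)
    m = m & np.isfinite(img)
    counts = m.sum(axis=1)
    if np.all(counts == 0):
        raise ValueError("all rows are fully masked")
    with np.errstate(invalid="ignore"):
        vals = np.where(m, img, 0.0).sum(axis=1) / np.where(counts > 0, counts, 1)
    flagged = counts < min_valid_fraction * img.shape[1]
    empty = counts == 0
    if np.any(empty):
        rows = np.arange(img.shape[0])
        vals = np.where(
            empty, np.interp(rows, rows[~empty], vals[~empty]), vals
        )
    return Profile1D(values=vals, spacing_mm=spacing_mm, source=source, flagged=flagged)


def kmeans_1d(profile):
    """Exact two-means clustering of scalars, deterministic.

    In one dimension the optimal 2-partition is contiguous in sorted order,
    so the global within-cluster-sum-of-squares optimum is found by scanning
    every threshold between consecutive sorted values (prefix sums make the
    scan linear).  Ties between equally good splits take the first (lowest
    threshold).  This always attains the optimum that randomized Lloyd
    iterations only reach with luck.

    Returns the sorted pair of cluster centers ``(low, high)``.
    """
    x = profile.values if isinstance(profile, Profile1D) else np.asarray(profile, float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("no tissue contrast: profile has fewer than 2 distinct values")
    xs = np.sort(x)
    n = xs.size
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    k = np.arange(1, n)  # split: low cluster = xs[:k]
    sum_lo, sq_lo = csum[k - 1], csq[k - 1]
    sum_hi, sq_hi = csum[-1] - sum_lo, csq[-1] - sq_lo
    wcss = (sq_lo - sum_lo**2 / k) + (sq_hi - sum_hi**2 / (n - k))
    best = int(np.argmin(wcss))
    c_lo = sum_lo[best] / k[best]
    c_hi = sum_hi[best] / (n - k[best])
    return (float(c_lo), float(c_hi))


@dataclass
class TissueBarcode:
    """Binary WM/GM sequence (1 = high/WM-like cluster)."""

    code: np.ndarray
    centers: tuple
    threshold: float
    spacing_mm: float

    def __post_init__(self):
        lo, hi = self.centers
        if not (lo < self.threshold < hi):
            raise ValueError("threshold must lie strictly between the cluster centers")


def binarize(profile: Profile1D, centers) -> TissueBarcode:
    """Midpoint threshold: value > (c_lo + c_hi)/2 -> 1, else 0 (ties -> 0)."""
    lo, hi = centers
    if not lo < hi:
        raise ValueError("cluster centers must be distinct")
    threshold = 0.5 * (lo + hi)
    code = (profile.values > threshold).astype(np.uint8)
    return TissueBarcode(
        code=code, centers=(float(lo), float(hi)), threshold=float(threshold),
        spacing_mm=profile.spacing_mm,
    )


def barcode_transitions_mm(bc: TissueBarcode) -> np.ndarray:
    """Longitudinal positions (mm) where the barcode changes value."""
    change = np.nonzero(np.diff(bc.code.astype(int)))[0] + 1
    return change * bc.spacing_mm


def compare_barcodes(psoct: TissueBarcode, mri: TissueBarcode, index_map) -> dict:
    """Row-wise agreement of the two barcodes through the longitudinal map.

    Maps each PS-OCT row to its MRI slice; reports the overall agreement
    fraction, per-class Dice coefficients, and the transition positions of
    both barcodes (mm from the cortical entry).
    """
    idx = np.asarray(index_map, int)
    inside = (idx >= 0) & (idx < len(mri.code))
    if not np.any(inside):
        raise ValueError("index map has no overlap with the MRI barcode")
    a = psoct.code[inside].astype(bool)
    b = mri.code[idx[inside]].astype(bool)
    agreement = float(np.mean(a == b))
    dice = {}
    for label, (x, y) in {"wm": (a, b), "gm": (~a, ~b)}.items():
        denom = x.sum() + y.sum()
        dice[label] = float(2.0 * np.sum(x & y) / denom) if denom else float("nan")
    return {
        "agreement": agreement,
        "dice": dice,
        "n_rows": int(inside.sum()),
        "transitions_psoct_mm": [float(t) for t in barcode_transitions_mm(psoct)],
        "transitions_mri_mm": [float(t) for t in barcode_transitions_mm(mri)],
    }
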