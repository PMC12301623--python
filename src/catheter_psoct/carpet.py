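"""En-face carpet views and the matching unfolded MRI ROI.

The helical pullback unrolls into a 2-D "carpet": rows are longitudinal
positions (one frame = one probe rotation = one helical pitch), columns are
azimuths, sampled at a fixed depth into tissue (300 um outside the sheath by
default).  On the MRI side, a 5x5-voxel cube along the trajectory — 9 central
pixels covering the catheter track, 16 perimeter pixels covering roughly the
carpet circumference — is unfolded into a 16-column strip.  Both share the
longitudinal origin (cortical entry), so a nearest-slice index map
co-registers them without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import MriVolume, Trajectory
from .reconstruction import LocalBirefMap, circular_mean_deg

__all__ = [
    "CarpetView",
    "RoiCube",
    "UnfoldedRoi",
    "extract_carpet",
    "extract_roi_cube",
    "unfold_perimeter",
    "longitudinal_mapping",
    "render_oa_hsv",
    "RING_OFFSETS",
]

#: Perimeter walk of the 5x5 cross-section ring: start on the +first-axis
#: side of the center, proceed counterclockwise.  16 entries of (di, dj).
RING_OFFSETS = [
    (2, 0), (2, 1), (2, 2), (1, 2), (0, 2), (-1, 2), (-2, 2), (-2, 1),
    (-2, 0), (-2, -1), (-2, -2), (-1, -2), (0, -2), (1, -2), (2, -2), (2, -1),
]

CENTRAL_OFFSETS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]


@dataclass
class CarpetView:
    """Unrolled en-face PS-OCT map: rows = frames, columns = A-line pairs."""

    retardance: np.ndarray  # (n_frames, n_pairs) deg/100um
    orientation: np.ndarray  # absolute orientation, deg [0, 180), NaN invalid
    intensity: np.ndarray
    mask: np.ndarray  # measurement validity
    depth_offset_um: float
    pitch_mm: float
    azimuth_deg: np.ndarray  # (n_pairs,)

    @property
    def n_rows(self) -> int:
        return self.retardance.shape[0]


@dataclass
class RoiCube:
    """5x5xN intensity block along the trajectory (N MRI slices)."""

    data: np.ndarray  # (5, 5, N)
    slice_spacing_mm: float
    center_index: tuple  # (i, j) of the trajectory column in the source volume
    start_slice: int

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def central_pixels(self) -> np.ndarray:
        """The 3x3 central block covering the catheter track, (9, N)."""
        return np.stack([self.data[2 + di, 2 + dj] for di, dj in CENTRAL_OFFSETS])

    def ring_pixels(self) -> np.ndarray:
        """The 16 perimeter pixels in the documented order, (16, N)."""
        return np.stack([self.data[2 + di, 2 + dj] for di, dj in RING_OFFSETS])


@dataclass
class UnfoldedRoi:
    """Unfolded 16-pixel perimeter: rows = MRI slices, columns = ring walk."""

    data: np.ndarray  # (N, 16)
    slice_spacing_mm: float
    start_offset: tuple = (2, 0)
    direction: str = "counterclockwise"


def extract_carpet(
    lb: LocalBirefMap,
    depth_offset_um: float = 300.0,
    band_px: int = 2,
) -> CarpetView:
    """Sample the reconstruction at a fixed depth outside the sheath.

    Retardance and intensity are averaged over a +/- ``band_px`` depth band
    (validity-weighted); orientation uses the circular mean over the band.
    """
    n_depth = lb.retardance.shape[0]
    idx = lb.sheath_band[1] + int(round(depth_offset_um / lb.axial_pixel_um))
    if not (0 <= idx < n_depth):
        raise ValueError(
            f"carpet depth offset {depth_offset_um} um falls outside the reconstructed range"
        )
    lo, hi = max(0, idx - band_px), min(n_depth, idx + band_px + 1)
    valid = (
        lb.measurement_valid[lo:hi]
        if lb.measurement_valid is not None
        else np.ones_like(lb.retardance[lo:hi], bool)
    )
    w = valid.astype(float)
    wsum = np.sum(w, axis=0)
    safe = np.where(wsum > 0, wsum, 1.0)
    ret = np.sum(lb.retardance[lo:hi] * w, axis=0) / safe
    inten = (
        np.sum(lb.intensity[lo:hi] * w, axis=0) / safe
        if lb.intensity is not None
        else np.zeros_like(ret)
    )
    ori_src = (
        lb.orientation_absolute if lb.orientation_absolute is not None else lb.orientation_apparent
    )
    band_ori = ori_src[lo:hi]
    ori_ok = np.isfinite(band_ori) & lb.mask[lo:hi]
    wo = ori_ok.astype(float)
    ori = circular_mean_deg(np.where(ori_ok, band_ori, 0.0), weights=wo, axis=0)
    ori = np.where(np.sum(wo, axis=0) > 0, ori, np.nan)
    mask = wsum > 0
    # (pair, frame) -> (frame/row, pair/column)
    return CarpetView(
        retardance=ret.T,
        orientation=ori.T,
        intensity=inten.T,
        mask=mask.T,
        depth_offset_um=depth_offset_um,
        pitch_mm=lb.pitch_mm,
        azimuth_deg=lb.azimuth_pair_deg,
    )


def extract_roi_cube(mri: MriVolume, trajectory: Trajectory, length_mm: float = 21.0) -> RoiCube:
    """Cut the 5x5-voxel ROI cube along an axis-aligned trajectory."""
    direction = np.asarray(trajectory.direction, float)
    if not np.allclose(np.abs(direction), [0.0, 0.0, 1.0], atol=1e-9):
        raise ValueError("trajectory must be aligned with the MRI slice axis")
    h = float(mri.voxel_mm[2])
    entry = np.asarray(trajectory.entry_mm, float)
    ci = int(round((entry[0] - mri.origin_mm[0]) / mri.voxel_mm[0]))
    cj = int(round((entry[1] - mri.origin_mm[1]) / mri.voxel_mm[1]))
    nx, ny, nz = mri.data.shape
    if ci - 2 < 0 or ci + 2 >= nx or cj - 2 < 0 or cj + 2 >= ny:
        raise ValueError("trajectory too close to the volume edge for the 5x5 window")
    # slice containing the cortical entry (slice k covers [k*h, (k+1)*h) from the volume edge)
    edge_z = mri.origin_mm[2] - 0.5 * h
    k0 = int(np.floor((entry[2] - edge_z) / h + 1e-9))
    n = int(np.ceil(length_mm / h - 1e-9))
    if k0 < 0 or k0 + n > nz:
        raise ValueError("analysis length exceeds the MRI volume extent")
    block = mri.data[ci - 2 : ci + 3, cj - 2 : cj + 3, k0 : k0 + n]
    return RoiCube(
        data=np.array(block), slice_spacing_mm=h, center_index=(ci, cj), start_slice=k0
    )


def unfold_perimeter(cube: RoiCube) -> UnfoldedRoi:
    """Read the 16 ring pixels of each slice into columns (fixed circular walk)."""
    return UnfoldedRoi(
        data=cube.ring_pixels().T.copy(), slice_spacing_mm=cube.slice_spacing_mm
    )


def longitudinal_mapping(carpet: CarpetView, roi: UnfoldedRoi) -> np.ndarray:
    """Nearest-slice index map from carpet rows to MRI slices.

    Both share the cortical-entry origin; MRI slice k covers longitudinal
    positions [k*h, (k+1)*h), so carpet row j at position j*pitch maps to
    slice floor(j*pitch / h).  No interpolation or averaging.
    """
    h = roi.slice_spacing_mm
    rows = np.arange(carpet.n_rows)
    return np.floor(rows * carpet.pitch_mm / h + 1e-9).astype(int)


def render_oa_hsv(
    carpet: CarpetView,
    display_max_deg_per_100um: float = 30.0,
    saturation: float = 1.0,
) -> np.ndarray:
    """Optic-axis colormap: hue = orientation (0 deg = blue), value = retardance.

    Masked or orientation-free pixels render black.  Returns an RGB float
    image of shape (n_rows, n_cols, 3) in [0, 1].
    """
    from matplotlib.colors import hsv_to_rgb

    ori = carpet.orientation
    hue = (2.0 / 3.0 + (ori % 180.0) / 180.0) % 1.0
    value = np.clip(carpet.retardance / display_max_deg_per_100um, 0.0, 1.0)
    bad = ~carpet.mask | ~np.isfinite(ori)
    hue = np.where(bad, 0.0, hue)
    value = np.where(bad, 0.0, value)
    hsv = np.stack([hue, np.full_like(hue, saturation), value], axis=-1)
    return hsv_to_rgb(hsv)
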