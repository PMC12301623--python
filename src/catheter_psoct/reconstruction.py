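"""Depth-resolved birefringence and absolute optic-axis reconstruction.

Inverts the catheter acquisition in five stages:

1. ``compute_stokes`` — Stokes vectors from the two detection channels,
   speckle-mitigated by Gaussian filtering of the intensity-weighted
   components (and spectral binning when enabled).
2. ``estimate_cumulative`` — per-pixel cumulative rotation from the pair of
   alternating probing states.
3. ``compensate_transmission`` — restores the D-transpose (reciprocity)
   symmetry of the round-trip rotation by a per-A-line correction rotation,
   removing non-reciprocal system/catheter transmission residuals.
4. ``peel_layers`` — one-pixel-layer recursion turning cumulative rotations
   into local retardance and apparent optic-axis orientation.
5. ``guide_star_correct`` — uses the catheter sheath (known, fixed optic axis
   in the probe frame) to estimate and remove the per-A-line orientation
   offset phi(α) introduced by the rotating catheter, yielding absolute
   orientation.

Reported retardance is double-pass, in degrees per 100 um.  With the
``negative_birefringence`` flag (default on, matching brain white matter) the
reported orientation is the fiber orientation: the measured optic axis is
flipped by 90 degrees, so 0 degrees means a circumferential fiber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from . import polarimetry as pol
from .acquisition import INPUT_STOKES, PullbackRaw

__all__ = [
    "ReconstructionConfig",
    "StokesVolume",
    "CumulativeMap",
    "LocalBirefMap",
    "compute_stokes",
    "estimate_cumulative",
    "compensate_transmission",
    "peel_layers",
    "guide_star_correct",
    "reconstruct_pullback",
    "circular_mean_deg",
    "circular_rmse_deg",
]


@dataclass(frozen=True)
class ReconstructionConfig:
    axial_sigma_px: float = 3.0
    lateral_sigma_pairs: float = 2.0
    dop_threshold: float = 0.7
    intensity_floor: float | None = None  # absolute; default derived from detector noise
    retardance_floor_deg_per_100um: float = 5.0
    sheath_known_orientation_deg: float | None = None  # default: catheter metadata
    sheath_min_mean_retardance_deg_per_100um: float = 1.0
    offset_smoothing_window_pairs: int = 15
    negative_birefringence: bool = True
    compensation_enabled: bool = True
    compensation_stride_pairs: int = 4
    compensation_stride_frames: int = 2
    compensation_window_pairs: int = 15
    compensation_window_frames: int = 3
    compensation_regularization: float = 1e-3


@dataclass
class StokesVolume:
    """Filtered, normalized Stokes data on the (depth, A-line pair, frame) grid."""

    states: np.ndarray  # (bins, depth, pair, frame, 2 states, 3)
    intensity: np.ndarray  # (bins, depth, pair, frame, 2 states)
    dop: np.ndarray  # (bins, depth, pair, frame, 2 states)
    azimuth_pair_deg: np.ndarray  # (pair,)

    @property
    def n_pairs(self) -> int:
        return self.states.shape[2]


@dataclass
class CumulativeMap:
    """Cumulative round-trip rotation per pixel (single spectral bin)."""

    rot: np.ndarray  # (depth, pair, frame, 3, 3)
    valid: np.ndarray  # (depth, pair, frame)
    azimuth_pair_deg: np.ndarray
    residual_asymmetry: np.ndarray | None = None  # quality metric from compensation


@dataclass
class LocalBirefMap:
    """Depth-resolved local retardance and optic-axis orientation.

    retardance: deg/100um (double pass); orientations in degrees [0, 180);
    ``orientation_absolute`` is present after guide-star correction.
    ``sheath_offset_deg`` is the recovered per-A-line offset series phi(α).
    """

    retardance: np.ndarray  # (depth, pair, frame)
    orientation_apparent: np.ndarray
    orientation_absolute: np.ndarray | None
    mask: np.ndarray  # orientation validity (measurement valid AND above retardance floor)
    measurement_valid: np.ndarray | None = None  # DOP/intensity validity only
    intensity: np.ndarray | None = None
    sheath_offset_deg: np.ndarray | None = None  # (frame, pair)
    sheath_flagged: np.ndarray | None = None  # A-lines where the sheath was interpolated
    azimuth_pair_deg: np.ndarray | None = None
    axial_pixel_um: float = 4.8
    pitch_mm: float = 0.2
    sheath_band: tuple = (0, 0)


def circular_mean_deg(angles_deg, weights=None, period: float = 180.0, axis=None):
    """Weighted circular mean of angles with the given period (degrees)."""
    ang = np.deg2rad(np.asarray(angles_deg, float) * (360.0 / period))
    w = np.ones_like(ang) if weights is None else np.asarray(weights, float)
    c = np.nansum(w * np.cos(ang), axis=axis)
    s = np.nansum(w * np.sin(ang), axis=axis)
    return (np.rad2deg(np.arctan2(s, c)) * (period / 360.0)) % period


def circular_diff_deg(a, b, period: float = 180.0):
    """Signed circular difference a - b in (-period/2, period/2]."""
    d = (np.asarray(a, float) - np.asarray(b, float)) % period
    return np.where(d > period / 2.0, d - period, d)


def circular_rmse_deg(a, b, period: float = 180.0):
    d = circular_diff_deg(a, b, period)
    return float(np.sqrt(np.nanmean(d**2)))


def compute_stokes(raw: PullbackRaw, config: ReconstructionConfig | None = None) -> StokesVolume:
    """Stokes estimation with spectral binning and Gaussian filtering.

    Adjacent A-lines are paired into (state-1, state-2) tuples; the
    intensity-weighted Stokes components are smoothed with a separable
    Gaussian (axial sigma in depth pixels, lateral sigma in A-line pairs,
    wrapping around the azimuth) and then renormalized.
    """
    config = config or ReconstructionConfig()
    fields = raw.fields
    n_al = fields.shape[2]
    if n_al % 2:
        import logging

        logging.getLogger(__name__).warning("odd A-line count: dropping the last A-line")
        fields = fields[:, :, :-1]
        n_al -= 1
    n_bins, n_depth, _, n_frames, _ = fields.shape
    n_pairs = n_al // 2
    states = np.empty((n_bins, n_depth, n_pairs, n_frames, 2, 3))
    inten = np.empty((n_bins, n_depth, n_pairs, n_frames, 2))
    dop = np.empty_like(inten)
    sig = (config.axial_sigma_px, config.lateral_sigma_pairs, 0.0)
    modes = ("nearest", "wrap", "nearest")
    for b in range(n_bins):
        for s in range(2):
            h = fields[b, :, s::2, :, 0]
            v = fields[b, :, s::2, :, 1]
            st = pol.stokes_from_fields(h, v)
            weighted = st.vec * st.intensity[..., None]
            if config.axial_sigma_px > 0 or config.lateral_sigma_pairs > 0:
                smooth_i = ndimage.gaussian_filter(st.intensity, sigma=sig, mode=modes)
                smooth_w = np.stack(
                    [
                        ndimage.gaussian_filter(weighted[..., k], sigma=sig, mode=modes)
                        for k in range(3)
                    ],
                    axis=-1,
                )
            else:
                smooth_i = st.intensity
                smooth_w = weighted
            norm = np.linalg.norm(smooth_w, axis=-1)
            with np.errstate(invalid="ignore", divide="ignore"):
                vec = smooth_w / np.where(norm > 0, norm, 1.0)[..., None]
                d = np.where(smooth_i > 0, norm / np.where(smooth_i > 0, smooth_i, 1.0), 0.0)
            states[b, :, :, :, s] = vec
            inten[b, :, :, :, s] = smooth_i
            dop[b, :, :, :, s] = d
    # pair azimuth = center of its two A-lines (avoid the 360-degree wrap)
    step = 360.0 / raw.azimuth_deg.size
    az_pairs = (raw.azimuth_deg[0::2] + 0.5 * step) % 360.0
    return StokesVolume(states=states, intensity=inten, dop=dop, azimuth_pair_deg=az_pairs)


def _default_intensity_floor(raw: PullbackRaw) -> float:
    # detector noise contributes 2*sigma^2 of intensity across the two channels
    return 10.0 * 2.0 * raw.acq.detector_noise_sigma**2


def estimate_cumulative(
    sv: StokesVolume,
    config: ReconstructionConfig | None = None,
    bin_index: int = 0,
    intensity_floor: float = 0.0,
) -> CumulativeMap:
    """Cumulative rotation per pixel from the alternating-state pair."""
    config = config or ReconstructionConfig()
    out1 = sv.states[bin_index, ..., 0, :]
    out2 = sv.states[bin_index, ..., 1, :]
    shape = out1.shape[:-1]
    in1 = np.broadcast_to(INPUT_STOKES[0], shape + (3,))
    in2 = np.broadcast_to(INPUT_STOKES[1], shape + (3,))
    rot, ok = pol.rotation_from_state_pairs(in1, in2, out1, out2)
    dop_ok = np.min(sv.dop[bin_index], axis=-1) >= config.dop_threshold
    int_ok = np.min(sv.intensity[bin_index], axis=-1) >= intensity_floor
    return CumulativeMap(
        rot=rot, valid=ok & dop_ok & int_ok, azimuth_pair_deg=sv.azimuth_pair_deg
    )


def _asymmetry(c):
    return c - pol.d_transpose(c)


def residual_asymmetry(cm: CumulativeMap) -> np.ndarray:
    """Frobenius norm of C - dT(C) per pixel (NaN where invalid)."""
    a = np.linalg.norm(_asymmetry(cm.rot), axis=(-2, -1))
    return np.where(cm.valid, a, np.nan)


def compensate_transmission(
    cm: CumulativeMap, config: ReconstructionConfig | None = None
) -> CumulativeMap:
    """Restore D-transpose symmetry of the cumulative rotation.

    For a linearly retarding sample the round-trip rotation satisfies
    dT(C) = C; residual asymmetry comes from noise and non-reciprocal system
    effects.  A correction rotation V is estimated on a coarse (A-line pair,
    frame) grid by minimizing ||dT(C_hat) - C_hat||_F^2 over a window of
    depths, with C_hat = dT(V)^-1 C V^-1, lightly regularized toward the
    identity (the objective has flat directions: any additional linear
    retarder conjugation preserves the symmetry and is later fixed by the
    guide star).  The estimate is applied to all pixels of its window;
    failures fall back to the previous A-line's estimate.
    """
    config = config or ReconstructionConfig()
    if not config.compensation_enabled:
        out = replace_rot(cm, cm.rot)
        out.residual_asymmetry = residual_asymmetry(cm)
        return out
    n_depth, n_pairs, n_frames = cm.valid.shape
    sp = max(1, config.compensation_stride_pairs)
    sf = max(1, config.compensation_stride_frames)
    wp = max(1, config.compensation_window_pairs // 2)
    wf = max(1, config.compensation_window_frames // 2)
    lam = config.compensation_regularization
    new_rot = np.array(cm.rot, copy=True)
    prev_v = np.zeros(3)
    for f0 in range(0, n_frames, sf):
        fs = slice(max(0, f0 - wf), min(n_frames, f0 + wf + 1))
        fs_apply = slice(f0, min(n_frames, f0 + sf))
        for p0 in range(0, n_pairs, sp):
            # window wraps in azimuth
            pidx = (np.arange(p0 - wp, p0 + wp + 1)) % n_pairs
            sel_rot = cm.rot[:, pidx][:, :, fs]
            sel_val = cm.valid[:, pidx][:, :, fs]
            mats = sel_rot[sel_val]
            p_apply = np.arange(p0, min(n_pairs, p0 + sp))
            if mats.shape[0] < 3:
                v_est = prev_v
            else:
                if mats.shape[0] > 64:  # subsample depths for speed
                    step = mats.shape[0] // 64 + 1
                    mats = mats[::step]

                def res(v):
                    vd = pol.retvec_to_rotation(
                        v / max(np.linalg.norm(v), 1e-12), np.linalg.norm(v)
                    )
                    vdt_inv = pol.d_transpose(vd).T
                    c_hat = vdt_inv @ mats @ vd.T
                    r = _asymmetry(c_hat).ravel()
                    return np.concatenate([r, lam * v])

                try:
                    sol = least_squares(res, x0=prev_v, method="lm", max_nfev=40)
                    v_est = sol.x
                except Exception:
                    v_est = prev_v
            prev_v = v_est
            ang = np.linalg.norm(v_est)
            vd = pol.retvec_to_rotation(v_est / max(ang, 1e-12), ang)
            vdt_inv = pol.d_transpose(vd).T
            blk = cm.rot[:, p_apply][:, :, fs_apply]
            new_rot[:, p_apply[:, None], np.arange(n_frames)[fs_apply][None, :]] = (
                vdt_inv @ blk @ vd.T
            )
    out = CumulativeMap(rot=new_rot, valid=cm.valid.copy(), azimuth_pair_deg=cm.azimuth_pair_deg)
    out.residual_asymmetry = residual_asymmetry(out)
    return out


def replace_rot(cm: CumulativeMap, rot) -> CumulativeMap:
    return CumulativeMap(rot=rot, valid=cm.valid.copy(), azimuth_pair_deg=cm.azimuth_pair_deg)


def peel_layers(
    cm: CumulativeMap,
    axial_pixel_um: float,
    config: ReconstructionConfig | None = None,
    pitch_mm: float = 0.2,
    sheath_band: tuple = (0, 0),
) -> LocalBirefMap:
    """Layer-peeling recursion: cumulative rotations to local properties.

    With P(0) = I, each depth step isolates the newly added one-pixel layer,
    N(z+1) = C(z+1) C(z)^-1 = P(z) L^2 P(z)^-1: half its rotation angle is
    the local double-pass retardance, and P(z)^-1 applied to its axis,
    projected to the equator, gives the apparent optic-axis orientation
    (halved azimuth).  Invalid depths are masked and P carried forward
    unchanged, avoiding error accumulation through signal-free gaps.
    """
    config = config or ReconstructionConfig()
    n_depth, n_pairs, n_frames = cm.valid.shape
    cols = n_pairs * n_frames
    rot = cm.rot.reshape(n_depth, cols, 3, 3)
    valid = cm.valid.reshape(n_depth, cols)
    deg_scale = 100.0 / axial_pixel_um  # per-pixel degrees -> deg/100um
    retardance = np.zeros((n_depth, cols))
    orientation = np.full((n_depth, cols), np.nan)
    mask = np.zeros((n_depth, cols), dtype=bool)
    p_cum = np.broadcast_to(np.eye(3), (cols, 3, 3)).copy()
    c_prev = np.broadcast_to(np.eye(3), (cols, 3, 3)).copy()
    for z in range(n_depth):
        ok = valid[z]
        n_mat = rot[z] @ np.swapaxes(c_prev, -1, -2)
        axis, angle = pol.rotation_to_retvec(n_mat)
        delta = angle / 2.0
        a_loc = np.einsum("cji,cj->ci", p_cum, axis)  # P^-1 = P^T applied to axis
        eq_norm = np.hypot(a_loc[:, 0], a_loc[:, 1])
        theta = (0.5 * np.rad2deg(np.arctan2(a_loc[:, 1], a_loc[:, 0]))) % 180.0
        ret_val = np.rad2deg(delta) * deg_scale
        defined = ok & (eq_norm > 1e-6)
        retardance[z] = np.where(ok, ret_val, 0.0)
        orientation[z] = np.where(defined, theta, np.nan)
        mask[z] = defined & (ret_val >= config.retardance_floor_deg_per_100um)
        # advance the recursion only through valid, defined layers
        upd = defined & (delta > 0)
        if np.any(upd):
            layer = pol.linear_retarder(theta[upd], delta[upd])
            p_cum[upd] = p_cum[upd] @ layer
        c_prev = np.where(ok[:, None, None], rot[z], c_prev)
    shape3 = (n_depth, n_pairs, n_frames)
    return LocalBirefMap(
        retardance=retardance.reshape(shape3),
        orientation_apparent=orientation.reshape(shape3),
        orientation_absolute=None,
        mask=mask.reshape(shape3),
        measurement_valid=valid.reshape(shape3).copy(),
        azimuth_pair_deg=cm.azimuth_pair_deg,
        axial_pixel_um=axial_pixel_um,
        pitch_mm=pitch_mm,
        sheath_band=sheath_band,
    )


def _circular_smooth_deg(angles_deg, window: int, period: float = 180.0):
    """Uniform circular smoothing along the last axis (wrap-around)."""
    if window <= 1:
        return angles_deg % period
    ang = np.deg2rad(np.asarray(angles_deg, float) * (360.0 / period))
    kernel = np.ones(window) / window
    c = ndimage.convolve1d(np.cos(ang), kernel, axis=-1, mode="wrap")
    s = ndimage.convolve1d(np.sin(ang), kernel, axis=-1, mode="wrap")
    return (np.rad2deg(np.arctan2(s, c)) * (period / 360.0)) % period


def guide_star_correct(
    lb: LocalBirefMap,
    sheath_band: tuple | None = None,
    known_sheath_orientation_deg: float = 0.0,
    config: ReconstructionConfig | None = None,
) -> LocalBirefMap:
    """Absolute optic axis via the catheter-sheath guide star.

    Per A-line the apparent sheath orientation (retardance-weighted circular
    mean over the sheath band) minus its known orientation gives the offset
    phi(α), which is circularly smoothed along azimuth and subtracted from the
    tissue orientations.  A-lines without a detectable sheath are filled from
    their azimuthal neighbors and flagged.
    """
    config = config or ReconstructionConfig()
    band = sheath_band if sheath_band is not None else lb.sheath_band
    i0, i1 = band
    if not (0 <= i0 < i1 <= lb.retardance.shape[0]):
        raise ValueError("invalid sheath band indices")
    ret_band = lb.retardance[i0:i1]  # (band, pair, frame)
    ori_band = lb.orientation_apparent[i0:i1]
    w = np.where(np.isfinite(ori_band), ret_band, 0.0)
    mean_ret = np.mean(ret_band, axis=0)  # (pair, frame)
    apparent_sheath = circular_mean_deg(
        np.where(np.isfinite(ori_band), ori_band, 0.0), weights=w, axis=0
    )  # (pair, frame)
    detected = (mean_ret >= config.sheath_min_mean_retardance_deg_per_100um) & (
        np.sum(w, axis=0) > 0
    )
    offset = circular_diff_deg(apparent_sheath, known_sheath_orientation_deg)  # (pair, frame)
    # fill undetected A-lines from azimuthal neighbors (circular interpolation)
    if not np.all(detected):
        ang = np.deg2rad(2.0 * offset)
        z = np.where(detected, np.exp(1j * ang), 0.0)
        k = np.ones(5)
        for _ in range(64):
            miss = ~detected & (np.abs(z) < 1e-9)
            if not np.any(miss):
                break
            zs = ndimage.convolve1d(z.real, k, axis=0, mode="wrap") + 1j * ndimage.convolve1d(
                z.imag, k, axis=0, mode="wrap"
            )
            z = np.where(miss & (np.abs(zs) > 1e-9), zs / np.abs(zs), z)
        offset = np.where(detected, offset, np.rad2deg(np.angle(z)) / 2.0)
    smoothed = _circular_smooth_deg(offset.T, config.offset_smoothing_window_pairs).T
    smoothed = circular_diff_deg(smoothed, 0.0)
    absolute = (lb.orientation_apparent - smoothed[None, :, :]) % 180.0
    return LocalBirefMap(
        retardance=lb.retardance,
        orientation_apparent=lb.orientation_apparent,
        orientation_absolute=absolute,
        mask=lb.mask,
        measurement_valid=lb.measurement_valid,
        intensity=lb.intensity,
        sheath_offset_deg=smoothed.T.copy(),  # (frame, pair)
        sheath_flagged=~detected.T,
        azimuth_pair_deg=lb.azimuth_pair_deg,
        axial_pixel_um=lb.axial_pixel_um,
        pitch_mm=lb.pitch_mm,
        sheath_band=band,
    )


def _apply_sign_convention(lb: LocalBirefMap, negative: bool) -> LocalBirefMap:
    if not negative:
        return lb
    flip = lambda x: None if x is None else (x + 90.0) % 180.0
    return LocalBirefMap(
        retardance=lb.retardance,
        orientation_apparent=flip(lb.orientation_apparent),
        orientation_absolute=flip(lb.orientation_absolute),
        mask=lb.mask,
        measurement_valid=lb.measurement_valid,
        intensity=lb.intensity,
        sheath_offset_deg=lb.sheath_offset_deg,
        sheath_flagged=lb.sheath_flagged,
        azimuth_pair_deg=lb.azimuth_pair_deg,
        axial_pixel_um=lb.axial_pixel_um,
        pitch_mm=lb.pitch_mm,
        sheath_band=lb.sheath_band,
    )


def reconstruct_pullback(
    raw: PullbackRaw, config: ReconstructionConfig | None = None
) -> LocalBirefMap:
    """Full inversion chain for one pullback (per spectral bin, then merged).

    Bins are reconstructed independently; retardance is averaged and
    orientation circularly averaged across bins before the sign convention is
    applied.
    """
    config = config or ReconstructionConfig()
    sv = compute_stokes(raw, config)
    floor = (
        config.intensity_floor
        if config.intensity_floor is not None
        else _default_intensity_floor(raw)
    )
    n_bins = raw.fields.shape[0]
    maps = []
    for b in range(n_bins):
        cm = estimate_cumulative(sv, config, bin_index=b, intensity_floor=floor)
        cm = compensate_transmission(cm, config)
        lb = peel_layers(
            cm,
            axial_pixel_um=raw.acq.axial_pixel_um,
            config=config,
            pitch_mm=raw.acq.pitch_mm,
            sheath_band=raw.sheath_band,
        )
        known = (
            config.sheath_known_orientation_deg
            if config.sheath_known_orientation_deg is not None
            else raw.catheter.sheath_orientation_deg
        )
        lb = guide_star_correct(lb, raw.sheath_band, known, config)
        maps.append(lb)
    if n_bins == 1:
        merged = maps[0]
    else:
        ret = np.mean([m.retardance for m in maps], axis=0)
        app = _merge_orientations([m.orientation_apparent for m in maps])
        absol = _merge_orientations([m.orientation_absolute for m in maps])
        mask = np.logical_and.reduce([m.mask for m in maps])
        merged = LocalBirefMap(
            retardance=ret,
            orientation_apparent=app,
            orientation_absolute=absol,
            mask=mask,
            measurement_valid=np.logical_and.reduce([m.measurement_valid for m in maps]),
            sheath_offset_deg=maps[0].sheath_offset_deg,
            sheath_flagged=maps[0].sheath_flagged,
            azimuth_pair_deg=maps[0].azimuth_pair_deg,
            axial_pixel_um=maps[0].axial_pixel_um,
            pitch_mm=maps[0].pitch_mm,
            sheath_band=maps[0].sheath_band,
        )
    merged.intensity = np.mean(sv.intensity, axis=(0, -1))
    return _apply_sign_convention(merged, config.negative_birefringence)


def _merge_orientations(stacks):
    arr = np.stack(stacks, axis=0)
    ang = np.deg2rad(2.0 * arr)
    c = np.nanmean(np.cos(ang), axis=0)
    s = np.nanmean(np.sin(ang), axis=0)
    out = (np.rad2deg(np.arctan2(s, c)) / 2.0) % 180.0
    return np.where(np.all(np.isnan(arr), axis=0), np.nan, out)
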