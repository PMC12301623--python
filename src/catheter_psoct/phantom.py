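"""Synthetic brain-like birefringence phantom and its MRI-like rendering.

The phantom emulates a deep-brain-stimulation-style insertion: a vertical
trajectory through a stack of tissue slabs (cortical gray matter, subcortical
white matter, deep gray matter containing a thin, strongly birefringent fiber
tract standing in for the internal capsule).  Each voxel carries a tissue
class, a birefringence magnitude Delta-n, and a 3-D unit fiber direction.
White matter is modeled as negatively birefringent by default: the optical
fast axis measured by PS-OCT is perpendicular to the fiber direction, which
downstream reporting folds back so that 0 degrees means a circumferential
fiber in the probe frame.

The same phantom is rendered into a coarse T1-weighted-like volume
(0.57 mm isotropic by default) by exact volume-weighted box averaging of
class intensities — the partial-volume mixing that blurs WM/GM boundaries at
MRI resolution — plus seeded Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CLASS_IDS",
    "LayerSpec",
    "PhantomConfig",
    "MriRenderConfig",
    "TissuePhantom",
    "MriVolume",
    "Trajectory",
    "build_dbs_phantom",
    "render_mri",
    "true_maps_along_trajectory",
    "retardance_deg_per_100um",
]

#: Tissue class codes used in the label grid.
CLASS_IDS = {"cortex_gm": 1, "wm": 2, "deep_gm": 3, "tract": 4}
GM_CLASSES = ("cortex_gm", "deep_gm")


class PhantomConfigError(ValueError):
    """Raised for inconsistent layer geometry or coverage."""


@dataclass(frozen=True)
class LayerSpec:
    """One slab along the trajectory axis: tissue class over [start, end) mm."""

    tissue: str
    start_mm: float
    end_mm: float


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and optical parameters of the slab phantom.

    ``layers`` must tile [0, length_mm) without gaps or overlap; ``inclusions``
    are painted on top (e.g. the high-birefringence tract inside deep GM).
    ``birefringence`` maps class name to Delta-n; ``fiber`` maps class name to
    a lab-frame fiber direction (normalized internally) or the string
    ``"circumferential"`` for fibers running tangentially around the
    trajectory axis (evaluated analytically at sample positions — always
    beam-orthogonal, apparent orientation 0 deg at every azimuth).  ``sign``
    is the birefringence sign of fibrous tissue (-1: measured optic axis is
    perpendicular to the fiber).
    """

    length_mm: float = 23.0
    lateral_halfwidth_mm: float = 4.0
    pitch_mm: float = 0.1
    layers: tuple[LayerSpec, ...] = (
        LayerSpec("cortex_gm", 0.0, 2.0),
        LayerSpec("wm", 2.0, 10.0),
        LayerSpec("deep_gm", 10.0, 23.0),
    )
    inclusions: tuple[LayerSpec, ...] = (LayerSpec("tract", 13.0, 15.0),)
    birefringence: dict = field(
        default_factory=lambda: {"cortex_gm": 0.0, "wm": 2e-4, "deep_gm": 0.0, "tract": 5e-4}
    )
    fiber: dict = field(
        default_factory=lambda: {"wm": "circumferential", "tract": (1.0, 0.0, 0.0)}
    )
    scattering_amplitude: dict = field(
        default_factory=lambda: {"cortex_gm": 0.6, "wm": 1.0, "deep_gm": 0.55, "tract": 1.1}
    )
    sign: int = -1

    def with_layers(self, layers, inclusions=None) -> "PhantomConfig":
        return replace(
            self,
            layers=tuple(layers),
            inclusions=tuple(inclusions) if inclusions is not None else self.inclusions,
        )


@dataclass(frozen=True)
class MriRenderConfig:
    """T1-like rendering: class intensities (WM bright), voxel size, noise."""

    voxel_mm: float = 0.57
    noise_sigma: float = 0.02
    intensity: dict = field(
        default_factory=lambda: {"cortex_gm": 0.55, "wm": 1.0, "deep_gm": 0.5, "tract": 1.0}
    )


@dataclass
class TissuePhantom:
    """Voxelized slab phantom; axis 2 of every grid runs along the trajectory."""

    labels: np.ndarray  # (nx, ny, nz) int8 class codes
    birefringence: np.ndarray  # (nx, ny, nz) Delta-n
    fiber: np.ndarray  # (nx, ny, nz, 3) unit fiber direction (0 where Delta-n == 0)
    pitch_mm: float
    origin_mm: np.ndarray  # position of voxel (0,0,0) center, lab frame
    sign: int
    config: PhantomConfig
    circumferential_ids: frozenset = frozenset()  # classes with tangential fibers

    @property
    def shape(self):
        return self.labels.shape

    def extent_mm(self):
        lo = self.origin_mm - 0.5 * self.pitch_mm
        hi = lo + np.array(self.shape) * self.pitch_mm
        return lo, hi

    def contains(self, points_mm) -> np.ndarray:
        lo, hi = self.extent_mm()
        p = np.asarray(points_mm, dtype=float)
        return np.all((p >= lo) & (p < hi), axis=-1)

    def sample(self, points_mm):
        """Nearest-voxel lookup of (labels, Delta-n, fiber) at lab-frame points."""
        p = np.asarray(points_mm, dtype=float)
        if not np.all(self.contains(p)):
            raise PhantomConfigError("sample points leave the phantom volume")
        idx = np.round((p - self.origin_mm) / self.pitch_mm).astype(int)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        i, j, k = idx[..., 0], idx[..., 1], idx[..., 2]
        labels = self.labels[i, j, k]
        fiber = self.fiber[i, j, k]
        if self.circumferential_ids:
            circ = np.isin(labels, list(self.circumferential_ids))
            if np.any(circ):
                xy = p[..., :2]
                r = np.linalg.norm(xy, axis=-1)
                safe = np.where(r > 1e-9, r, 1.0)
                tang = np.stack(
                    [-xy[..., 1] / safe, xy[..., 0] / safe, np.zeros_like(r)], axis=-1
                )
                fiber = np.where(circ[..., None] & (r > 1e-9)[..., None], tang, fiber)
        return labels, self.birefringence[i, j, k], fiber


@dataclass
class MriVolume:
    """Scalar MRI-like volume on an axis-aligned grid in phantom coordinates."""

    data: np.ndarray
    voxel_mm: np.ndarray  # per-axis spacing, mm
    origin_mm: np.ndarray  # center of voxel (0,0,0)
    coverage: np.ndarray | None = None  # fraction of each voxel inside the phantom

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_mm)
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass(frozen=True)
class Trajectory:
    """Straight probe path: entry point, unit direction (vertical by default)."""

    entry_mm: tuple = (0.0, 0.0, 0.0)
    direction: tuple = (0.0, 0.0, 1.0)
    length_mm: float = 23.0

    def __post_init__(self):
        d = np.linalg.norm(np.asarray(self.direction, float))
        if not np.isclose(d, 1.0, atol=1e-9):
            raise PhantomConfigError("trajectory direction must be a unit vector")
        if self.length_mm <= 0:
            raise PhantomConfigError("trajectory length must be positive")


def _validate_layers(config: PhantomConfig):
    layers = sorted(config.layers, key=lambda s: s.start_mm)
    pos = 0.0
    for lay in layers:
        if lay.tissue not in CLASS_IDS:
            raise PhantomConfigError(f"unknown tissue class {lay.tissue!r}")
        if lay.end_mm <= lay.start_mm:
            raise PhantomConfigError(f"layer {lay.tissue} has non-positive thickness")
        if not np.isclose(lay.start_mm, pos, atol=1e-9):
            raise PhantomConfigError(
                f"layers must tile [0, {config.length_mm}] without gaps/overlap; "
                f"found boundary at {lay.start_mm} expected {pos}"
            )
        pos = lay.end_mm
    if not np.isclose(pos, config.length_mm, atol=1e-9):
        raise PhantomConfigError("layers do not cover the full trajectory length")
    for inc in config.inclusions:
        if inc.tissue not in CLASS_IDS:
            raise PhantomConfigError(f"unknown tissue class {inc.tissue!r}")
        if inc.start_mm < 0 or inc.end_mm > config.length_mm or inc.end_mm <= inc.start_mm:
            raise PhantomConfigError("inclusion outside trajectory range")
    return layers


def build_dbs_phantom(config: PhantomConfig | None = None, seed: int | None = 0) -> TissuePhantom:
    """Build the slab phantom.  Deterministic for a given seed.

    The grid spans +/- lateral_halfwidth_mm in x and y and [0, length_mm]
    along z; voxel centers start at the lower corner plus half a pitch.
    """
    config = config or PhantomConfig()
    layers = _validate_layers(config)
    p = config.pitch_mm
    nxy = int(round(2 * config.lateral_halfwidth_mm / p))
    nz = int(round(config.length_mm / p))
    z_centers = (np.arange(nz) + 0.5) * p
    z_labels = np.zeros(nz, dtype=np.int8)
    for lay in list(layers) + list(config.inclusions):
        sel = (z_centers >= lay.start_mm) & (z_centers < lay.end_mm)
        z_labels[sel] = CLASS_IDS[lay.tissue]
    labels = np.broadcast_to(z_labels, (nxy, nxy, nz)).astype(np.int8)
    name_of = {v: k for k, v in CLASS_IDS.items()}
    dn_of = np.zeros(max(CLASS_IDS.values()) + 1)
    fiber_of = np.zeros((max(CLASS_IDS.values()) + 1, 3))
    circ_ids = set()
    for cid, cname in name_of.items():
        dn_of[cid] = config.birefringence.get(cname, 0.0)
        spec = config.fiber.get(cname, (0.0, 0.0, 0.0))
        if isinstance(spec, str):
            if spec != "circumferential":
                raise PhantomConfigError(f"unknown fiber mode {spec!r} for class {cname}")
            circ_ids.add(cid)
            continue
        f = np.asarray(spec, dtype=float)
        n = np.linalg.norm(f)
        if dn_of[cid] > 0:
            if n == 0:
                raise PhantomConfigError(f"birefringent class {cname} needs a fiber direction")
            f = f / n
        fiber_of[cid] = f
    birefringence = dn_of[labels]
    fiber = fiber_of[labels]
    origin = np.array([-config.lateral_halfwidth_mm + 0.5 * p, -config.lateral_halfwidth_mm + 0.5 * p, 0.5 * p])
    return TissuePhantom(
        labels=np.ascontiguousarray(labels),
        birefringence=birefringence.astype(np.float64),
        fiber=fiber.astype(np.float64),
        pitch_mm=p,
        origin_mm=origin,
        sign=config.sign,
        config=config,
        circumferential_ids=frozenset(circ_ids),
    )


def _box_average_axis(values, coverage, axis, src_pitch, dst_pitch):
    """Exact 1-D box average of piecewise-constant data along one axis."""
    v = np.moveaxis(values, axis, 0)
    cov = np.moveaxis(coverage, axis, 0)
    n = v.shape[0]
    length = n * src_pitch
    m = int(np.ceil(length / dst_pitch - 1e-12))
    # cumulative integral of v at arbitrary positions
    csum = np.concatenate([np.zeros((1,) + v.shape[1:]), np.cumsum(v, axis=0) * src_pitch], axis=0)
    ccov = np.concatenate([np.zeros((1,) + v.shape[1:]), np.cumsum(cov, axis=0) * src_pitch], axis=0)

    def integral(c, x):
        idx = np.clip(np.floor(x / src_pitch).astype(int), 0, n - 1)
        frac = x - idx * src_pitch
        step = (c[idx + 1] - c[idx]) / src_pitch
        return c[idx] + step * frac

    edges_lo = np.arange(m) * dst_pitch
    edges_hi = np.minimum(edges_lo + dst_pitch, length)
    out = np.empty((m,) + v.shape[1:])
    out_cov = np.empty_like(out)
    for j in range(m):
        width = edges_hi[j] - edges_lo[j]
        iv = integral(csum, edges_hi[j]) - integral(csum, edges_lo[j])
        ic = integral(ccov, edges_hi[j]) - integral(ccov, edges_lo[j])
        out[j] = iv / width
        out_cov[j] = ic / dst_pitch  # fraction of the *nominal* voxel inside the phantom
    return np.moveaxis(out, 0, axis), np.moveaxis(out_cov, 0, axis)


def render_mri(
    phantom: TissuePhantom,
    config: MriRenderConfig | None = None,
    seed: int | None = 0,
) -> MriVolume:
    """Render the phantom into a coarse T1-like volume with partial-volume mixing.

    Each MRI voxel is the exact volume-weighted average of per-class intensities
    over the phantom voxels it covers (separable box average), plus Gaussian
    noise of standard deviation ``noise_sigma``.
    """
    config = config or MriRenderConfig()
    if config.voxel_mm <= 0:
        raise PhantomConfigError("MRI voxel size must be positive")
    name_of = {v: k for k, v in CLASS_IDS.items()}
    inten_of = np.zeros(max(CLASS_IDS.values()) + 1)
    for cid, cname in name_of.items():
        if cname not in config.intensity:
            raise PhantomConfigError(f"missing MRI intensity for class {cname}")
        inten_of[cid] = config.intensity[cname]
    vol = inten_of[phantom.labels]
    cov = np.ones_like(vol)
    for axis in range(3):
        vol, cov = _box_average_axis(vol, cov, axis, phantom.pitch_mm, config.voxel_mm)
    lo, _ = phantom.extent_mm()
    origin = lo + 0.5 * config.voxel_mm
    if config.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, config.noise_sigma, size=vol.shape)
    return MriVolume(
        data=vol,
        voxel_mm=np.full(3, float(config.voxel_mm)),
        origin_mm=origin,
        coverage=cov,
    )


def retardance_deg_per_100um(delta_n, perp_fraction, wavelength_nm: float) -> np.ndarray:
    """Double-pass local retardance in degrees per 100 um of depth.

    delta_n scaled by the squared transverse fiber fraction; the double pass
    contributes the factor 2 in the optical path.
    """
    lam_um = wavelength_nm * 1e-3
    rad_per_um = 2.0 * np.pi * np.asarray(delta_n) * np.asarray(perp_fraction) * 2.0 / lam_um
    return np.rad2deg(rad_per_um) * 100.0


def true_maps_along_trajectory(
    phantom: TissuePhantom,
    trajectory: Trajectory,
    acq,
    catheter,
    depth_offset_um: float = 300.0,
):
    """Ground-truth carpet: true local retardance and fiber orientation.

    For every (frame, A-line) of the planned pullback, samples the phantom at
    the carpet radius (sheath outer surface + ``depth_offset_um``) and returns
    a dict with ``retardance`` (deg/100um), ``orientation`` (deg in [0, 180),
    NaN where undefined) and ``defined`` (bool mask), each of shape
    (n_frames, n_alines).  Orientation is the *fiber* orientation: for a
    negatively birefringent phantom the optical axis the instrument sees is
    perpendicular, and reconstruction folds it back to this convention.
    """
    from .acquisition import project_fiber_orientation  # local import: avoids cycle

    direction = np.asarray(trajectory.direction, float)
    if not np.allclose(direction, [0.0, 0.0, 1.0], atol=1e-9):
        raise PhantomConfigError("only vertical (grid-axis-aligned) trajectories are supported")
    n_frames = acq.n_frames(trajectory.length_mm)
    alphas = acq.azimuths_deg(catheter.start_azimuth_deg)
    radius_mm = catheter.sheath_outer_diameter_mm / 2.0 + depth_offset_um * 1e-3
    zs = np.arange(n_frames) * acq.pitch_mm
    a = np.deg2rad(alphas)
    beam = np.stack([np.cos(a), np.sin(a), np.zeros_like(a)], axis=-1)  # (nal, 3)
    entry = np.asarray(trajectory.entry_mm, float)
    pts = entry + zs[:, None, None] * direction + radius_mm * beam[None, :, :]
    if not np.all(phantom.contains(pts)):
        raise PhantomConfigError("carpet radius leaves the phantom volume; widen the grid")
    _, dn, fib = phantom.sample(pts)
    orient = np.full(dn.shape, np.nan)
    perp = np.zeros_like(dn)
    has_fiber = dn > 0
    if np.any(has_fiber):
        th, scale, defined = project_fiber_orientation(
            fib[has_fiber], np.broadcast_to(alphas, dn.shape)[has_fiber]
        )
        orient[has_fiber] = np.where(defined, th, np.nan)
        perp[has_fiber] = scale
    ret = retardance_deg_per_100um(dn, perp, acq.center_wavelength_nm)
    defined = has_fiber & np.isfinite(orient) & (ret > 0)
    return {"retardance": ret, "orientation": orient % 180.0, "defined": defined}
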