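"""File I/O: HDF5 pullbacks and maps, NIfTI MRI volumes, TIFF/PNG exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .acquisition import AcquisitionConfig, CatheterModel, PullbackRaw
from .phantom import MriVolume, Trajectory
from .reconstruction import LocalBirefMap

__all__ = [
    "FormatError",
    "save_pullback",
    "load_pullback",
    "save_biref_map",
    "load_biref_map",
    "save_mri_nifti",
    "load_mri_nifti",
    "save_carpet_tiff",
    "write_json",
    "sha256_of",
]


class FormatError(ValueError):
    """Malformed or incomplete on-disk data."""


def save_pullback(path, raw: PullbackRaw) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("fields", data=raw.fields, compression="gzip", compression_opts=1)
        f.create_dataset("azimuth", data=raw.azimuth_deg)
        gt = f.create_group("ground_truth")
        gt.create_dataset("retardance", data=raw.true_retardance.astype(np.float32))
        gt.create_dataset("orientation", data=raw.true_orientation.astype(np.float32))
        gt.create_dataset("offset_deg", data=raw.true_offset_deg.astype(np.float32))
        f.attrs["meta"] = raw.meta_json()
        f.attrs["sheath_band"] = raw.sheath_band
        f.attrs["retardance_units"] = "deg per 100 um (double pass)"


def load_pullback(path) -> PullbackRaw:
    with h5py.File(path, "r") as f:
        for name in ("fields", "azimuth", "ground_truth/retardance"):
            if name not in f:
                raise FormatError(f"pullback file {path} is missing dataset '{name}'")
        if "meta" not in f.attrs:
            raise FormatError(f"pullback file {path} is missing the 'meta' attribute")
        meta = json.loads(f.attrs["meta"])
        return PullbackRaw(
            fields=f["fields"][()],
            azimuth_deg=f["azimuth"][()],
            sheath_band=tuple(int(x) for x in f.attrs["sheath_band"]),
            acq=AcquisitionConfig(**meta["acq"]),
            catheter=CatheterModel(**meta["catheter"]),
            trajectory=Trajectory(
                entry_mm=tuple(meta["trajectory"]["entry_mm"]),
                direction=tuple(meta["trajectory"]["direction"]),
                length_mm=meta["trajectory"]["length_mm"],
            ),
            seed=meta["seed"],
            true_retardance=f["ground_truth/retardance"][()].astype(float),
            true_orientation=f["ground_truth/orientation"][()].astype(float),
            true_offset_deg=f["ground_truth/offset_deg"][()].astype(float),
            phantom_sign=meta.get("phantom_sign", -1),
        )


def save_biref_map(path, lb: LocalBirefMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("retardance", data=lb.retardance.astype(np.float32))
        f["retardance"].attrs["units"] = "deg per 100 um (double pass)"
        f.create_dataset("orientation_apparent", data=lb.orientation_apparent.astype(np.float32))
        f["orientation_apparent"].attrs["units"] = "deg in [0, 180)"
        if lb.orientation_absolute is not None:
            f.create_dataset(
                "orientation_absolute", data=lb.orientation_absolute.astype(np.float32)
            )
            f["orientation_absolute"].attrs["units"] = "deg in [0, 180)"
        f.create_dataset("mask", data=lb.mask)
        if lb.measurement_valid is not None:
            f.create_dataset("measurement_valid", data=lb.measurement_valid)
        if lb.intensity is not None:
            f.create_dataset("intensity", data=lb.intensity.astype(np.float32))
        if lb.sheath_offset_deg is not None:
            f.create_dataset("sheath_offset", data=lb.sheath_offset_deg.astype(np.float32))
            f["sheath_offset"].attrs["units"] = "deg"
        if lb.azimuth_pair_deg is not None:
            f.create_dataset("azimuth_pair", data=lb.azimuth_pair_deg)
        f.attrs["axial_pixel_um"] = lb.axial_pixel_um
        f.attrs["pitch_mm"] = lb.pitch_mm
        f.attrs["sheath_band"] = lb.sheath_band


def load_biref_map(path) -> LocalBirefMap:
    with h5py.File(path, "r") as f:
        for name in ("retardance", "orientation_apparent", "mask"):
            if name not in f:
                raise FormatError(f"birefringence map {path} is missing dataset '{name}'")

        def opt(name):
            return f[name][()] if name in f else None

        return LocalBirefMap(
            retardance=f["retardance"][()].astype(float),
            orientation_apparent=f["orientation_apparent"][()].astype(float),
            orientation_absolute=(
                f["orientation_absolute"][()].astype(float)
                if "orientation_absolute" in f
                else None
            ),
            mask=f["mask"][()].astype(bool),
            measurement_valid=(
                f["measurement_valid"][()].astype(bool) if "measurement_valid" in f else None
            ),
            intensity=opt("intensity"),
            sheath_offset_deg=opt("sheath_offset"),
            azimuth_pair_deg=opt("azimuth_pair"),
            axial_pixel_um=float(f.attrs["axial_pixel_um"]),
            pitch_mm=float(f.attrs["pitch_mm"]),
            sheath_band=tuple(int(x) for x in f.attrs["sheath_band"]),
        )


def save_mri_nifti(path, mri: MriVolume) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(mri.data, np.float32), mri.affine)
    img.header.set_zooms(tuple(float(v) for v in mri.voxel_mm))
    nib.save(img, str(path))


def load_mri_nifti(path) -> MriVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    zooms = np.asarray(img.header.get_zooms()[:3], float)
    if np.any(zooms <= 0):
        raise FormatError(f"NIfTI volume {path} has non-positive voxel size (pixdim)")
    aff = img.affine
    return MriVolume(
        data=np.asarray(img.get_fdata()),
        voxel_mm=zooms,
        origin_mm=np.asarray(aff[:3, 3], float),
    )


def save_carpet_tiff(path, plane: np.ndarray, scale: float = 100.0) -> None:
    """16-bit TIFF export (values multiplied by ``scale`` and clipped)."""
    import tifffile

    data = np.nan_to_num(np.asarray(plane, float), nan=0.0)
    u16 = np.clip(data * scale, 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), u16, metadata={"scale": scale})


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
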