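"""Stage runner tying the simulation/reconstruction/comparison chain together.

Each stage reads its inputs from and writes its outputs to a working
directory with fixed file names, appending an entry (parameters, file
digests, timing) to ``manifest.json``.  All randomness flows from the single
pipeline seed through named per-stage substreams.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import barcode as bc
from . import carpet as cp
from . import io as pio
from .acquisition import simulate_pullback
from .config import PipelineConfig
from .phantom import build_dbs_phantom, render_mri
from .reconstruction import reconstruct_pullback

__all__ = ["STAGES", "run_stage", "run_all", "MissingInputError", "stage_seed"]

STAGES = ("phantom", "simulate", "reconstruct", "carpet", "mri-roi", "barcode", "compare", "render")

FILES = {
    "phantom": "phantom.h5",
    "pullback": "pullback.h5",
    "biref": "biref.h5",
    "carpet": "carpet.h5",
    "mri": "mri.nii.gz",
    "roi": "unfolded_roi.h5",
    "barcodes": "barcodes.json",
    "compare": "agreement.json",
    "render": "oa_carpet.png",
}


class MissingInputError(FileNotFoundError):
    """A stage was run before the stage that produces its input."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream of the global seed (< 2**31)."""
    import zlib

    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def _require(workdir: Path, *names):
    for name in names:
        p = workdir / FILES[name]
        if not p.exists():
            raise MissingInputError(
                f"missing input {p.name}: run the producing stage first"
            )
    return [workdir / FILES[n] for n in names]


def _manifest_append(workdir: Path, entry: dict):
    path = workdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": []}
    manifest["stages"] = [s for s in manifest["stages"] if s["stage"] != entry["stage"]] + [entry]
    path.write_text(json.dumps(manifest, indent=2) + "\n")


def run_stage(name: str, config: PipelineConfig, workdir) -> dict:
    """Execute one pipeline stage; returns its manifest entry."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outputs: list[Path] = []

    if name == "phantom":
        ph = build_dbs_phantom(config.phantom, seed=stage_seed(config.seed, "phantom"))
        import h5py

        out = workdir / FILES["phantom"]
        with h5py.File(out, "w") as f:
            f.create_dataset("labels", data=ph.labels, compression="gzip")
            f.create_dataset("birefringence", data=ph.birefringence.astype(np.float32),
                             compression="gzip")
            f.create_dataset("fiber", data=ph.fiber.astype(np.float32), compression="gzip")
            f.attrs["pitch_mm"] = ph.pitch_mm
            f.attrs["origin_mm"] = ph.origin_mm
            f.attrs["sign"] = ph.sign
        outputs = [out]
    elif name == "simulate":
        _require(workdir, "phantom")
        ph = build_dbs_phantom(config.phantom, seed=stage_seed(config.seed, "phantom"))
        raw = simulate_pullback(
            ph, config.trajectory, config.catheter, config.acquisition,
            seed=stage_seed(config.seed, "simulate"),
        )
        out = workdir / FILES["pullback"]
        pio.save_pullback(out, raw)
        outputs = [out]
    elif name == "reconstruct":
        (src,) = _require(workdir, "pullback")
        raw = pio.load_pullback(src)
        lb = reconstruct_pullback(raw, config.reconstruction)
        out = workdir / FILES["biref"]
        pio.save_biref_map(out, lb)
        outputs = [out]
    elif name == "carpet":
        (src,) = _require(workdir, "biref")
        lb = pio.load_biref_map(src)
        view = cp.extract_carpet(lb, config.carpet.depth_offset_um, config.carpet.band_px)
        out = workdir / FILES["carpet"]
        import h5py

        with h5py.File(out, "w") as f:
            f.create_dataset("retardance", data=view.retardance.astype(np.float32))
            f.create_dataset("orientation", data=view.orientation.astype(np.float32))
            f.create_dataset("intensity", data=view.intensity.astype(np.float32))
            f.create_dataset("mask", data=view.mask)
            f.attrs["pitch_mm"] = view.pitch_mm
            f.attrs["depth_offset_um"] = view.depth_offset_um
        pio.save_carpet_tiff(workdir / "carpet_retardance.tiff", view.retardance)
        outputs = [out, workdir / "carpet_retardance.tiff"]
    elif name == "mri-roi":
        ph = build_dbs_phantom(config.phantom, seed=stage_seed(config.seed, "phantom"))
        mri = render_mri(ph, config.mri, seed=stage_seed(config.seed, "mri"))
        mri_path = workdir / FILES["mri"]
        pio.save_mri_nifti(mri_path, mri)
        cube = cp.extract_roi_cube(mri, config.trajectory, config.carpet.roi_length_mm)
        roi = cp.unfold_perimeter(cube)
        out = workdir / FILES["roi"]
        import h5py

        with h5py.File(out, "w") as f:
            f.create_dataset("unfolded", data=roi.data.astype(np.float32))
            f.create_dataset("cube", data=cube.data.astype(np.float32))
            f.attrs["slice_spacing_mm"] = roi.slice_spacing_mm
        pio.save_carpet_tiff(workdir / "unfolded_roi.tiff", roi.data, scale=10000.0)
        outputs = [mri_path, out, workdir / "unfolded_roi.tiff"]
    elif name == "barcode":
        import h5py

        carpet_path, roi_path = _require(workdir, "carpet", "roi")
        with h5py.File(carpet_path, "r") as f:
            ret = f["retardance"][()]
            mask = f["mask"][()]
            pitch = float(f.attrs["pitch_mm"])
        with h5py.File(roi_path, "r") as f:
            roi = f["unfolded"][()]
            spacing = float(f.attrs["slice_spacing_mm"])
        p_oct = bc.longitudinal_profile(ret, mask, pitch, "retardance",
                                        config.barcode.min_valid_fraction)
        p_mri = bc.longitudinal_profile(roi, None, spacing, "mri",
                                        config.barcode.min_valid_fraction)
        b_oct = bc.binarize(p_oct, bc.kmeans_1d(p_oct))
        b_mri = bc.binarize(p_mri, bc.kmeans_1d(p_mri))
        out = workdir / FILES["barcodes"]
        pio.write_json(out, {
            "psoct": {"code": b_oct.code.tolist(), "centers": list(b_oct.centers),
                      "threshold": b_oct.threshold, "spacing_mm": b_oct.spacing_mm},
            "mri": {"code": b_mri.code.tolist(), "centers": list(b_mri.centers),
                    "threshold": b_mri.threshold, "spacing_mm": b_mri.spacing_mm},
        })
        outputs = [out]
    elif name == "compare":
        (bar_path,) = _require(workdir, "barcodes")
        data = json.loads(bar_path.read_text())
        b_oct = bc.TissueBarcode(np.array(data["psoct"]["code"], np.uint8),
                                 tuple(data["psoct"]["centers"]),
                                 data["psoct"]["threshold"], data["psoct"]["spacing_mm"])
        b_mri = bc.TissueBarcode(np.array(data["mri"]["code"], np.uint8),
                                 tuple(data["mri"]["centers"]),
                                 data["mri"]["threshold"], data["mri"]["spacing_mm"])
        idx = np.floor(np.arange(len(b_oct.code)) * b_oct.spacing_mm / b_mri.spacing_mm
                       + 1e-9).astype(int)
        report = bc.compare_barcodes(b_oct, b_mri, idx)
        out = workdir / FILES["compare"]
        pio.write_json(out, report)
        outputs = [out]
    elif name == "render":
        (src,) = _require(workdir, "carpet")
        import h5py

        with h5py.File(src, "r") as f:
            view = cp.CarpetView(
                retardance=f["retardance"][()], orientation=f["orientation"][()],
                intensity=f["intensity"][()], mask=f["mask"][()],
                depth_offset_um=float(f.attrs["depth_offset_um"]),
                pitch_mm=float(f.attrs["pitch_mm"]),
                azimuth_deg=np.array([]),
            )
        rgb = cp.render_oa_hsv(view, config.carpet.display_max_deg_per_100um)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = workdir / FILES["render"]
        plt.imsave(out, rgb)
        outputs = [out]

    entry = {
        "stage": name,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": {p.name: pio.sha256_of(p) for p in outputs},
    }
    _manifest_append(workdir, entry)
    return entry


def run_all(config: PipelineConfig, workdir, stages=STAGES) -> list[dict]:
    return [run_stage(name, config, workdir) for name in stages]
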