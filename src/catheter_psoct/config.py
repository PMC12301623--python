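"""Pipeline configuration: YAML loading with strict validation.

Every numeric field is validated by its owning dataclass at construction
time; unknown keys anywhere in the file are rejected.  Units are explicit in
key names (mm, um, deg, rad).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .acquisition import AcquisitionConfig, CatheterModel
from .phantom import LayerSpec, MriRenderConfig, PhantomConfig, Trajectory
from .reconstruction import ReconstructionConfig

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class CarpetConfig:
    depth_offset_um: float = 300.0
    band_px: int = 2
    roi_length_mm: float = 21.0
    display_max_deg_per_100um: float = 30.0


@dataclass(frozen=True)
class BarcodeConfig:
    min_valid_fraction: float = 0.25


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    mri: MriRenderConfig = field(default_factory=MriRenderConfig)
    trajectory: Trajectory = field(default_factory=Trajectory)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    catheter: CatheterModel = field(default_factory=CatheterModel)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    carpet: CarpetConfig = field(default_factory=CarpetConfig)
    barcode: BarcodeConfig = field(default_factory=BarcodeConfig)
    seed: int = 0
    outdir: str = "results/pipeline"

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data, path):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = dict(data)
    if cls is PhantomConfig:
        for key in ("layers", "inclusions"):
            if key in kwargs:
                kwargs[key] = tuple(_layer(entry, f"{path}.{key}") for entry in kwargs[key])
    for key in ("entry_mm", "direction"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _layer(entry, path):
    if isinstance(entry, dict):
        names = {"tissue", "start_mm", "end_mm"}
        if set(entry) - names:
            raise ConfigError(f"{path}: unknown layer keys {sorted(set(entry) - names)}")
        return LayerSpec(**entry)
    if isinstance(entry, (list, tuple)) and len(entry) == 3:
        return LayerSpec(str(entry[0]), float(entry[1]), float(entry[2]))
    raise ConfigError(f"{path}: layer must be a mapping or a [tissue, start, end] triple")


_SECTIONS = {
    "phantom": PhantomConfig,
    "mri": MriRenderConfig,
    "trajectory": Trajectory,
    "acquisition": AcquisitionConfig,
    "catheter": CatheterModel,
    "reconstruction": ReconstructionConfig,
    "carpet": CarpetConfig,
    "barcode": BarcodeConfig,
}


def load_config(path=None, text=None, overrides=None) -> PipelineConfig:
    """Load a PipelineConfig from YAML (file path or literal text)."""
    if text is None:
        if path is None:
            data = {}
        else:
            with open(path) as f:
                data = yaml.safe_load(f) or {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed", "outdir"}
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name], name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "outdir" in data:
        kwargs["outdir"] = str(data["outdir"])
    cfg = PipelineConfig(**kwargs)
    if overrides:
        cfg = apply_overrides(cfg, overrides)
    return cfg


def apply_overrides(cfg: PipelineConfig, overrides: dict) -> PipelineConfig:
    """Apply {'section.key': value} overrides (CLI flags)."""
    updates: dict = {}
    for dotted, value in overrides.items():
        section, _, key = dotted.partition(".")
        if section in ("seed", "outdir") and not key:
            updates[section] = value
            continue
        if section not in _SECTIONS:
            raise ConfigError(f"unknown config section {section!r}")
        current = updates.get(section, getattr(cfg, section))
        if key not in {f.name for f in fields(type(current))}:
            raise ConfigError(f"unknown key {dotted!r}")
        updates[section] = replace(current, **{key: value})
    return replace(cfg, **updates)
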