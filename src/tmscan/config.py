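"""Run configuration: YAML/JSON loading with strict validation."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .forward import DEFAULT_PAIRING_RADIUS_MM, FreqSweep
from .grid import GridSpec
from .phantom import CohortSpec
from .recon import DEFAULT_FOOTPRINT_RADIUS_MM, TransformParams
from .segment import SegmentationConfig


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; all fields have defaults except
    the master seed, which must be supplied explicitly."""

    master_seed: int
    grid: GridSpec = field(default_factory=GridSpec)
    sweep: FreqSweep = field(default_factory=FreqSweep)
    transform: TransformParams = field(default_factory=TransformParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    pairing_radius_mm: float = DEFAULT_PAIRING_RADIUS_MM
    footprint_radius_mm: float = DEFAULT_FOOTPRINT_RADIUS_MM
    snr_db: float = 30.0
    views: tuple[str, ...] = ("LCC", "RCC", "LMLO", "RMLO")
    out_dir: str = "tmscan_out"
    save_phantoms: bool = True
    save_images: bool = True
    verbosity: str = "info"


_SECTION_TYPES = {
    "grid": GridSpec,
    "sweep": FreqSweep,
    "transform": TransformParams,
    "segmentation": SegmentationConfig,
    "cohort": CohortSpec,
}


def _build_section(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {path!r}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        sub = {f.name: f for f in dataclasses.fields(cls)}[key]
        if sub.name == "grid" and isinstance(value, dict):
            value = _build_section(GridSpec, value, f"{path}.grid")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    """Validated RunConfig; unknown keys are rejected with their names."""
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "master_seed" not in data:
        raise ValueError("config must set master_seed")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES and isinstance(value, dict):
            section = dict(value)
            if key == "cohort" and "grid" not in section and isinstance(data.get("grid"), dict):
                section["grid"] = data["grid"]
            value = _build_section(_SECTION_TYPES[key], section, key)
        elif key == "views" and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    cfg = RunConfig(**kwargs)
    # keep the cohort's phantom grid consistent with the run grid
    if cfg.cohort.grid != cfg.grid:
        cfg.cohort = dataclasses.replace(cfg.cohort, grid=cfg.grid)
    return cfg


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    out = dataclasses.asdict(cfg)
    out["cohort"].pop("grid", None)
    return _listify(out)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration with defaults applied."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(data if data is not None else {})


def save_config(path: str | Path, cfg: RunConfig) -> None:
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
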