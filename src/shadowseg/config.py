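"""Run configuration: TOML parsing, defaults, range checks, seeding."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .acquisition import DEFAULT_BACKGROUND, DEFAULT_BRIGHTNESS
from .optics import STEDConfig
from .phantom import PhantomConfig
from .segmentation import SegmentationParams

log = logging.getLogger("shadowseg")


@dataclass
class AcquisitionConfig:
    dwell_low_us: float = 10.0
    dwell_high_us: float = 70.0
    brightness_scale: float = DEFAULT_BRIGHTNESS
    background_rate: float = DEFAULT_BACKGROUND
    invert_on_save: bool = True


@dataclass
class RestorationConfig:
    kind: str = "vst_baseline"
    smoothing_scale: float | None = None  # None: dwell-adapted default
    n_members: int = 3


@dataclass
class OpticsConfig:
    sted: STEDConfig = field(default_factory=STEDConfig)
    pupil_samples: int = 96
    target_fwhm_nm: float = 130.0
    optics_voxel_nm: float = 25.0
    extent_nm: float = 2400.0


@dataclass
class RunConfig:
    """Typed configuration for an end-to-end reproducible run.

    Every stochastic stage derives its random stream from
    ``master_seed`` plus a fixed per-stage tag, so a serialized config
    fully determines all outputs.
    """

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    restoration: RestorationConfig = field(default_factory=RestorationConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    master_seed: int = 0
    output_dir: str = "shadowseg_run"
    stages: dict = field(default_factory=lambda: {
        "phantom": True, "psf": True, "acquire": True, "restore": True,
        "segment": True, "analyze": True, "evaluate": True})

    def stage_seed(self, tag: str) -> int:
        h = hashlib.sha256(f"{self.master_seed}:{tag}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2 ** 31 - 1)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_as_jsonable(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _apply(dc, block: dict, path: str):
    names = {f.name for f in dataclasses.fields(dc)}
    for key, value in block.items():
        if key not in names:
            raise ValueError(f"unknown config key [{path}] {key}")
        current = getattr(dc, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply(current, value, f"{path}.{key}")
        elif isinstance(current, tuple) and isinstance(value, list):
            setattr(dc, key, tuple(value))
        else:
            setattr(dc, key, value)


def validate_config(path: str | Path | None = None,
                    data: dict | None = None) -> RunConfig:
    """Parse a TOML config file, apply defaults and range-check.

    An empty file yields all defaults.  The agglomeration threshold must
    lie in (0, 1); values outside the validated 0.2-0.4 range are
    accepted with a logged warning.
    """
    if data is None:
        text = Path(path).read_text() if path is not None else ""
        data = tomllib.loads(text)
    cfg = RunConfig()
    for block_name in ("optics", "phantom", "acquisition", "restoration",
                       "segmentation"):
        if block_name in data:
            _apply(getattr(cfg, block_name), data[block_name], block_name)
    for key in ("master_seed", "output_dir"):
        if key in data:
            setattr(cfg, key, data[key])
    if "stages" in data:
        cfg.stages.update(data["stages"])

    theta = cfg.segmentation.threshold
    if not 0.0 < theta < 1.0:
        raise ValueError(f"agglomeration threshold {theta} outside (0, 1)")
    if not 0.2 <= theta <= 0.4:
        log.warning("agglomeration threshold %.2f outside the validated "
                    "0.2-0.4 range", theta)
    if cfg.acquisition.dwell_low_us >= cfg.acquisition.dwell_high_us:
        raise ValueError("dwell_low_us must be shorter than dwell_high_us")
    if cfg.acquisition.dwell_low_us <= 0:
        raise ValueError("dwell times must be positive")
    if cfg.phantom.voxel_size_nm <= 0:
        raise ValueError("voxel size must be positive")
    return cfg
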