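"""Run configuration: one YAML file wiring all stages, strict keys, seeded.

Schema (all sections optional; omitted keys take the dataclass defaults)::

    seed: 1                 # global seed; every stage derives its own from it
    colony_sim: {field_width_px: 1920, differentiated_fraction: 0.2, ...}
    cnn: {learning_rate: 1.0e-3, batch_size: 32, epochs: 10, ...}
    laser: {power_W: 0.8, speed_mm_s: 100.0, beam_width_um: 50.0,
            line_interval_um: 25.0}
    thermal: {D_mm2_s: 0.1, ambient_C: 29.5, ...}
    kill: {mode: dose_threshold, dose_threshold_J_mm2: 0.16, ...}
    targeting: {threshold: 0.5, stride_px: 70, oracle: false}

Unknown keys anywhere are rejected with the offending path in the message.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml

from .colony_sim import ColonySimParams
from .kill_eval import KillModel
from .patch_cnn import TrainHyper
from .scan_planner import LaserParams
from .photothermal import ThermalParams


@dataclass(frozen=True)
class TargetingConfig:
    threshold: float = 0.5
    stride_px: int = 70
    oracle: bool = False

    def __post_init__(self) -> None:
        if self.stride_px <= 0:
            raise ValueError("stride_px must be positive")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    colony_sim: ColonySimParams = field(default_factory=ColonySimParams)
    cnn: TrainHyper = field(default_factory=lambda: TrainHyper(seed=0))
    laser: LaserParams = field(
        default_factory=lambda: LaserParams(0.8, 100.0, 50.0, 25.0)
    )
    thermal: ThermalParams = field(default_factory=ThermalParams)
    kill: KillModel = field(default_factory=KillModel)
    targeting: TargetingConfig = field(default_factory=TargetingConfig)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


_SECTIONS = {
    "colony_sim": ColonySimParams,
    "cnn": TrainHyper,
    "laser": LaserParams,
    "thermal": ThermalParams,
    "kill": KillModel,
    "targeting": TargetingConfig,
}


def _build_section(name: str, cls, payload: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown key(s) in section '{name}': {sorted(unknown)}")
    obj = cls(**payload)
    if hasattr(obj, "validate"):
        obj.validate()
    return obj


def load_config(path: str | Path | None = None, overrides: dict | None = None,
                seed: int | None = None) -> RunConfig:
    """Parse a YAML config; CLI flag overrides win over file values."""
    payload: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        payload = raw
    for k, v in (overrides or {}).items():
        payload.setdefault(k, {})
        if isinstance(v, dict):
            payload[k] = {**payload[k], **v}
        else:
            payload[k] = v

    unknown = set(payload) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")

    global_seed = int(seed if seed is not None else payload.get("seed", 0))
    kwargs = {"seed": global_seed}
    for name, cls in _SECTIONS.items():
        section = dict(payload.get(name, {}))
        if name in ("colony_sim", "cnn") and "seed" not in section:
            digest = hashlib.sha256(f"{global_seed}:{name}".encode()).digest()
            section["seed"] = int.from_bytes(digest[:4], "big") % (2**31)
        kwargs[name] = _build_section(name, cls, section)
    return RunConfig(**kwargs)


def config_dict(cfg: RunConfig) -> dict:
    out = {"seed": cfg.seed}
    for name in _SECTIONS:
        out[name] = dataclasses.asdict(getattr(cfg, name))
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, cfg: RunConfig, command: str,
                   inputs: list[Path] | None = None,
                   outputs: list[Path] | None = None) -> Path:
    """Provenance record: config echo, seeds, version, file checksums."""
    try:
        pkg_version = version("lilack")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "command": command,
        "package_version": pkg_version,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config_dict(cfg),
        "inputs": {str(p): _sha256(Path(p)) for p in (inputs or [])},
        "outputs": {str(p): _sha256(Path(p)) for p in (outputs or [])},
    }
    path = Path(outdir) / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
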