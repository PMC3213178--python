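"""Run configuration and provenance.

A :class:`RunConfig` collects everything a pipeline stage needs — network
location, objective definitions, stimulus conditions, POETs schedule
constants, sensitivity and robustness settings — in one YAML-serialisable
object.  Every free constant of the method lives here, never inline in the
code.  A :class:`RunManifest` records the config hash, seeds and input
checksums so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .poets import POETSConfig
from .simulate import Condition, StimulusProtocol

__all__ = ["RunConfig", "RunManifest", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Invalid run configuration; the message carries the field path."""


@dataclass
class SensitivitySettings:
    window: tuple[float, float] = (0.0, 100.0)
    k_vectors: int | None = None  # default: 95% spectral energy
    threshold: float = 0.001
    member_fraction: float = 0.1  # ensemble subsample for sensitivity
    condition: str = "insulin"


@dataclass
class RobustnessSettings:
    marker: str = "R80S"
    delta: float = 0.1
    c_severe: float = 0.25
    window: tuple[float, float] | None = None  # default: protocol horizon
    conditions: tuple[str, ...] = ("insulin", "basal")
    targets: tuple[str, ...] = ()


@dataclass
class RunConfig:
    network: str = "network.txt"
    network_format: str | None = None
    objectives: str = "objectives/objectives.yaml"
    output_dir: str = "results"
    seed: int = 0
    conditions: dict[str, Condition] = field(default_factory=dict)
    poets: POETSConfig = field(default_factory=POETSConfig)
    sensitivity: SensitivitySettings = field(default_factory=SensitivitySettings)
    robustness: RobustnessSettings = field(default_factory=RobustnessSettings)
    solver: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "network": self.network,
            "network_format": self.network_format,
            "objectives": self.objectives,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "solver": dict(self.solver),
            "poets": asdict(self.poets),
            "sensitivity": asdict(self.sensitivity),
            "robustness": asdict(self.robustness),
            "conditions": {
                name: {
                    "stimulus_species": list(c.protocol.stimulus_species),
                    "stimulus_amount": c.protocol.stimulus_amount,
                    "stimulus_time": c.protocol.stimulus_time,
                    "horizon": c.protocol.horizon,
                    "rate_multipliers": dict(c.rate_multipliers),
                    "knockdowns": list(c.knockdowns),
                }
                for name, c in self.conditions.items()
            },
        }
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def _expect(mapping: Mapping, key: str, types, path: str, default=None):
    if key not in mapping:
        if default is not None or key in ("network_format",):
            return default
        raise ConfigError(f"missing config field {path}.{key}")
    val = mapping[key]
    if types is not None and not isinstance(val, types):
        raise ConfigError(
            f"config field {path}.{key} has type {type(val).__name__}, "
            f"expected {types}"
        )
    return val


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    conditions: dict[str, Condition] = {}
    for name, c in (raw.get("conditions") or {}).items():
        p = f"conditions.{name}"
        horizon = float(_expect(c, "horizon", (int, float), p, 100.0))
        if horizon <= 0:
            raise ConfigError(f"{p}.horizon must be > 0")
        protocol = StimulusProtocol(
            tuple(c.get("stimulus_species", ())),
            float(c.get("stimulus_amount", 0.0)),
            float(c.get("stimulus_time", 0.0)),
            horizon,
        )
        conditions[name] = Condition(
            name,
            protocol,
            rate_multipliers={
                str(k): float(v) for k, v in (c.get("rate_multipliers") or {}).items()
            },
            knockdowns=tuple(c.get("knockdowns", ())),
        )
    poets_raw = raw.get("poets") or {}
    unknown = set(poets_raw) - set(POETSConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown poets config keys: {sorted(unknown)}")
    sens_raw = dict(raw.get("sensitivity") or {})
    if "window" in sens_raw:
        w = tuple(float(v) for v in sens_raw["window"])
        if len(w) != 2 or not w[1] > w[0]:
            raise ConfigError(f"sensitivity.window must be (start, end) with end > start, got {w}")
        sens_raw["window"] = w
    rob_raw = dict(raw.get("robustness") or {})
    if rob_raw.get("window") is not None:
        rob_raw["window"] = tuple(float(v) for v in rob_raw["window"])
    if "conditions" in rob_raw:
        rob_raw["conditions"] = tuple(rob_raw["conditions"])
    if "targets" in rob_raw:
        rob_raw["targets"] = tuple(
            tuple(t) if isinstance(t, list) else t for t in rob_raw["targets"]
        )
    return RunConfig(
        network=str(_expect(raw, "network", str, "", "network.txt")),
        network_format=raw.get("network_format"),
        objectives=str(raw.get("objectives", "objectives/objectives.yaml")),
        output_dir=str(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
        conditions=conditions,
        poets=POETSConfig(**poets_raw),
        sensitivity=SensitivitySettings(**sens_raw),
        robustness=RobustnessSettings(**rob_raw),
        solver=dict(raw.get("solver") or {}),
    )


def config_hash(config_dict: Mapping) -> str:
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written atomically at the end of every stage."""

    stage: str
    config_hash: str
    seed: int
    software_version: str = ""
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    wall_seconds: float = 0.0
    extra: dict[str, Any] = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _checksum(p)

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        target = directory / f"manifest_{self.stage}.json"
        tmp = target.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(asdict(self), indent=1, default=str))
        os.replace(tmp, target)
        return target


class StageTimer:
    """Context manager stamping wall time into a manifest."""

    def __init__(self, manifest: RunManifest):
        self.manifest = manifest

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self.manifest

    def __exit__(self, *exc):
        self.manifest.wall_seconds = time.perf_counter() - self._t0
        return False
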