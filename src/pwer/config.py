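"""Configuration loading and validation for studies and trial analyses."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .simulate import ConfigError, SimulationConfig

__all__ = ["AnalysisSettings", "load_config", "load_analysis_settings", "dump_config"]

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclass(frozen=True)
class AnalysisSettings:
    """Settings for analysing a patient-level trial dataset."""

    alpha: float = 0.025
    regime: str = "unknown-homogeneous"
    estimator: str = "mle"  # mle | marginal | file
    prevalence_file: str | None = None
    pi_min: float | str | None = None  # None (off) | "auto" | value
    mode: str = "pwer"  # pwer | fwer | unadjusted
    tail_points: int = 2**13

    def __post_init__(self) -> None:
        problems = []
        if not 0.0 < self.alpha < 1.0:
            problems.append(f"alpha={self.alpha} outside the open interval (0, 1)")
        if self.estimator not in ("mle", "marginal", "file"):
            problems.append(f"unknown estimator {self.estimator!r}")
        if self.estimator == "file" and not self.prevalence_file:
            problems.append("estimator 'file' needs prevalence_file")
        if self.mode not in ("pwer", "fwer", "unadjusted"):
            problems.append(f"unknown mode {self.mode!r}")
        if problems:
            raise ConfigError("; ".join(problems))


def _read_mapping(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return data


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a simulation config from YAML or JSON.

    Unknown keys and out-of-range values are reported together.
    """
    data = _read_mapping(path)
    unknown = sorted(set(data) - _SIM_FIELDS)
    problems = [f"unknown key {k!r}" for k in unknown]
    if problems:
        raise ConfigError("; ".join(problems))
    for key in ("prob_support", "sigma2_law"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return SimulationConfig(**data)


def load_analysis_settings(path: str | Path) -> AnalysisSettings:
    data = _read_mapping(path)
    known = {f.name for f in dataclasses.fields(AnalysisSettings)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError("; ".join(f"unknown key {k!r}" for k in unknown))
    return AnalysisSettings(**data)


def dump_config(cfg: SimulationConfig | AnalysisSettings) -> dict[str, Any]:
    """Normalized plain-dict form of a config (round-trips through load)."""
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, tuple):
            v = list(v)
        elif hasattr(v, "tolist"):
            v = v.tolist()
        out[f.name] = v
    return out
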