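"""Experiment configuration: structured-text (YAML) round trip with defaults.

A configuration file only needs to list the values that differ from the
model defaults (the reference synapse parameters and simulation-detail
values); an empty file yields the full default configuration.  Unknown keys
and invariant violations raise a descriptive error, and
``load_config(save_config(cfg))`` is the identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .dynamics import LearningConfig, PriorSpec
from .network import RecorderConfig

_TASKS = ("routing", "lever", "stdp", "background")


@dataclass
class ExperimentConfig:
    """Fully resolved description of one simulation run."""

    task: str = "routing"
    seed: int = 0
    duration_s: float = 3600.0
    learning: LearningConfig = field(default_factory=LearningConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    recorders: RecorderConfig = field(default_factory=RecorderConfig)
    # task manipulations (seconds; None = never)
    task_switch_at_s: Optional[float] = None
    no_rewiring_after_s: Optional[float] = None
    consolidate_at_s: Optional[float] = None
    # routing reward parameters
    reward_threshold_hz: float = 25.0
    reward_slope_hz: float = 5.0

    def __post_init__(self) -> None:
        if self.task not in _TASKS:
            raise ValueError(f"unknown task {self.task!r}; choose from {_TASKS}")
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")


def _to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    prior = d["prior"]
    if isinstance(prior.get("mu"), np.ndarray):
        prior["mu"] = prior["mu"].tolist()
    lb = d["learning"].get("theta_bounds")
    if lb is not None:
        d["learning"]["theta_bounds"] = list(lb)
    return d


def _from_dict(data: dict) -> ExperimentConfig:
    data = dict(data or {})
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    def sub(cls, key):
        raw = data.pop(key, {}) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - names
        if bad:
            raise ValueError(f"unknown {key} keys: {sorted(bad)}")
        if key == "learning" and raw.get("theta_bounds") is not None:
            raw["theta_bounds"] = tuple(raw["theta_bounds"])
        return cls(**raw)

    learning = sub(LearningConfig, "learning")
    prior = sub(PriorSpec, "prior")
    recorders = sub(RecorderConfig, "recorders")
    return ExperimentConfig(
        learning=learning, prior=prior, recorders=recorders, **data
    )


def load_config(path) -> ExperimentConfig:
    """Read a YAML experiment configuration, applying defaults for absent keys."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a mapping")
    return _from_dict(data)


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=True))


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable hash of the fully resolved configuration."""
    blob = json.dumps(_to_dict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
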