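"""Run configuration: validated, serializable, hashable.

A :class:`RunConfig` captures everything needed to reproduce a simulation:
model family, task dimensionality and length, every oscillator/RL/learning
parameter, the master seed and the replication count.  Configs round-trip
through YAML or JSON, unknown keys are rejected, and a short content hash
is embedded in output files so analysis inputs can be matched to the run
that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .experiment import MODEL_KINDS, SimParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    model: str = "rw-full"
    beta: float = 0.2
    n_dims: int = 1
    n_trials: int | None = None     # default: 360 (1-D) or 3600 (multi-D)
    n_blocks: int = 6
    n_reps: int = 1
    seed: int = 0
    proc_freq: float = 40.0
    proc_damp: float = 0.3
    proc_r_min: float = 1.0
    ctrl_freq: float = 5.0
    ctrl_damp: float = 0.003
    ctrl_r_min: float = 0.05
    ctrl_init_radius: float = 1.0
    bias: float = 5.0
    trial_steps: int = 500
    iti_steps: int = 250
    input_drive: float = 1.0
    nodes_per_module: int | None = None
    alpha: float | None = None
    sigma: float | None = None
    switch_threshold: float = 0.5
    q_init: float | None = None
    inhibition: float = 2.0
    inhibition_decay: float = 0.9

    def __post_init__(self) -> None:
        if self.model not in MODEL_KINDS:
            raise ValueError(f"model must be one of {MODEL_KINDS}, "
                             f"got {self.model!r}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if self.n_dims not in (1, 2, 3):
            raise ValueError("n_dims must be 1, 2 or 3")
        if self.n_reps < 1 or self.n_blocks < 1:
            raise ValueError("n_reps and n_blocks must be positive")
        if self.iti_steps >= self.trial_steps:
            raise ValueError("iti_steps must be shorter than trial_steps")

    @property
    def task_length(self) -> int:
        if self.n_trials is not None:
            return self.n_trials
        return 360 if self.n_dims == 1 else 3600

    def sim_params(self) -> SimParams:
        keep = {f.name for f in fields(SimParams)}
        return SimParams(**{k: v for k, v in asdict(self).items() if k in keep})

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON config; unknown or invalid fields raise ValueError."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
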