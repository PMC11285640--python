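"""Run configuration, deterministic per-stage seed derivation, YAML I/O."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .ensemble_ipm import GbcHyperparams
from .neural_model import MlpHyperparams
from .sensitivity import ImputationConfig
from .synthetic_claims import SimulationConfig, ConfigurationError

__all__ = ["RunConfig", "derive_seed", "load_config", "save_config", "config_hash"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (master seed, stage tag), < 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs.

    Every stochastic stage derives its own seed from ``master_seed`` and
    a stage tag, so stages never share random streams and the whole run
    is reproducible from one integer.
    """

    master_seed: int = 0
    output_dir: str = "run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mlp: MlpHyperparams = field(default_factory=MlpHyperparams)
    gbc: GbcHyperparams = field(default_factory=GbcHyperparams)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    train_fraction: float = 0.8
    threshold: float = 0.5
    report_decimals: int = 2
    sensitivity_rate: float = 0.4
    run_sensitivity: bool = True
    n_bootstrap: int = 2000

    def validate(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if not (0 <= self.threshold <= 1):
            raise ConfigurationError("threshold must lie in [0, 1]")
        if not (0 <= self.sensitivity_rate < 1):
            raise ConfigurationError("sensitivity_rate must lie in [0, 1)")
        self.simulation.validate()

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.master_seed, stage)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mlp"]["hidden_layer_spec"] = list(self.mlp.hidden_layer_spec)
        return d


_NESTED = {
    "simulation": SimulationConfig,
    "mlp": MlpHyperparams,
    "gbc": GbcHyperparams,
    "imputation": ImputationConfig,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    if cls is MlpHyperparams and "hidden_layer_spec" in data:
        data = dict(data, hidden_layer_spec=tuple(data["hidden_layer_spec"]))
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys fail before any compute."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in raw.items():
        if key in _NESTED:
            kwargs[key] = _build(_NESTED[key], value or {})
        else:
            kwargs[key] = value
    cfg = _build(RunConfig, kwargs)
    cfg.validate()
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
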