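"""Run configuration, seeding, and manifests.

A run is fully specified by a :class:`RunConfig` (all model constants,
defaulting to the values the model was designed with) plus a single
master seed.  The master seed fans out deterministically to one child
seed per stochastic component (environment generation, weight
initialisation, exploration, evaluation), so every artifact is
reproducible from (config, seed) alone; a manifest records the config
hash, seeds, and package version alongside results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "RunConfig",
    "load_config",
    "save_config",
    "run_manifest",
    "child_seeds",
]


class ConfigurationError(ValueError):
    """A config file failed validation."""


@dataclass
class NeuronConfig:
    v_threshold: float = -55.0
    v_rest: float = -75.0
    tau_m: float = 20.0
    membrane_resistance: float = 1.0
    dt: float = 1.0


@dataclass
class PlasticityConfig:
    a_plus: float = 0.925
    a_minus: float = 0.1
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    tau_e: float = 5.0
    learning_rate: float = 0.1


@dataclass
class ToMConfig:
    gamma: float = 2.0
    beta: float = 1.0


@dataclass
class ScoreConfig:
    r_base: float = 50.0
    c_time: float = 3.0
    l_collision: float = 40.0
    l_help: float = 10.0


@dataclass
class TrainingSection:
    policy_episodes: int = 300
    tom_episodes: int = 300
    window_length: int = 20
    exploration_epsilon: float = 1.0
    epsilon_min: float = 0.05
    step_cap: int = 30


@dataclass
class RunConfig:
    """Complete, validated run configuration with model defaults."""

    neuron: NeuronConfig = field(default_factory=NeuronConfig)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    tom: ToMConfig = field(default_factory=ToMConfig)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    training: TrainingSection = field(default_factory=TrainingSection)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        if not self.neuron.v_threshold > self.neuron.v_rest:
            raise ConfigurationError("neuron.v_threshold must exceed neuron.v_rest")
        for name in ("tau_m", "dt"):
            if getattr(self.neuron, name) <= 0:
                raise ConfigurationError(f"neuron.{name} must be positive")
        for name in ("tau_plus", "tau_minus", "tau_e"):
            if getattr(self.plasticity, name) <= 0:
                raise ConfigurationError(f"plasticity.{name} must be positive")
        if self.plasticity.a_plus < 0 or self.plasticity.a_minus < 0:
            raise ConfigurationError("plasticity amplitudes must be non-negative")
        for name in ("r_base", "c_time", "l_collision", "l_help"):
            if getattr(self.score, name) < 0:
                raise ConfigurationError(f"score.{name} must be non-negative")
        if self.training.policy_episodes < 0 or self.training.tom_episodes < 0:
            raise ConfigurationError("training episode counts must be >= 0")
        if not 0 <= self.training.exploration_epsilon <= 1:
            raise ConfigurationError("training.exploration_epsilon must be in [0, 1]")
        if self.training.window_length < 1:
            raise ConfigurationError("training.window_length must be >= 1")


_SECTIONS = {
    "neuron": NeuronConfig,
    "plasticity": PlasticityConfig,
    "tom": ToMConfig,
    "score": ScoreConfig,
    "training": TrainingSection,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in section '{section}': {', '.join(sorted(unknown))}"
        )
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load a YAML config; omitted keys take the model defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    sections = {
        name: _build_section(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    cfg = RunConfig(seed=int(data.get("seed", 0)), **sections)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    canonical = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def child_seeds(master: int, n: int) -> list[int]:
    """Deterministic per-component child seeds (each below 2**31)."""
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def run_manifest(cfg: RunConfig, weight_files: dict | None = None) -> dict:
    """Reproducibility record for one run.

    ``weight_files`` maps a role name to a file path; each file's sha256
    is recorded so results can be tied to exact weights.
    """
    from . import __version__

    checksums = {}
    for role, path in (weight_files or {}).items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            h.update(fh.read())
        checksums[role] = h.hexdigest()
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "package_version": __version__,
        "weight_checksums": checksums,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    return manifest
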