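"""Declarative run configuration: one document driving corpus, training and
experiment protocol, with strict key validation and a stable content hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .al_loop import STRATEGIES, ExperimentConfig
from .lpm import TrainConfig
from .plcm import DEFAULT_ALPHAS, DEFAULT_Z
from .synthetic import CorpusSpec, NoiseParams

__all__ = ["ConfigError", "RunConfig", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Unknown keys, bad types, or out-of-range configuration values."""


def _strict(cls, mapping, section):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown {section} keys: {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section} section: {exc}") from exc


@dataclass(frozen=True)
class CorpusSection:
    n_per_class: int = 1000
    noise_fraction: float = 0.058
    patch_size: int = 32
    n_test_per_class: int = 100
    empty_foreign_share: float = 0.5
    seed: int = 0

    def to_spec(self) -> CorpusSpec:
        try:
            return CorpusSpec(
                n_clean_per_class=self.n_per_class,
                noise_fraction=self.noise_fraction,
                patch_size=self.patch_size,
                n_test_per_class=self.n_test_per_class,
                noise_params=NoiseParams(empty_foreign_share=self.empty_foreign_share),
                seed=self.seed,
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass(frozen=True)
class TrainSection:
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    momentum: float = 0.5
    lam: float = 1.0
    epsilon: float = 1.0

    def to_train_config(self, seed: int = 0) -> TrainConfig:
        try:
            return TrainConfig(seed=seed, **asdict(self))
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass(frozen=True)
class ExperimentSection:
    iterations: int = 10
    budget: int = 100
    initial_labeled: int = 100
    trials: int = 5
    alpha: float | list[float] = field(default_factory=lambda: list(DEFAULT_ALPHAS))
    z_epochs: int = DEFAULT_Z
    collect: str = "predicted"
    bald_passes: int = 25


@dataclass(frozen=True)
class RunConfig:
    """The full declarative document; unknown keys are rejected, missing keys
    take the documented defaults, and the hash is stable under key order."""

    corpus: CorpusSection = field(default_factory=CorpusSection)
    train: TrainSection = field(default_factory=TrainSection)
    experiment: ExperimentSection = field(default_factory=ExperimentSection)
    strategy: str = "proposed"
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"strategy must be one of {STRATEGIES}")
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {self.schema_version}")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        if not isinstance(doc, dict):
            raise ConfigError("configuration document must be a mapping")
        allowed = {"corpus", "train", "experiment", "strategy", "seed", "schema_version"}
        unknown = set(doc) - allowed
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        return cls(
            corpus=_strict(CorpusSection, doc.get("corpus", {}), "corpus"),
            train=_strict(TrainSection, doc.get("train", {}), "train"),
            experiment=_strict(ExperimentSection, doc.get("experiment", {}), "experiment"),
            strategy=doc.get("strategy", "proposed"),
            seed=int(doc.get("seed", 0)),
            schema_version=int(doc.get("schema_version", SCHEMA_VERSION)),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_experiment_config(self) -> ExperimentConfig:
        e = self.experiment
        alphas = tuple(e.alpha) if isinstance(e.alpha, (list, tuple)) else float(e.alpha)
        try:
            return ExperimentConfig(
                iterations=e.iterations,
                budget=e.budget,
                initial_labeled=e.initial_labeled,
                trials=e.trials,
                alphas=alphas,
                z_epochs=e.z_epochs,
                collect=e.collect,
                bald_passes=e.bald_passes,
                train=self.train.to_train_config(seed=self.seed),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def render_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML (or JSON) config document with strict key checking."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return RunConfig.from_dict(doc or {})
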