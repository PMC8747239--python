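"""Experiment configuration: YAML round-trip, validation, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .synth import CohortConfig
from .lstm import Hyperparams
from .evaluate import SCHEMES


@dataclass
class PreprocessParams:
    cutoff_hz: float = 4.0
    order: int = 4
    median_window: int = 5

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be > 0")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.median_window % 2 == 0 or self.median_window < 1:
            raise ValueError("median_window must be odd and >= 1")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one full run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    threshold: float = 0.30
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    schemes: tuple[str, ...] = SCHEMES
    k_folds: int = 5
    split_seed: int = 0
    model_seed: int = 0
    use_true_range: bool = False
    out_dir: str = "report"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.preprocess.cutoff_hz >= self.cohort.kin_rate_hz / 2:
            raise ValueError("cutoff must be below the kinematic Nyquist rate")
        for s in self.schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown scheme {s!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schemes"] = list(self.schemes)
        d["hyperparams"]["loss_weights"] = list(
            self.hyperparams.loss_weights)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SECTION_TYPES = {"cohort": CohortConfig, "preprocess": PreprocessParams,
                  "hyperparams": Hyperparams}
_SCALAR_KEYS = {"threshold", "schemes", "k_folds", "split_seed",
                "model_seed", "use_true_range", "out_dir"}


def _build_section(cls, d: dict, name: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    if cls is Hyperparams and "loss_weights" in d:
        d = {**d, "loss_weights": tuple(d["loss_weights"])}
    return cls(**d)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config; unknown keys fail fast."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _SCALAR_KEYS - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name] or {}, name)
    for key in _SCALAR_KEYS & set(raw):
        kwargs[key] = tuple(raw[key]) if key == "schemes" else raw[key]
    return ExperimentConfig(**kwargs)


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
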