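"""Run configuration: every tunable of the pipeline in one validated object.

Defaults follow the study protocol the pipeline targets: five 4-Hz bands
covering 1-20 Hz, four CSP filter pairs per band (40 features), a temporal
2/3-1/3 train/test split and 10,000 permutations for significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .ovo import ClassifierSpec
from .preprocess import BandSpec, DEFAULT_BANDS, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    n_filter_pairs: int = 4
    alpha: float = 5.0
    tol: float = 1e-4
    max_iter: int = 100
    train_fraction: float = 2.0 / 3.0
    n_perm: int = 10_000
    amplitude_limit_uV: float = 75.0
    window_length: float = 1.5
    classifier: str = "lda"
    classifier_params: dict = field(default_factory=dict)
    seed_simulation: int = 0
    seed_am: int = 1
    seed_permutation: int = 2
    seed_classifier: int = 3

    def __post_init__(self) -> None:
        BandSpec(tuple(tuple(b) for b in self.bands))  # validates
        if self.n_filter_pairs < 1:
            raise InvalidInputError("n_filter_pairs must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise InvalidInputError("train_fraction must be in (0, 1)")
        if self.n_perm < 100:
            raise InvalidInputError("n_perm must be >= 100")
        if self.alpha < 0 or self.tol <= 0 or self.max_iter < 1:
            raise InvalidInputError("require alpha >= 0, tol > 0, max_iter >= 1")
        if self.amplitude_limit_uV <= 0 or self.window_length <= 0:
            raise InvalidInputError("limits and window must be positive")

    def band_spec(self) -> BandSpec:
        return BandSpec(tuple(tuple(b) for b in self.bands))

    def classifier_spec(self) -> ClassifierSpec:
        return ClassifierSpec(
            name=self.classifier,
            params=dict(self.classifier_params),
            seed=self.seed_classifier,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in raw:
            raw["bands"] = tuple(tuple(b) for b in raw["bands"])
        cfg = cls(**raw)
        logger.info("loaded config: %s", cfg.to_dict())
        return cfg

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["bands"] = [list(b) for b in d["bands"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
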