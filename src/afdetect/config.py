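"""Run configuration: one serializable object covering every pipeline stage.

Defaults reproduce the reference settings: 31-feature extraction, 20-fold
cross-validation, top-17 feature selection, 0.8/0.2 train/test split, 30 s
segments, and the Table of training hyperparameters behind
:class:`afdetect.model.HyperParams`.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .model import HyperParams
from .preprocess import FilterSpec


@dataclass
class RunConfig:
    filter: FilterSpec = field(default_factory=FilterSpec)
    hyperparams: HyperParams = field(default_factory=HyperParams)
    k_select: int = 17
    n_folds: int = 20
    test_fraction: float = 0.2
    segment_s: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.k_select < 1 or self.n_folds < 2 or self.segment_s <= 0:
            raise ValueError("invalid config values")

    def to_dict(self) -> dict:
        return {
            "filter": dataclasses.asdict(self.filter),
            "hyperparams": dataclasses.asdict(self.hyperparams),
            "k_select": self.k_select,
            "n_folds": self.n_folds,
            "test_fraction": self.test_fraction,
            "segment_s": self.segment_s,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(
            filter=FilterSpec(**d.get("filter", {})),
            hyperparams=HyperParams(**d.get("hyperparams", {})),
            k_select=d.get("k_select", 17),
            n_folds=d.get("n_folds", 20),
            test_fraction=d.get("test_fraction", 0.2),
            segment_s=d.get("segment_s", 30.0),
            seed=d.get("seed", 0),
        )
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: Optional[str] = None, seed: Optional[int] = None) -> "RunConfig":
        d = {}
        if path:
            d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls.from_dict(d)
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=seed)
            hp = dataclasses.replace(cfg.hyperparams, random_seed=seed)
            cfg = dataclasses.replace(cfg, hyperparams=hp)
        return cfg

    def dump(self, path) -> None:
        """Write the resolved configuration beside a stage's outputs."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
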