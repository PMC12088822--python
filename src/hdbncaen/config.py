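"""Flat YAML run configuration with strict key checking.

Defaults follow the framework's published tuning: learning rate 0.001 decayed
by ×0.1 every 10 epochs, dropout 0.5, early-stopping patience 5, batch 64 for
tabular data (32 for image grids), 70/15/15 stratified split.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .ensemble import CAENConfig
from .hdbn import TrainConfig
from .synthdata import SynthSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # global
    seed: int = 0
    # synthesis
    n_samples: int = 1000
    n_numeric: int = 4
    n_categorical: int = 2
    n_timeseries: int = 0
    class_prior: float = 0.5
    mean_separation: float = 1.0
    categorical_skew: float = 0.3
    ts_length: int = 20
    ar_coefficient: float = 0.5
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    # preprocessing
    outlier_method: str = "iqr"
    z_threshold: float = 3.0
    remove_outliers: bool = True
    knn_k: int = 5
    train_frac: float = 0.70
    valid_frac: float = 0.15
    test_frac: float = 0.15
    # training
    learning_rate: float = 0.001
    lr_decay: float = 0.1
    lr_decay_every: int = 10
    batch_size: int = 64
    epochs: int = 30
    cd_k: int = 1
    l2: float = 1e-4
    dropout: float = 0.5
    patience: int = 5
    optimizer: str = "sgd"
    hdbn_layers: tuple = (16, 8)
    dense_hidden: tuple = (32, 16)
    attention_dim: int = 16
    performance_threshold: float = 0.0
    max_recalibration: int = 10
    # metrics
    patch_size: int = 16
    agreement_threshold: float = 0.9

    def synth_spec(self) -> SynthSpec:
        return SynthSpec(
            n_samples=self.n_samples, n_numeric=self.n_numeric,
            n_categorical=self.n_categorical, n_timeseries=self.n_timeseries,
            class_prior=self.class_prior, mean_separation=self.mean_separation,
            categorical_skew=self.categorical_skew, ts_length=self.ts_length,
            ar_coefficient=self.ar_coefficient, missing_rate=self.missing_rate,
            outlier_rate=self.outlier_rate, seed=self.seed)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, lr_decay=self.lr_decay,
            lr_decay_every=self.lr_decay_every, batch_size=self.batch_size,
            epochs=self.epochs, cd_k=self.cd_k, l2=self.l2,
            dropout=self.dropout, patience=self.patience,
            optimizer=self.optimizer, seed=self.seed)

    def caen_config(self) -> CAENConfig:
        return CAENConfig(
            train=self.train_config(), hdbn_layers=tuple(self.hdbn_layers),
            dense_hidden=tuple(self.dense_hidden),
            attention_dim=self.attention_dim,
            performance_threshold=self.performance_threshold,
            max_recalibration=self.max_recalibration)

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.train_frac, self.valid_frac, self.test_frac)

    @classmethod
    def from_dict(cls, overrides: dict) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = sorted(set(overrides) - set(known))
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        bad_types = []
        coerced = {}
        for k, v in overrides.items():
            want = known[k].type
            if want in ("int",) and not isinstance(v, int):
                bad_types.append(k)
            elif want == "float" and not isinstance(v, (int, float)):
                bad_types.append(k)
            elif want == "bool" and not isinstance(v, bool):
                bad_types.append(k)
            elif want == "str" and not isinstance(v, str):
                bad_types.append(k)
            elif want == "tuple":
                if not isinstance(v, (list, tuple)):
                    bad_types.append(k)
                else:
                    v = tuple(v)
            coerced[k] = v
        if bad_types:
            raise ValueError(f"badly typed configuration keys: {sorted(bad_types)}")
        return cls(**coerced)


def load_config(path: str | Path | None) -> RunConfig:
    """Parse a flat YAML config file; an empty/absent file yields defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    payload = yaml.safe_load(text) or {}
    if not isinstance(payload, dict):
        raise ValueError("config file must contain a key-value mapping")
    return RunConfig.from_dict(payload)
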