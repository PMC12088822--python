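"""Shared containers: feature schema and labeled mixed-type datasets.

A :class:`LabeledDataset` holds a flat :class:`pandas.DataFrame` of feature
columns plus a binary label vector.  Time-series features are stored expanded,
one column per time step (``name_t0 .. name_t{T-1}``), so that imputation,
scaling and CSV round-trips treat every cell uniformly; the schema records the
grouping so sequence-aware models can reassemble the channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Feature", "FeatureSchema", "LabeledDataset"]

KINDS = ("numeric", "categorical-nominal", "categorical-ordinal", "timeseries")


@dataclass(frozen=True)
class Feature:
    """One declared feature: a name, a kind, and kind-specific detail.

    ``levels`` is the category vocabulary (ordered for ordinal features);
    ``length`` is the number of time steps for time-series features.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical-ordinal" and not self.levels:
            raise ValueError(f"ordinal feature {self.name!r} needs an ordered level list")
        if self.kind == "timeseries" and (self.length is None or self.length < 1):
            raise ValueError(f"timeseries feature {self.name!r} needs a positive length")

    @property
    def columns(self) -> tuple[str, ...]:
        if self.kind == "timeseries":
            return tuple(f"{self.name}_t{j}" for j in range(int(self.length)))
        return (self.name,)

    @property
    def is_categorical(self) -> bool:
        return self.kind.startswith("categorical")


@dataclass(frozen=True)
class FeatureSchema:
    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def columns(self) -> list[str]:
        return [c for f in self.features for c in f.columns]

    def of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    @property
    def numeric_columns(self) -> list[str]:
        """All real-valued cell columns (numeric features + time-series steps)."""
        return [c for f in self.of_kind("numeric", "timeseries") for c in f.columns]

    @property
    def categorical_columns(self) -> list[str]:
        return [f.name for f in self.features if f.is_categorical]

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"name": f.name, "kind": f.kind,
             "levels": list(f.levels) if f.levels else None, "length": f.length}
            for f in self.features
        ]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        return cls(tuple(
            Feature(d["name"], d["kind"],
                    tuple(d["levels"]) if d.get("levels") else None, d.get("length"))
            for d in payload
        ))


@dataclass
class LabeledDataset:
    """Feature table + binary labels + schema.

    ``frame`` columns follow ``schema.columns`` exactly; numeric cells are
    floats with NaN marking missingness, categorical cells are strings with
    NaN marking missingness.  ``y`` is an int array of 0/1 labels, one per row.
    """

    frame: pd.DataFrame
    y: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.frame) != len(self.y):
            raise ValueError("label count must equal row count")
        if self.y.size and not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if list(self.frame.columns) != self.schema.columns:
            raise ValueError("frame columns do not match schema")

    def __len__(self) -> int:
        return len(self.frame)

    def copy(self) -> "LabeledDataset":
        return LabeledDataset(self.frame.copy(), self.y.copy(), self.schema)

    def take(self, idx: Iterable[int]) -> "LabeledDataset":
        idx = np.asarray(list(idx), dtype=int)
        return LabeledDataset(self.frame.iloc[idx].reset_index(drop=True),
                              self.y[idx], self.schema)

    def numeric_matrix(self) -> np.ndarray:
        return self.frame[self.schema.numeric_columns].to_numpy(dtype=float)

    def timeseries_tensor(self) -> np.ndarray:
        """Stack time-series features into (n, T, channels); empty if none."""
        ts = self.schema.of_kind("timeseries")
        if not ts:
            return np.zeros((len(self), 0, 0))
        chans = [self.frame[list(f.columns)].to_numpy(dtype=float) for f in ts]
        return np.stack(chans, axis=-1)  # (n, T, n_channels)

    # -- plain-text persistence (CSV + JSON sidecar) ------------------------

    def to_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        out = self.frame.copy()
        out.insert(0, "label", self.y)
        out.to_csv(path, index=False)
        if schema_path is not None:
            self.schema.to_json(schema_path)

    @classmethod
    def from_csv(cls, path: str | Path, schema: FeatureSchema | str | Path) -> "LabeledDataset":
        if not isinstance(schema, FeatureSchema):
            schema = FeatureSchema.from_json(schema)
        frame = pd.read_csv(path)
        y = frame.pop("label").to_numpy(dtype=int)
        cat = set()
        for f in schema.features:
            if f.is_categorical:
                cat.add(f.name)
        for c in frame.columns:
            if c in cat:
                frame[c] = frame[c].astype(object).where(frame[c].notna(), np.nan)
                frame[c] = frame[c].map(lambda v: v if (isinstance(v, float) and np.isnan(v)) else str(v))
            else:
                frame[c] = frame[c].astype(float)
        return cls(frame[schema.columns], y, schema)
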