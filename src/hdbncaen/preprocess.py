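"""Clinical tabular preprocessing: clean, flag outliers, scale, encode, split.

Every fitted quantity (imputation statistics, scaler parameters, PCA loadings,
selected features) is estimated on the training part only and applied frozen
to validation/test — the split indices are drawn first, from labels alone, so
nothing fitted ever sees held-out feature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .data import Feature, FeatureSchema, LabeledDataset

__all__ = [
    "FeatureSchema", "ScalerParams", "SplitBundle",
    "impute", "Imputer", "flag_outliers", "fit_scaler", "scale", "encode",
    "pca_transform", "chi_square_score", "rfe_select", "derive_bmi",
    "augment_images", "stratified_split", "Preprocessor", "ProcessedSplits",
]


# ---------------------------------------------------------------------------
# imputation

@dataclass
class Imputer:
    """Median/mode/KNN imputer with statistics frozen at fit time.

    Numeric cells take the training median, categorical cells the training
    mode (ties broken toward the lexicographically smallest category), and
    time-series cells the mean of the k nearest complete training rows under
    Euclidean distance on co-observed numeric cells.
    """

    schema: FeatureSchema
    k: int = 5
    medians_: dict[str, float] = field(default_factory=dict)
    modes_: dict[str, str] = field(default_factory=dict)
    donor_rows_: np.ndarray | None = None  # complete numeric rows for KNN

    def fit(self, data: LabeledDataset) -> "Imputer":
        if self.k < 1:
            raise ValueError("k must be at least 1")
        for f in self.schema.of_kind("numeric"):
            col = data.frame[f.name].to_numpy(dtype=float)
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                raise ValueError(f"feature {f.name!r} is fully missing")
            self.medians_[f.name] = float(np.median(obs))
        for f in self.schema.of_kind("categorical-nominal", "categorical-ordinal"):
            col = data.frame[f.name]
            obs = col[col.notna()]
            if obs.empty:
                raise ValueError(f"feature {f.name!r} is fully missing")
            counts = obs.value_counts()
            top = counts[counts == counts.max()].index
            self.modes_[f.name] = sorted(map(str, top))[0]
        ts_cols = [c for f in self.schema.of_kind("timeseries") for c in f.columns]
        if ts_cols:
            num = data.frame[self.schema.numeric_columns].to_numpy(dtype=float)
            complete = ~np.isnan(num).any(axis=1)
            if not complete.any():
                raise ValueError("no complete rows available for KNN imputation")
            self.donor_rows_ = num[complete]
        return self

    def transform(self, data: LabeledDataset) -> LabeledDataset:
        out = data.copy()
        for name, med in self.medians_.items():
            col = out.frame[name].to_numpy(dtype=float)
            col[np.isnan(col)] = med
            out.frame[name] = col
        for name, mode in self.modes_.items():
            col = out.frame[name].copy()
            col[col.isna()] = mode
            out.frame[name] = col
        ts_feats = self.schema.of_kind("timeseries")
        if ts_feats and self.donor_rows_ is not None:
            num_cols = self.schema.numeric_columns
            X = out.frame[num_cols].to_numpy(dtype=float)
            missing_rows = np.where(np.isnan(X).any(axis=1))[0]
            for i in missing_rows:
                row = X[i]
                obs = ~np.isnan(row)
                if not obs.any():  # nothing co-observed: fall back to donor mean
                    fill = self.donor_rows_.mean(axis=0)
                else:
                    d2 = ((self.donor_rows_[:, obs] - row[obs]) ** 2).sum(axis=1)
                    nearest = np.argsort(d2, kind="stable")[: self.k]
                    fill = self.donor_rows_[nearest].mean(axis=0)
                row[~obs] = fill[~obs]
                X[i] = row
            out.frame[num_cols] = X
        return out


def impute(data: LabeledDataset, schema: FeatureSchema, k: int = 5) -> LabeledDataset:
    """Fit-and-apply imputation on one dataset (see :class:`Imputer`)."""
    return Imputer(schema, k).fit(data).transform(data)


# ---------------------------------------------------------------------------
# outliers, scaling, encoding

def flag_outliers(x: Sequence[float], method: Literal["zscore", "iqr"] = "zscore",
                  z_threshold: float = 3.0) -> np.ndarray:
    """Boolean outlier flags by |Z| > threshold or the Tukey IQR fences.

    Z uses the population standard deviation and a *strict* inequality; the
    IQR fences are [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with linearly interpolated
    (type-7) quartiles.
    """
    x = np.asarray(x, dtype=float)
    if method == "zscore":
        sd = x.std()
        if sd == 0:
            raise ValueError("z-score undefined for a constant vector (sigma = 0)")
        return np.abs((x - x.mean()) / sd) > z_threshold
    if method == "iqr":
        if x.size < 4:
            raise ValueError("IQR rule needs at least 4 observations")
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
    raise ValueError(f"unknown outlier method {method!r}")


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature statistics fitted on the training split only."""

    min: float
    max: float
    mean: float
    std: float  # population (ddof 0)

    def __post_init__(self) -> None:
        if self.max < self.min:
            raise ValueError("max must be >= min")
        if self.std < 0:
            raise ValueError("std must be nonnegative")


def fit_scaler(x: Sequence[float]) -> ScalerParams:
    x = np.asarray(x, dtype=float)
    return ScalerParams(float(x.min()), float(x.max()), float(x.mean()), float(x.std()))


def scale(x: Sequence[float], method: Literal["minmax", "standard"],
          params: ScalerParams) -> np.ndarray:
    """Apply a fitted scaler; values outside the training range extrapolate."""
    x = np.asarray(x, dtype=float)
    if method == "minmax":
        if params.max == params.min:
            raise ValueError("min-max scaling undefined for a degenerate feature")
        return (x - params.min) / (params.max - params.min)
    if method == "standard":
        if params.std == 0:
            raise ValueError("standardization undefined for a constant feature")
        return (x - params.mean) / params.std
    raise ValueError(f"unknown scaling method {method!r}")


def encode(x: Sequence[str], kind: Literal["nominal", "ordinal"],
           levels: Sequence[str]) -> np.ndarray:
    """One-hot (all levels kept) or integer-rank encoding of a categorical."""
    levels = list(levels)
    index = {lvl: i for i, lvl in enumerate(levels)}
    codes = np.empty(len(x), dtype=int)
    for i, v in enumerate(x):
        if v not in index:
            raise ValueError(f"unseen category {v!r} at transform time")
        codes[i] = index[v]
    if kind == "ordinal":
        return codes.reshape(-1, 1).astype(float)
    if kind == "nominal":
        return np.eye(len(levels))[codes]
    raise ValueError(f"unknown encoding kind {kind!r}")


# ---------------------------------------------------------------------------
# feature engineering

def pca_transform(X: np.ndarray, n_components: int | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components by SVD of the centered matrix.

    Returns (scores Z, orthonormal loading matrix W, explained variances in
    nonincreasing order, ddof-1 convention).  When ``n_components`` is unset,
    keeps the smallest number of components explaining >= 95% of variance.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(n - 1, 1)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if n_components is None:
        total = var.sum()
        cum = np.cumsum(var) / total if total > 0 else np.ones_like(var)
        n_components = int(np.searchsorted(cum, 0.95 - 1e-12) + 1)
    if n_components > p:
        raise ValueError("n_components exceeds the number of features")
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    W = Vt[:n_components].T
    return Xc @ W, W, var[:n_components]


def chi_square_score(observed: np.ndarray) -> float:
    """Pearson chi-square statistic of a contingency table of counts."""
    O = np.asarray(observed, dtype=float)
    if (O < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = O.sum(axis=1, keepdims=True)
    cols = O.sum(axis=0, keepdims=True)
    total = O.sum()
    if (rows == 0).any() or (cols == 0).any() or total == 0:
        raise ValueError("zero margin: expected counts undefined")
    E = rows * cols / total
    return float(((O - E) ** 2 / E).sum())


def _ridge_coefs(X: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Closed-form ridge fit on ±1 targets over standardized features."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    t = 2.0 * y - 1.0
    p = Xs.shape[1]
    return np.linalg.solve(Xs.T @ Xs + alpha * np.eye(p), Xs.T @ t)


def rfe_select(X: np.ndarray, y: np.ndarray, n_keep: int) -> np.ndarray:
    """Recursive feature elimination with an internal ridge linear scorer.

    Repeatedly refits and drops the surviving feature with the smallest
    |coefficient| until ``n_keep`` remain; fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_keep < 1:
        raise ValueError("n_keep must be at least 1")
    if n_keep > X.shape[1]:
        raise ValueError("n_keep exceeds the number of features")
    alive = list(range(X.shape[1]))
    while len(alive) > n_keep:
        coef = _ridge_coefs(X[:, alive], y)
        drop = int(np.argmin(np.abs(coef)))  # first minimum: deterministic
        alive.pop(drop)
    return np.array(sorted(alive), dtype=int)


def derive_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight / height² (kg/m²)."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    if weight_kg < 0:
        raise ValueError("weight must be nonnegative")
    return weight_kg / height_m**2


# ---------------------------------------------------------------------------
# image augmentation

def augment_images(images: Sequence[np.ndarray],
                   ops: Sequence[Literal["rotate", "flip", "crop", "noise"]],
                   seed: int, noise_sd: float = 0.05,
                   crop_fraction: float = 0.8) -> list[np.ndarray]:
    """Originals plus one transformed copy per op (count × (1+|ops|)).

    Rotations are random 90° multiples, flips are left-right, crops take a
    random ``crop_fraction`` window re-padded with zeros to the original
    size, and noise is additive Gaussian with ``noise_sd``.
    """
    if not ops:
        raise ValueError("ops must be nonempty")
    unknown = set(ops) - {"rotate", "flip", "crop", "noise"}
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = substream(seed, "augment")
    out: list[np.ndarray] = []
    for img in images:
        img = np.asarray(img, dtype=float)
        if img.size == 0:
            raise ValueError("cannot augment an empty image")
        out.append(img.copy())
    for op in ops:
        for img in images:
            img = np.asarray(img, dtype=float)
            if op == "rotate":
                out.append(np.rot90(img, k=int(rng.integers(1, 4))).copy())
            elif op == "flip":
                out.append(np.fliplr(img).copy())
            elif op == "crop":
                h, w = img.shape
                ch = max(1, int(round(h * crop_fraction)))
                cw = max(1, int(round(w * crop_fraction)))
                r = int(rng.integers(0, h - ch + 1))
                c = int(rng.integers(0, w - cw + 1))
                pad = np.zeros_like(img)
                pad[:ch, :cw] = img[r:r + ch, c:c + cw]
                out.append(pad)
            elif op == "noise":
                out.append(img + noise_sd * rng.standard_normal(img.shape))
    return out


# ---------------------------------------------------------------------------
# splitting

@dataclass
class SplitBundle:
    train: LabeledDataset
    valid: LabeledDataset
    test: LabeledDataset
    permutation: np.ndarray  # original row index of every row, in part order


def stratified_split(data: LabeledDataset,
                     fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                     seed: int = 0) -> SplitBundle:
    """Disjoint exhaustive train/valid/test split preserving class balance.

    Per-class allocation is by floor of the target fraction; leftover rows go
    to train first, then validation, then test.
    """
    f = np.asarray(fractions, dtype=float)
    if (f <= 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = substream(seed, "split")
    parts: list[list[int]] = [[], [], []]
    for cls in (0, 1):
        idx = np.where(data.y == cls)[0]
        if idx.size and idx.size < 3:
            raise ValueError(f"class {cls} has fewer than 3 members")
        rng.shuffle(idx)
        counts = np.floor(f * idx.size).astype(int)
        leftover = idx.size - counts.sum()
        for p in range(3):
            if leftover == 0:
                break
            counts[p] += 1
            leftover -= 1
        stops = np.cumsum(counts)
        parts[0].extend(idx[: stops[0]])
        parts[1].extend(idx[stops[0]: stops[1]])
        parts[2].extend(idx[stops[1]: stops[2]])
    perm = np.array(parts[0] + parts[1] + parts[2], dtype=int)
    return SplitBundle(data.take(parts[0]), data.take(parts[1]),
                       data.take(parts[2]), perm)


# ---------------------------------------------------------------------------
# fitted end-to-end pipeline

@dataclass
class ProcessedSplits:
    """Model-ready numeric design matrices for the three parts."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_valid: np.ndarray
    y_valid: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    feature_names: list[str]
    seq_train: np.ndarray | None = None  # (n, T, C) when time-series present
    seq_valid: np.ndarray | None = None
    seq_test: np.ndarray | None = None


@dataclass
class Preprocessor:
    """Split → impute → flag outliers → scale → encode, leakage-free.

    Numeric columns are min–max scaled to [0,1] (Bernoulli-visible models
    downstream expect activation probabilities); categoricals are one-hot or
    rank encoded.  Outlier handling removes flagged *training* rows only;
    validation and test rows are never dropped, so evaluation stays honest.
    """

    outlier_method: Literal["zscore", "iqr", "none"] = "iqr"
    z_threshold: float = 3.0
    remove_outliers: bool = True
    knn_k: int = 5
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    _imputer: Imputer | None = None
    _scalers: dict | None = None
    _schema: FeatureSchema | None = None

    def run(self, data: LabeledDataset) -> ProcessedSplits:
        schema = data.schema
        bundle = stratified_split(data, self.fractions, self.seed)
        imputer = Imputer(schema, self.knn_k).fit(bundle.train)
        train = imputer.transform(bundle.train)
        valid = imputer.transform(bundle.valid)
        test = imputer.transform(bundle.test)

        if self.remove_outliers and self.outlier_method != "none":
            flagged = np.zeros(len(train), dtype=bool)
            for c in schema.numeric_columns:
                x = train.frame[c].to_numpy(dtype=float)
                try:
                    flagged |= flag_outliers(x, self.outlier_method, self.z_threshold)
                except ValueError:
                    continue  # constant / too-short column: nothing to flag
            if flagged.any() and (~flagged).sum() >= 4:
                train = train.take(np.where(~flagged)[0])

        scalers = {c: fit_scaler(train.frame[c].to_numpy(dtype=float))
                   for c in schema.numeric_columns}
        self._imputer, self._scalers, self._schema = imputer, scalers, schema

        Xtr, names = self._design(train)
        Xva, _ = self._design(valid)
        Xte, _ = self._design(test)
        return ProcessedSplits(Xtr, train.y, Xva, valid.y, Xte, test.y, names,
                               self._seqs(train), self._seqs(valid), self._seqs(test))

    def transform(self, data: LabeledDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """Apply the train-fitted imputer/scalers/encoders to new data.

        Returns (X, y, sequences); no rows are dropped.
        """
        if self._scalers is None:
            raise RuntimeError("run() must be called before transform()")
        part = self._imputer.transform(data)
        X, _ = self._design(part)
        return X, part.y, self._seqs(part)

    def _design(self, part: LabeledDataset) -> tuple[np.ndarray, list[str]]:
        schema, scalers = self._schema, self._scalers
        blocks: list[np.ndarray] = []
        names: list[str] = []
        for f in schema.features:
            if f.kind in ("numeric", "timeseries"):
                for c in f.columns:
                    p = scalers[c]
                    if p.max == p.min:  # degenerate: constant after impute
                        blocks.append(np.zeros((len(part), 1)))
                    else:
                        blocks.append(np.clip(
                            scale(part.frame[c].to_numpy(dtype=float),
                                  "minmax", p), 0.0, 1.0).reshape(-1, 1))
                    names.append(c)
            elif f.kind == "categorical-nominal":
                blocks.append(encode(part.frame[f.name].tolist(), "nominal", f.levels))
                names.extend(f"{f.name}={lvl}" for lvl in f.levels)
            else:  # ordinal -> rank scaled to [0,1]
                ranks = encode(part.frame[f.name].tolist(), "ordinal", f.levels)
                denom = max(len(f.levels) - 1, 1)
                blocks.append(ranks / denom)
                names.append(f.name)
        X = np.hstack(blocks) if blocks else np.zeros((len(part), 0))
        return X, names

    def _seqs(self, part: LabeledDataset) -> np.ndarray | None:
        ts_feats = self._schema.of_kind("timeseries")
        if not ts_feats:
            return None
        chans = []
        for f in ts_feats:
            cols = []
            for c in f.columns:
                p = self._scalers[c]
                x = part.frame[c].to_numpy(dtype=float)
                if p.max == p.min:
                    cols.append(np.zeros(len(part)))
                else:
                    cols.append(np.clip(scale(x, "minmax", p), 0.0, 1.0))
            chans.append(np.stack(cols, axis=1))  # (n, T)
        return np.stack(chans, axis=-1)  # (n, T, C), train-fitted scaling
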