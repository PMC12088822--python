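"""Seeded generators of mixed-type clinical-style datasets with known truth.

The generating model is deliberately simple and fully known, so every
downstream stage (preprocessing, feature extraction, ensembling, metrics) can
be tested against closed-form answers:

* binary labels drawn from a Bernoulli class prior;
* numeric features class-conditionally Gaussian, means ``±Δμ/2`` and unit
  within-class standard deviation (``Δμ`` = ``mean_separation``);
* categorical features class-conditionally multinomial, with class 1 skewed
  toward the first level by ``categorical_skew``;
* time-series channels stationary AR(1) around a class-dependent level;
* MCAR cell missingness and far-outlier injection as a separate corruption
  step that never touches labels.

For the numeric-only equal-covariance case the Bayes accuracy of the model is
available in closed form, which anchors end-to-end recovery tests.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._rng import substream
from .data import Feature, FeatureSchema, LabeledDataset

__all__ = [
    "SynthSpec", "LabeledDataset", "make_tabular", "make_timeseries",
    "make_dataset", "corrupt", "make_mask_pair", "bayes_accuracy", "bayes_rule",
]

N_LEVELS = 3  # categorical vocabulary size: "a", "b", "c"


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the generating model (defaults are the study conditions).

    ``mean_separation`` is per-feature Δμ in units of the common within-class
    standard deviation σ=1; with 4 independent numeric features and Δμ=1 the
    Bayes accuracy is Φ(√4·1/2)=Φ(1)≈0.8413.
    """

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
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if min(self.n_numeric, self.n_categorical, self.n_timeseries) < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.n_numeric + self.n_categorical + self.n_timeseries == 0:
            raise ValueError("at least one feature family must be nonempty")
        if not 0.0 < self.class_prior < 1.0:
            raise ValueError("class_prior must lie in (0,1)")
        if self.mean_separation < 0:
            raise ValueError("mean_separation must be nonnegative")
        if not 0.0 <= self.categorical_skew < 1.0:
            raise ValueError("categorical_skew must lie in [0,1)")
        if self.ts_length < 2:
            raise ValueError("ts_length must be at least 2")
        if not abs(self.ar_coefficient) < 1.0:
            raise ValueError("|ar_coefficient| must be < 1 (stationarity)")
        for name in ("missing_rate", "outlier_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be a probability")


def _labels(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(spec.n_samples) < spec.class_prior).astype(int)


def _level_probs(skew: float) -> tuple[np.ndarray, np.ndarray]:
    uniform = np.full(N_LEVELS, 1.0 / N_LEVELS)
    skewed = (1.0 - skew) * uniform
    skewed[0] += skew
    return uniform, skewed


def make_tabular(spec: SynthSpec) -> LabeledDataset:
    """Class-conditional Gaussian numerics + multinomial categoricals."""
    spec.validate()
    if spec.n_numeric + spec.n_categorical == 0:
        raise ValueError("spec declares no tabular features")
    rng = substream(spec.seed, "tabular")
    y = _labels(spec, rng)
    delta = spec.mean_separation
    cols: dict[str, np.ndarray] = {}
    feats: list[Feature] = []
    means = (y - 0.5) * delta  # ±Δμ/2
    for j in range(spec.n_numeric):
        cols[f"num{j}"] = rng.normal(means, 1.0)
        feats.append(Feature(f"num{j}", "numeric"))
    levels = tuple(string.ascii_lowercase[:N_LEVELS])
    p0, p1 = _level_probs(spec.categorical_skew)
    for j in range(spec.n_categorical):
        u = rng.random(spec.n_samples)
        cum0, cum1 = np.cumsum(p0), np.cumsum(p1)
        idx0 = np.searchsorted(cum0, u, side="right")
        idx1 = np.searchsorted(cum1, u, side="right")
        idx = np.where(y == 1, idx1, idx0).clip(0, N_LEVELS - 1)
        cols[f"cat{j}"] = np.array(levels, dtype=object)[idx]
        feats.append(Feature(f"cat{j}", "categorical-nominal", levels=levels))
    frame = pd.DataFrame(cols)
    return LabeledDataset(frame, y, FeatureSchema(tuple(feats)))


def make_timeseries(spec: SynthSpec) -> LabeledDataset:
    """Stationary AR(1) channels around class-dependent levels ±Δμ/2."""
    spec.validate()
    if spec.n_timeseries == 0:
        raise ValueError("spec declares no timeseries features")
    rng = substream(spec.seed, "timeseries")
    y = _labels(spec, rng)
    phi = spec.ar_coefficient
    level = (y - 0.5) * spec.mean_separation
    T = spec.ts_length
    cols: dict[str, np.ndarray] = {}
    feats: list[Feature] = []
    stat_sd = 1.0 / np.sqrt(1.0 - phi**2)
    for j in range(spec.n_timeseries):
        x = np.empty((spec.n_samples, T))
        x[:, 0] = level + stat_sd * rng.standard_normal(spec.n_samples)
        for t in range(1, T):
            x[:, t] = level + phi * (x[:, t - 1] - level) + rng.standard_normal(spec.n_samples)
        f = Feature(f"ts{j}", "timeseries", length=T)
        feats.append(f)
        for t, c in enumerate(f.columns):
            cols[c] = x[:, t]
    return LabeledDataset(pd.DataFrame(cols), y, FeatureSchema(tuple(feats)))


def make_dataset(spec: SynthSpec) -> LabeledDataset:
    """All declared feature families, sharing one label vector, then corrupted."""
    spec.validate()
    parts: list[LabeledDataset] = []
    if spec.n_numeric + spec.n_categorical > 0:
        parts.append(make_tabular(spec))
    if spec.n_timeseries > 0:
        parts.append(make_timeseries(spec))
    base = parts[0]
    for extra in parts[1:]:
        # regenerate with the first part's labels so families agree per row
        extra = _with_labels(extra, spec, base.y)
        base = LabeledDataset(pd.concat([base.frame, extra.frame], axis=1),
                              base.y, FeatureSchema(base.schema.features + extra.schema.features))
    if spec.missing_rate > 0 or spec.outlier_rate > 0:
        base = corrupt(base, spec.missing_rate, spec.outlier_rate, spec.seed)
    return base


def _with_labels(ds: LabeledDataset, spec: SynthSpec, y: np.ndarray) -> LabeledDataset:
    """Re-center class-dependent columns of ``ds`` onto labels ``y``.

    Both families draw labels from the same prior but independent streams;
    for a merged dataset the time-series levels must follow the tabular labels.
    """
    shift = (y - ds.y) * spec.mean_separation  # move ±Δμ where labels differ
    frame = ds.frame.copy()
    for c in ds.schema.numeric_columns:
        frame[c] = frame[c].to_numpy() + shift
    return LabeledDataset(frame, y, ds.schema)


def corrupt(data: LabeledDataset, missing_rate: float, outlier_rate: float,
            seed: int) -> LabeledDataset:
    """Mask cells MCAR and inject far outliers; labels and schema untouched.

    Outlier cells are displaced at least 8 within-class standard deviations
    from the feature's class-conditional mean, so both the |Z|>3 and the
    Tukey-fence rules provably flag them.
    """
    for name, r in (("missing_rate", missing_rate), ("outlier_rate", outlier_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be a probability")
    if missing_rate == 0 and outlier_rate == 0:
        return data.copy()
    rng = substream(seed, "corrupt")
    out = data.copy()
    num_cols = data.schema.numeric_columns
    if outlier_rate > 0 and num_cols:
        for c in num_cols:
            x = out.frame[c].to_numpy(dtype=float)
            hit = rng.random(len(x)) < outlier_rate
            if hit.any():
                mu = np.array([x[out.y == k].mean() for k in (0, 1)])[out.y[hit]]
                sd = np.array([max(x[out.y == k].std(), 1e-12) for k in (0, 1)])[out.y[hit]]
                sign = np.where(rng.random(hit.sum()) < 0.5, -1.0, 1.0)
                x[hit] = mu + sign * (8.0 + 2.0 * rng.random(hit.sum())) * sd
                out.frame[c] = x
    if missing_rate > 0:
        for c in data.schema.columns:
            hit = rng.random(len(out)) < missing_rate
            if hit.any():
                col = out.frame[c].copy()
                col[hit] = np.nan
                out.frame[c] = col
    return out


def make_mask_pair(height: int, width: int, flip_prob: float,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth rectangle mask and a noisy 'prediction' of it.

    The predicted mask equals the truth with each pixel flipped independently
    with probability ``flip_prob`` — a fixture for overlap metrics.
    """
    if height < 1 or width < 1:
        raise ValueError("mask dimensions must be positive")
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be a probability")
    rng = substream(seed, "mask")
    truth = np.zeros((height, width), dtype=bool)
    truth[height // 4: max(height // 4 + 1, 3 * height // 4),
          width // 4: max(width // 4 + 1, 3 * width // 4)] = True
    flips = rng.random(truth.shape) < flip_prob
    return truth, truth ^ flips


def _check_numeric_only(spec: SynthSpec) -> None:
    if spec.n_categorical or spec.n_timeseries:
        raise ValueError("closed-form Bayes rule requires a numeric-only spec")
    if spec.n_numeric == 0:
        raise ValueError("spec has no numeric features")


def bayes_accuracy(spec: SynthSpec) -> float:
    """Closed-form accuracy of the optimal rule under the generating model.

    With d independent features, per-feature separation Δμ and unit sd, the
    Mahalanobis distance between class means is s=√d·Δμ and the optimal
    accuracy is π0·Φ(s/2 + ln(π0/π1)/s) + π1·Φ(s/2 − ln(π0/π1)/s)
    (Φ(s/2) for equal priors).
    """
    spec.validate()
    _check_numeric_only(spec)
    p1 = spec.class_prior
    p0 = 1.0 - p1
    s = np.sqrt(spec.n_numeric) * spec.mean_separation
    if s == 0.0:
        return max(p0, p1)
    c = np.log(p0 / p1)
    return float(p0 * ndtr(s / 2 + c / s) + p1 * ndtr(s / 2 - c / s))


def bayes_rule(spec: SynthSpec, X: np.ndarray) -> np.ndarray:
    """Labels assigned by the true generating rule (the Bayes classifier)."""
    spec.validate()
    _check_numeric_only(spec)
    X = np.asarray(X, dtype=float)
    score = spec.mean_separation * X.sum(axis=1) + np.log(spec.class_prior / (1 - spec.class_prior))
    return (score > 0).astype(int)
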