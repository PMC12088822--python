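"""Adaptive ensemble: softmax weighting of base learners by validation loss.

Three base learners — the deep-belief-network classifier, a dense net, and an
attention net — each produce class-probability rows.  The ensemble prediction
is the convex combination Ŷ = Σ_m w_m Ŷ_m with weights

    w_m = exp(−L_m) / Σ_j exp(−L_j),

where L_m is learner m's validation cross-entropy, so lower-loss learners get
strictly larger weights and the weights are invariant to a constant shift of
all losses.  If the aggregated validation accuracy falls below a performance
threshold the losses and weights are recalibrated (bounded by a maximum
iteration count); every (losses, weights) pair is recorded.

Base-learner *parameters* are trained by gradient descent on L2-regularized
cross-entropy; the ensemble *weights* are always set by the softmax rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import softmax as _sp_softmax

from . import hdbn as hdbn_mod
from . import learners as learners_mod
from .hdbn import HDBNModel, TrainConfig
from .learners import LearnerModel, Prediction

__all__ = [
    "EnsembleState", "CAENConfig", "CAENModel",
    "softmax_weights", "aggregate", "cross_entropy", "total_loss", "sgd_step",
    "fit", "predict",
]

EPS = 1e-12


def softmax_weights(losses: Sequence[float]) -> np.ndarray:
    """w_m ∝ exp(−L_m): positive, sum to 1, strictly decreasing in own loss."""
    L = np.asarray(losses, dtype=float)
    if L.size == 0:
        raise ValueError("losses must be nonempty")
    if not np.isfinite(L).all():
        raise ValueError("losses must be finite")
    return _sp_softmax(-L)


def aggregate(predictions: Sequence[Prediction], weights: Sequence[float]) -> Prediction:
    """Weighted sum of probability matrices; rows remain distributions."""
    preds = [np.asarray(p, dtype=float) for p in predictions]
    w = np.asarray(weights, dtype=float)
    if len(preds) != w.size:
        raise ValueError("one weight per learner required")
    shapes = {p.shape for p in preds}
    if len(shapes) != 1:
        raise ValueError("prediction shapes differ")
    if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
        raise ValueError("weights must be a convex combination")
    return np.tensordot(w, np.stack(preds), axes=1)


def cross_entropy(y: Sequence[int], proba: Prediction) -> float:
    """Mean negative log-probability of the true class, ε-clipped."""
    y = np.asarray(y, dtype=int)
    proba = np.asarray(proba, dtype=float)
    if y.size == 0:
        raise ValueError("cannot compute a loss over zero samples")
    if proba.shape != (y.size, 2):
        raise ValueError("prediction matrix must be (n, 2)")
    p_true = np.clip(proba[np.arange(y.size), y], EPS, 1.0)
    return float(-np.mean(np.log(p_true)))


def total_loss(L: float, weights_or_params, lam: float) -> float:
    """L_total = L + λ·Σ‖·‖² over the given parameter arrays."""
    if lam < 0:
        raise ValueError("regularization strength must be nonnegative")
    arrays = weights_or_params
    if isinstance(arrays, np.ndarray):
        arrays = [arrays]
    reg = sum(float((np.asarray(a, dtype=float) ** 2).sum()) for a in arrays)
    return float(L + lam * reg)


def sgd_step(params, grads, eta: float):
    """Elementwise descent step w ← w − η·g over matching array pytrees."""
    single = isinstance(params, np.ndarray)
    ps = [params] if single else list(params)
    gs = [grads] if single else list(grads)
    if len(ps) != len(gs):
        raise ValueError("params and grads must match")
    out = []
    for p, g in zip(ps, gs):
        p = np.asarray(p, dtype=float)
        g = np.asarray(g, dtype=float)
        if p.shape != g.shape:
            raise ValueError("shape mismatch between parameter and gradient")
        if not np.isfinite(g).all():
            raise ValueError("non-finite gradient")
        out.append(p - eta * g)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# model fitting

@dataclass
class EnsembleState:
    losses: np.ndarray          # L_m per learner
    weights: np.ndarray         # w_m per learner, sums to 1
    iteration: int
    history: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


@dataclass
class CAENConfig:
    """Ensemble-level knobs; per-learner training uses ``train``.

    ``performance_threshold`` is the validation accuracy below which weights
    are recalibrated (default 0: the loop runs once); ``max_recalibration``
    bounds the loop.  ``epochs_overrides`` maps learner name → epoch count,
    for deliberately handicapping a learner in experiments.
    """

    train: TrainConfig = field(default_factory=TrainConfig)
    hdbn_layers: tuple[int, ...] = (16, 8)
    dense_hidden: tuple[int, ...] = (32, 16)
    attention_dim: int = 16
    performance_threshold: float = 0.0
    max_recalibration: int = 10
    epochs_overrides: dict = field(default_factory=dict)

    def learner_config(self, name: str) -> TrainConfig:
        cfg = replace(self.train)
        if name in self.epochs_overrides:
            cfg = replace(cfg, epochs=int(self.epochs_overrides[name]))
        return cfg


@dataclass
class CAENModel:
    learners: dict               # name -> HDBNModel | LearnerModel
    state: EnsembleState
    config: CAENConfig

    @property
    def names(self) -> list[str]:
        return list(self.learners)


def _learner_proba(name: str, model, X: np.ndarray,
                   seq: np.ndarray | None) -> Prediction:
    if name == "hdbn":
        return hdbn_mod.predict_proba(model, X)
    if name == "attention":
        inputs = seq if seq is not None else X
        return learners_mod.predict_proba(model, inputs)
    return learners_mod.predict_proba(model, X)


def fit(train: tuple, valid: tuple, config: CAENConfig | None = None) -> CAENModel:
    """Train all base learners, then set ensemble weights from validation loss.

    ``train``/``valid`` are ``(X, y)`` or ``(X, y, sequences)`` tuples of
    preprocessed features in [0,1].  Requires at least two trainable learners.
    """
    config = config or CAENConfig()
    X, y = np.asarray(train[0], float), np.asarray(train[1], int)
    Xv, yv = np.asarray(valid[0], float), np.asarray(valid[1], int)
    seq = train[2] if len(train) > 2 else None
    seqv = valid[2] if len(valid) > 2 else None

    models: dict[str, object] = {}
    cfg = config.learner_config("hdbn")
    stack = hdbn_mod.pretrain_stack(X, config.hdbn_layers, cfg)
    models["hdbn"] = hdbn_mod.finetune(stack, X, y, cfg, Xv, yv)
    cfg = config.learner_config("dense")
    models["dense"] = learners_mod.train_dense(X, y, cfg, Xv, yv,
                                               hidden=config.dense_hidden)
    cfg = config.learner_config("attention")
    attn_train = seq if seq is not None else X
    attn_valid = seqv if seqv is not None else Xv
    models["attention"] = learners_mod.train_attention(
        attn_train, y, cfg, attn_valid, yv, d_model=config.attention_dim)
    if len(models) < 2:
        raise ValueError("at least two trainable learners are required")

    val_preds = {n: _learner_proba(n, m, Xv, seqv) for n, m in models.items()}
    history: list[tuple[np.ndarray, np.ndarray]] = []
    iteration = 0
    while True:
        losses = np.array([cross_entropy(yv, val_preds[n]) for n in models])
        weights = softmax_weights(losses)
        history.append((losses.copy(), weights.copy()))
        iteration += 1
        agg = aggregate(list(val_preds.values()), weights)
        acc = float((agg.argmax(axis=1) == yv).mean())
        if acc >= config.performance_threshold or iteration >= config.max_recalibration:
            break
    state = EnsembleState(losses, weights, iteration, history)
    return CAENModel(models, state, config)


def predict(model: CAENModel, X: np.ndarray,
            seq: np.ndarray | None = None) -> tuple[Prediction, np.ndarray]:
    """Aggregate with the stored weights; hard labels by argmax (ties → 0)."""
    X = np.asarray(X, dtype=float)
    preds = [_learner_proba(n, m, X, seq) for n, m in model.learners.items()]
    proba = aggregate(preds, model.state.weights)
    return proba, proba.argmax(axis=1)
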