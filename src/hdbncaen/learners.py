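"""Non-DBN base learners: a dense feed-forward net and a small self-attention
classifier, behind one trainable-classifier contract.

Both produce a (n, 2) row-stochastic probability matrix from
:func:`predict_proba`, train by mini-batch gradient descent on L2-regularized
cross-entropy with the shared step-decay/early-stopping loop, and expose
analytic gradients that are verified against finite differences in the tests.

Architectures (the field leaves these open; chosen to train in seconds on
desk-scale data, all configurable): dense = two rectifier layers [32, 16]
with inverted dropout and a softmax head; attention = single-head scaled
dot-product self-attention over time steps at model dimension 16, mean-pooled,
softmax head.  Tabular inputs reach the attention learner as a
length-n_features sequence of scalar tokens; each token gets a learned
per-position value embedding plus positional bias so feature identity
survives the (otherwise permutation-invariant) attention mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rng import substream
from .hdbn import TrainConfig, _softmax, _train_supervised

__all__ = ["LearnerModel", "train_dense", "train_attention", "predict_proba",
           "tabular_to_sequences", "dense_loss_and_grads",
           "attention_loss_and_grads", "attention_weights"]

Prediction = np.ndarray  # (n_samples, 2), rows sum to 1


@dataclass
class LearnerModel:
    kind: str                       # "dense" | "attention"
    params: dict[str, np.ndarray]
    arch: dict
    history: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# dense feed-forward network

def _dense_init(n_in: int, hidden: Sequence[int], seed: int) -> LearnerModel:
    rng = substream(seed, "dense-init")
    sizes = [n_in, *hidden, 2]
    params: dict[str, np.ndarray] = {}
    for i, (a, b) in enumerate(zip(sizes, sizes[1:])):
        params[f"W{i}"] = rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
        params[f"b{i}"] = np.zeros(b)
    return LearnerModel("dense", params, {"hidden": list(hidden), "n_in": n_in})


def dense_loss_and_grads(model: LearnerModel, X: np.ndarray, y: np.ndarray,
                         l2: float, dropout_mask: np.ndarray | None = None):
    """Cross-entropy + L2 and backprop gradients for the rectifier MLP.

    ``dropout_mask`` multiplies the last hidden activation (head input).
    Gradients are returned in parameter-name order W0, b0, W1, b1, …
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(X)
    depth = len(model.arch["hidden"])
    acts = [X]
    for i in range(depth):
        acts.append(np.maximum(acts[-1] @ model.params[f"W{i}"] + model.params[f"b{i}"], 0.0))
    top = acts[-1] if dropout_mask is None else acts[-1] * dropout_mask
    logits = top @ model.params[f"W{depth}"] + model.params[f"b{depth}"]
    proba = _softmax(logits)
    ce = -np.mean(np.log(np.clip(proba[np.arange(n), y], 1e-12, 1.0)))
    reg = l2 * sum(float((model.params[f"W{i}"] ** 2).sum()) for i in range(depth + 1))
    dlogits = (proba - np.eye(2)[y]) / n
    grads: dict[str, np.ndarray] = {}
    grads[f"W{depth}"] = top.T @ dlogits + 2 * l2 * model.params[f"W{depth}"]
    grads[f"b{depth}"] = dlogits.sum(axis=0)
    delta = dlogits @ model.params[f"W{depth}"].T
    if dropout_mask is not None:
        delta = delta * dropout_mask
    for i in range(depth - 1, -1, -1):
        delta = delta * (acts[i + 1] > 0)
        grads[f"W{i}"] = acts[i].T @ delta + 2 * l2 * model.params[f"W{i}"]
        grads[f"b{i}"] = delta.sum(axis=0)
        delta = delta @ model.params[f"W{i}"].T
    ordered = [grads[k] for k in sorted(model.params, key=_param_order)]
    return ce + reg, ordered


def _param_order(name: str) -> tuple:
    return (int(name[1:]), name[0])  # W0,b0,W1,b1,... (b after W per index)


def _ordered_params(model: LearnerModel) -> list[np.ndarray]:
    return [model.params[k] for k in sorted(model.params, key=_param_order)]


def train_dense(X: np.ndarray, y: np.ndarray, config: TrainConfig,
                X_val: np.ndarray | None = None,
                y_val: np.ndarray | None = None,
                hidden: Sequence[int] = (32, 16)) -> LearnerModel:
    """Train the rectifier MLP on numeric features."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("inputs must be finite")
    model = _dense_init(X.shape[1], hidden, config.seed)
    _train_supervised(model, _ordered_params(model), dense_loss_and_grads,
                      X, np.asarray(y, dtype=int), X_val, y_val, config,
                      head_width=hidden[-1], kind="dense")
    return model


# ---------------------------------------------------------------------------
# single-head self-attention classifier

def tabular_to_sequences(X: np.ndarray) -> np.ndarray:
    """View a numeric matrix as per-sample sequences of scalar tokens."""
    X = np.asarray(X, dtype=float)
    return X[:, :, None]  # (n, T=n_features, C=1)


def _attention_init(T: int, C: int, d: int, seed: int) -> LearnerModel:
    rng = substream(seed, "attn-init")
    p = {
        "Wemb": rng.standard_normal((C, d)) / np.sqrt(C),
        "P": 0.1 * rng.standard_normal((T, d)),     # positional bias
        "Wq": rng.standard_normal((d, d)) / np.sqrt(d),
        "Wk": rng.standard_normal((d, d)) / np.sqrt(d),
        "Wv": rng.standard_normal((d, d)) / np.sqrt(d),
        "Wo": rng.standard_normal((d, 2)) / np.sqrt(d),
        "bo": np.zeros(2),
    }
    return LearnerModel("attention", p, {"T": T, "C": C, "d": d})


def _attention_forward(model: LearnerModel, X: np.ndarray):
    p = model.params
    d = model.arch["d"]
    E = np.einsum("btc,cd->btd", X, p["Wemb"]) + p["P"]
    Q = E @ p["Wq"]
    K = E @ p["Wk"]
    V = E @ p["Wv"]
    S = np.einsum("btd,bsd->bts", Q, K) / np.sqrt(d)
    S = S - S.max(axis=-1, keepdims=True)
    A = np.exp(S)
    A = A / A.sum(axis=-1, keepdims=True)
    H = np.einsum("bts,bsd->btd", A, V)
    pooled = H.mean(axis=1)
    return E, Q, K, V, A, H, pooled


def attention_weights(model: LearnerModel, X: np.ndarray) -> np.ndarray:
    """(n, T, T) attention matrices; each row is a distribution over tokens."""
    X = _coerce_sequences(X, model.arch)
    return _attention_forward(model, X)[4]


def attention_loss_and_grads(model: LearnerModel, X: np.ndarray, y: np.ndarray,
                             l2: float, dropout_mask: np.ndarray | None = None):
    """Loss and analytic gradients for the attention classifier."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(X)
    p = model.params
    d = model.arch["d"]
    E, Q, K, V, A, H, pooled = _attention_forward(model, X)
    top = pooled if dropout_mask is None else pooled * dropout_mask
    proba = _softmax(top @ p["Wo"] + p["bo"])
    ce = -np.mean(np.log(np.clip(proba[np.arange(n), y], 1e-12, 1.0)))
    reg_keys = ("Wemb", "Wq", "Wk", "Wv", "Wo")
    reg = l2 * sum(float((p[k] ** 2).sum()) for k in reg_keys)
    dlogits = (proba - np.eye(2)[y]) / n
    g = {k: np.zeros_like(v) for k, v in p.items()}
    g["Wo"] = top.T @ dlogits + 2 * l2 * p["Wo"]
    g["bo"] = dlogits.sum(axis=0)
    dpooled = dlogits @ p["Wo"].T
    if dropout_mask is not None:
        dpooled = dpooled * dropout_mask
    T = model.arch["T"]
    dH = np.repeat(dpooled[:, None, :] / T, T, axis=1)
    dA = np.einsum("btd,bsd->bts", dH, V)
    dV = np.einsum("bts,btd->bsd", A, dH)
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dQ = np.einsum("bts,bsd->btd", dS, K) / np.sqrt(d)
    dK = np.einsum("bts,btd->bsd", dS, Q) / np.sqrt(d)
    dE = dQ @ p["Wq"].T + dK @ p["Wk"].T + dV @ p["Wv"].T
    g["Wq"] = np.einsum("btd,bte->de", E, dQ) + 2 * l2 * p["Wq"]
    g["Wk"] = np.einsum("btd,bte->de", E, dK) + 2 * l2 * p["Wk"]
    g["Wv"] = np.einsum("btd,bte->de", E, dV) + 2 * l2 * p["Wv"]
    g["Wemb"] = np.einsum("btc,btd->cd", X, dE) + 2 * l2 * p["Wemb"]
    g["P"] = dE.sum(axis=0)
    ordered = [g[k] for k in sorted(p)]
    return ce + reg, ordered


def _attn_ordered_params(model: LearnerModel) -> list[np.ndarray]:
    return [model.params[k] for k in sorted(model.params)]


def _coerce_sequences(X, arch: dict | None = None) -> np.ndarray:
    if isinstance(X, (list, tuple)):
        lengths = {np.asarray(s).shape[0] for s in X}
        if len(lengths) > 1:
            raise ValueError("ragged sequences: pad to a common length first")
        X = np.stack([np.asarray(s, dtype=float) for s in X])
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = tabular_to_sequences(X)
    if X.ndim != 3:
        raise ValueError("sequences must have shape (n, T, channels)")
    if arch is not None and (X.shape[1] != arch["T"] or X.shape[2] != arch["C"]):
        raise ValueError("sequence shape does not match the trained model")
    return X


def train_attention(X_sequences, y: np.ndarray, config: TrainConfig,
                    X_val=None, y_val=None, d_model: int = 16) -> LearnerModel:
    """Train the self-attention classifier on (n, T, channels) sequences."""
    X = _coerce_sequences(X_sequences)
    if not np.isfinite(X).all():
        raise ValueError("inputs must be finite")
    if X_val is not None:
        X_val = _coerce_sequences(X_val)
    model = _attention_init(X.shape[1], X.shape[2], d_model, config.seed)
    _train_supervised(model, _attn_ordered_params(model), attention_loss_and_grads,
                      X, np.asarray(y, dtype=int), X_val, y_val, config,
                      head_width=d_model, kind="attention")
    return model


# ---------------------------------------------------------------------------
# shared inference contract

def predict_proba(model: LearnerModel, X) -> Prediction:
    """Deterministic class-probability rows (dropout off at inference)."""
    if model.kind == "dense":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != model.arch["n_in"]:
            raise ValueError("input shape does not match the trained model")
        depth = len(model.arch["hidden"])
        a = X
        for i in range(depth):
            a = np.maximum(a @ model.params[f"W{i}"] + model.params[f"b{i}"], 0.0)
        return _softmax(a @ model.params[f"W{depth}"] + model.params[f"b{depth}"])
    if model.kind == "attention":
        X = _coerce_sequences(X, model.arch)
        *_, pooled = _attention_forward(model, X)
        return _softmax(pooled @ model.params["Wo"] + model.params["bo"])
    raise ValueError(f"unknown learner kind {model.kind!r}")
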