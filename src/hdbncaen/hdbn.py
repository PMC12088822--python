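"""Stacked-RBM deep belief network: energy model, CD training, fine-tuning.

The restricted Boltzmann machine here is Bernoulli–Bernoulli with bilinear
energy

    E(v, h) = − vᵀ W h − bᵀ v − cᵀ h,

joint P(v,h) = exp(−E)/Z.  For tiny models (n_v + n_h ≤ 20) the partition
function and all model moments are computed by exhaustive enumeration; these
exact quantities serve as oracles for the sampled contrastive-divergence
statistics and for log-likelihood regression tests.

Pretraining is greedy and layer-wise (CD-k, mean-field propagation between
layers); fine-tuning unrolls the stack into a logistic feed-forward network
with a 2-class softmax head and trains the whole thing by mini-batch gradient
descent on L2-regularized cross-entropy, with step-decayed learning rate,
inverted dropout on the head input, and patience-based early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from ._rng import substream

__all__ = [
    "RBMParams", "HDBNModel", "TrainConfig",
    "energy", "conditionals", "exact_partition", "joint_probability",
    "model_expectations", "cd_update", "train_rbm", "pretrain_stack",
    "finetune", "extract_features", "predict_proba", "loss_and_grads",
]

ENUM_LIMIT = 20  # max n_visible + n_hidden for exact enumeration


@dataclass
class TrainConfig:
    """Gradient-training knobs shared by all learners.

    Defaults: initial learning rate 0.001 decayed by ×0.1 every 10 epochs,
    batch 64, dropout 0.5, early-stopping patience 5 epochs — plus CD depth
    k=1 and a small L2 weight penalty λ.
    """

    learning_rate: float = 0.001
    lr_decay: float = 0.1
    lr_decay_every: int = 10
    batch_size: int = 64
    epochs: int = 30
    cd_k: int = 1
    l2: float = 1e-4
    dropout: float = 0.5
    patience: int = 5
    optimizer: Literal["sgd", "adam"] = "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be nonnegative")
        if self.cd_k < 1:
            raise ValueError("cd_k must be at least 1")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0,1)")

    def lr_at(self, epoch: int) -> float:
        return self.learning_rate * self.lr_decay ** (epoch // self.lr_decay_every)


@dataclass
class RBMParams:
    """θ = (W, b, c): weights, visible biases, hidden biases."""

    W: np.ndarray  # (n_visible, n_hidden)
    b: np.ndarray  # (n_visible,)
    c: np.ndarray  # (n_hidden,)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[0],) \
                or self.c.shape != (self.W.shape[1],):
            raise ValueError("inconsistent RBM parameter shapes")
        if not (np.isfinite(self.W).all() and np.isfinite(self.b).all()
                and np.isfinite(self.c).all()):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]


def energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """Bilinear RBM energy of one joint configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("state dimensions do not match the RBM")
    return float(-(v @ params.W @ h) - params.b @ v - params.c @ h)


def conditionals(state: np.ndarray, params: RBMParams,
                 direction: Literal["hidden_given_visible",
                                    "visible_given_hidden"]) -> np.ndarray:
    """Factorial logistic conditionals implied by the bilinear energy."""
    state = np.asarray(state, dtype=float)
    if direction == "hidden_given_visible":
        if state.shape[-1] != params.n_visible:
            raise ValueError("visible state has wrong dimension")
        return expit(state @ params.W + params.c)
    if direction == "visible_given_hidden":
        if state.shape[-1] != params.n_hidden:
            raise ValueError("hidden state has wrong dimension")
        return expit(state @ params.W.T + params.b)
    raise ValueError(f"unknown direction {direction!r}")


def _all_states(n: int) -> np.ndarray:
    """All 2^n binary vectors of length n, one per row."""
    return ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)


def _check_enumerable(params: RBMParams) -> None:
    if params.n_visible + params.n_hidden > ENUM_LIMIT:
        raise ValueError(
            f"model too large to enumerate ({params.n_visible}+{params.n_hidden} "
            f"units, limit {ENUM_LIMIT})")


def _neg_energies(params: RBMParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    V = _all_states(params.n_visible)
    H = _all_states(params.n_hidden)
    negE = V @ params.W @ H.T + (V @ params.b)[:, None] + (H @ params.c)[None, :]
    return V, H, negE


def exact_partition(params: RBMParams) -> float:
    """Z = Σ_{v,h} exp(−E), by exhaustive enumeration (tiny models only)."""
    _check_enumerable(params)
    _, _, negE = _neg_energies(params)
    return float(np.exp(logsumexp(negE)))


def joint_probability(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """P(v,h) = exp(−E(v,h))/Z for an enumerable RBM."""
    _check_enumerable(params)
    _, _, negE = _neg_energies(params)
    return float(np.exp(-energy(v, h, params) - logsumexp(negE)))


def model_expectations(params: RBMParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact ⟨v hᵀ⟩, ⟨v⟩, ⟨h⟩ under the model, by enumeration (oracle)."""
    _check_enumerable(params)
    V, H, negE = _neg_energies(params)
    P = np.exp(negE - logsumexp(negE))
    Evh = V.T @ P @ H
    Ev = V.T @ P.sum(axis=1)
    Eh = H.T @ P.sum(axis=0)
    return Evh, Ev, Eh


def exact_log_likelihood(params: RBMParams, V: np.ndarray) -> float:
    """Mean log P(v) over rows of V, by enumeration over hidden states."""
    _check_enumerable(params)
    H = _all_states(params.n_hidden)
    # log Σ_h exp(vᵀWh + bᵀv + cᵀh) − log Z
    scores = V @ params.W @ H.T + (V @ params.b)[:, None] + (H @ params.c)[None, :]
    _, _, negE = _neg_energies(params)
    return float(np.mean(logsumexp(scores, axis=1)) - logsumexp(negE))


def _cd_stats(params: RBMParams, batch: np.ndarray, k: int,
              rng: np.random.Generator):
    """Positive/negative sufficient statistics of one CD-k step."""
    v0 = batch
    ph0 = conditionals(v0, params, "hidden_given_visible")
    v = v0
    for _ in range(k):
        h = (rng.random(ph0.shape) < conditionals(v, params, "hidden_given_visible")
             ).astype(float)
        pv = conditionals(h, params, "visible_given_hidden")
        v = (rng.random(pv.shape) < pv).astype(float)
    phk = conditionals(v, params, "hidden_given_visible")
    B = len(batch)
    pos = (v0.T @ ph0 / B, v0.mean(axis=0), ph0.mean(axis=0))
    neg = (v.T @ phk / B, v.mean(axis=0), phk.mean(axis=0))
    return pos, neg


def cd_update(params: RBMParams, batch: np.ndarray, k: int, eta: float,
              seed: int) -> RBMParams:
    """One contrastive-divergence parameter update on a batch.

    Positive statistics use data-clamped hidden probabilities; negative
    statistics come from a k-step Gibbs chain started at the data (sampled
    states, with probabilities for the final hidden layer).
    """
    batch = np.asarray(batch, dtype=float)
    if batch.size == 0:
        raise ValueError("batch must be nonempty")
    if batch.ndim != 2 or batch.shape[1] != params.n_visible:
        raise ValueError("batch width does not match n_visible")
    rng = substream(seed, "cd")
    (pW, pb, pc), (nW, nb, nc) = _cd_stats(params, batch, k, rng)
    return RBMParams(params.W + eta * (pW - nW),
                     params.b + eta * (pb - nb),
                     params.c + eta * (pc - nc))


def train_rbm(X: np.ndarray, n_hidden: int, config: TrainConfig,
              layer_seed: int = 0) -> tuple[RBMParams, list[float]]:
    """CD-k mini-batch training of one RBM; returns params + per-epoch
    reconstruction mean-squared error."""
    X = np.asarray(X, dtype=float)
    if n_hidden < 1:
        raise ValueError("layer size must be positive")
    if X.min() < 0 or X.max() > 1:
        raise ValueError("visible data must lie in [0,1]")
    rng = substream(config.seed, "rbm-init", layer_seed)
    # 1/sqrt(fan-in) scale: large enough that CD has correlation signal to
    # amplify and the unrolled network backpropagates without vanishing
    params = RBMParams(rng.standard_normal((X.shape[1], n_hidden)) / np.sqrt(X.shape[1]),
                       np.zeros(X.shape[1]), np.zeros(n_hidden))
    chain = substream(config.seed, "rbm-chain", layer_seed)
    order = substream(config.seed, "rbm-order", layer_seed)
    history: list[float] = []
    n = len(X)
    for epoch in range(config.epochs):
        eta = config.lr_at(epoch)
        perm = order.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = X[perm[start:start + config.batch_size]]
            (pW, pb, pc), (nW, nb, nc) = _cd_stats(params, batch, config.cd_k, chain)
            params = RBMParams(params.W + eta * (pW - nW),
                               params.b + eta * (pb - nb),
                               params.c + eta * (pc - nc))
        ph = conditionals(X, params, "hidden_given_visible")
        recon = conditionals(ph, params, "visible_given_hidden")
        history.append(float(((X - recon) ** 2).mean()))
    return params, history


def pretrain_stack(X: np.ndarray, layer_sizes: Sequence[int],
                   config: TrainConfig) -> list[RBMParams]:
    """Greedy layer-wise pretraining; mean-field propagation between layers."""
    if any(s <= 0 for s in layer_sizes):
        raise ValueError("layer sizes must be positive")
    data = np.asarray(X, dtype=float)
    stack: list[RBMParams] = []
    for depth, size in enumerate(layer_sizes):
        params, _ = train_rbm(data, size, config, layer_seed=depth)
        stack.append(params)
        data = conditionals(data, params, "hidden_given_visible")
    return stack


# ---------------------------------------------------------------------------
# supervised fine-tuning (unrolled logistic network + softmax head)

@dataclass
class HDBNModel:
    """Unrolled stack (logistic layers) plus a 2-class softmax head."""

    weights: list[np.ndarray]   # layer weight matrices, chained shapes
    biases: list[np.ndarray]
    head_W: np.ndarray          # (top_size, 2)
    head_b: np.ndarray          # (2,)
    layer_sizes: list[int]
    history: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for W_l, W_next in zip(self.weights, self.weights[1:]):
            if W_l.shape[1] != W_next.shape[0]:
                raise ValueError("adjacent layer dimensions do not chain")
        if self.weights and self.weights[-1].shape[1] != self.head_W.shape[0]:
            raise ValueError("head input dim must equal top layer size")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: HDBNModel, X: np.ndarray) -> list[np.ndarray]:
    acts = [np.asarray(X, dtype=float)]
    for W, b in zip(model.weights, model.biases):
        acts.append(expit(acts[-1] @ W + b))
    return acts


def extract_features(model: HDBNModel, X: np.ndarray) -> np.ndarray:
    """Top-layer activations (pre-head): the hierarchical feature matrix."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError("input width does not match the model")
    return _forward(model, X)[-1]


def predict_proba(model: HDBNModel, X: np.ndarray) -> np.ndarray:
    """Class-probability rows from the softmax head (dropout disabled)."""
    top = extract_features(model, X)
    return _softmax(top @ model.head_W + model.head_b)


def loss_and_grads(model: HDBNModel, X: np.ndarray, y: np.ndarray, l2: float,
                   dropout_mask: np.ndarray | None = None):
    """L2-regularized cross-entropy and analytic gradients via backprop.

    Returns (loss, grads) with grads ordered [W_0, b_0, …, head_W, head_b].
    ``dropout_mask`` (already inverted-scaled) multiplies the head input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ValueError("label/feature row mismatch")
    n = len(X)
    acts = _forward(model, X)
    top = acts[-1] if dropout_mask is None else acts[-1] * dropout_mask
    proba = _softmax(top @ model.head_W + model.head_b)
    eps = 1e-12
    ce = -np.mean(np.log(np.clip(proba[np.arange(n), y], eps, 1.0)))
    reg = l2 * (sum(float((W**2).sum()) for W in model.weights)
                + float((model.head_W**2).sum()))
    onehot = np.eye(2)[y]
    dlogits = (proba - onehot) / n
    g_headW = top.T @ dlogits + 2 * l2 * model.head_W
    g_headb = dlogits.sum(axis=0)
    delta = dlogits @ model.head_W.T
    if dropout_mask is not None:
        delta = delta * dropout_mask
    gWs: list[np.ndarray] = []
    gbs: list[np.ndarray] = []
    for idx in range(len(model.weights) - 1, -1, -1):
        a = acts[idx + 1]
        delta = delta * a * (1 - a)  # through the logistic nonlinearity
        gWs.append(acts[idx].T @ delta + 2 * l2 * model.weights[idx])
        gbs.append(delta.sum(axis=0))
        delta = delta @ model.weights[idx].T
    gWs.reverse()
    gbs.reverse()
    grads = [g for pair in zip(gWs, gbs) for g in pair] + [g_headW, g_headb]
    return ce + reg, grads


def _model_params(model: HDBNModel) -> list[np.ndarray]:
    out = [g for pair in zip(model.weights, model.biases) for g in pair]
    return out + [model.head_W, model.head_b]


def finetune(stack: Sequence[RBMParams], X: np.ndarray, y: np.ndarray,
             config: TrainConfig, X_val: np.ndarray | None = None,
             y_val: np.ndarray | None = None) -> HDBNModel:
    """Unroll a pretrained stack and train it end-to-end with labels.

    Layer weights initialize from each RBM's (W, c); the softmax head starts
    small and random.  All layers update (full backprop).  With a validation
    set, early stopping restores the best-validation-loss parameters after
    ``patience`` epochs without improvement.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ValueError("label/feature row mismatch")
    rng = substream(config.seed, "finetune-init")
    top = stack[-1].n_hidden
    model = HDBNModel([p.W.copy() for p in stack], [p.c.copy() for p in stack],
                      rng.standard_normal((top, 2)) / np.sqrt(top), np.zeros(2),
                      [p.n_hidden for p in stack])
    _train_supervised(model, _model_params(model), loss_and_grads,
                      X, y, X_val, y_val, config, head_width=top, kind="hdbn")
    return model


def _train_supervised(model, params: list[np.ndarray], loss_fn,
                      X, y, X_val, y_val, config: TrainConfig,
                      head_width: int, kind: str) -> None:
    """Shared mini-batch SGD/Adam loop with decay, dropout and early stop."""
    n = len(X)
    order = substream(config.seed, kind, "order")
    drop = substream(config.seed, kind, "dropout")
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    t = 0
    best_val = np.inf
    best_params = None
    stale = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        eta = config.lr_at(epoch)
        perm = order.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            mask = None
            if config.dropout > 0:
                keep = 1.0 - config.dropout
                mask = (drop.random((len(idx), head_width)) < keep) / keep
            _, grads = loss_fn(model, X[idx], y[idx], config.l2, mask)
            t += 1
            for p, g, m, v in zip(params, grads, adam_m, adam_v):
                if not np.all(np.isfinite(g)):
                    raise FloatingPointError("non-finite gradient")
                if config.optimizer == "adam":
                    b1, b2, eps = 0.9, 0.999, 1e-8
                    m[...] = b1 * m + (1 - b1) * g
                    v[...] = b2 * v + (1 - b2) * g**2
                    p -= eta * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
                else:
                    p -= eta * g
        tr_loss, _ = loss_fn(model, X, y, config.l2, None)
        history["train_loss"].append(float(tr_loss))
        if X_val is not None and len(X_val):
            val_loss, _ = loss_fn(model, X_val, y_val, config.l2, None)
            history["val_loss"].append(float(val_loss))
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = [p.copy() for p in params]
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_params is not None:
        for p, bp in zip(params, best_params):
            p[...] = bp
    model.history = history
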