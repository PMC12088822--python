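"""JSON model bundles: shapes + flattened arrays, round-trip safe."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ensemble import CAENConfig, CAENModel, EnsembleState
from .hdbn import HDBNModel, TrainConfig
from .learners import LearnerModel

__all__ = ["save_model", "load_model", "save_learner", "load_learner"]


def _arr(a: np.ndarray) -> dict:
    a = np.asarray(a, dtype=float)
    return {"shape": list(a.shape), "data": a.ravel().tolist()}


def _unarr(d: dict) -> np.ndarray:
    return np.asarray(d["data"], dtype=float).reshape(d["shape"])


def _dump_learner(model) -> dict:
    if isinstance(model, HDBNModel):
        return {"kind": "hdbn",
                "weights": [_arr(w) for w in model.weights],
                "biases": [_arr(b) for b in model.biases],
                "head_W": _arr(model.head_W), "head_b": _arr(model.head_b),
                "layer_sizes": list(model.layer_sizes)}
    return {"kind": model.kind,
            "params": {k: _arr(v) for k, v in model.params.items()},
            "arch": model.arch}


def _load_learner(d: dict):
    if d["kind"] == "hdbn":
        return HDBNModel([_unarr(w) for w in d["weights"]],
                         [_unarr(b) for b in d["biases"]],
                         _unarr(d["head_W"]), _unarr(d["head_b"]),
                         list(d["layer_sizes"]))
    return LearnerModel(d["kind"], {k: _unarr(v) for k, v in d["params"].items()},
                        dict(d["arch"]))


def save_learner(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_dump_learner(model)))


def load_learner(path: str | Path):
    return _load_learner(json.loads(Path(path).read_text()))


def save_model(model: CAENModel, path: str | Path) -> None:
    payload = {
        "learners": {n: _dump_learner(m) for n, m in model.learners.items()},
        "losses": model.state.losses.tolist(),
        "weights": model.state.weights.tolist(),
        "iteration": model.state.iteration,
        "history": [[l.tolist(), w.tolist()] for l, w in model.state.history],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> CAENModel:
    d = json.loads(Path(path).read_text())
    state = EnsembleState(np.asarray(d["losses"]), np.asarray(d["weights"]),
                          int(d["iteration"]),
                          [(np.asarray(l), np.asarray(w)) for l, w in d["history"]])
    learners = {n: _load_learner(m) for n, m in d["learners"].items()}
    return CAENModel(learners, state, CAENConfig())
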