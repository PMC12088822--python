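"""End-to-end orchestration: simulate → preprocess → train → predict → report."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import ensemble, metrics, synthdata
from .config import RunConfig
from .data import LabeledDataset
from .preprocess import Preprocessor, ProcessedSplits

__all__ = ["run_pipeline", "preprocess_dataset"]

log = logging.getLogger("hdbncaen")


def preprocess_dataset(data: LabeledDataset, config: RunConfig) -> ProcessedSplits:
    pre = Preprocessor(outlier_method=config.outlier_method,
                       z_threshold=config.z_threshold,
                       remove_outliers=config.remove_outliers,
                       knn_k=config.knn_k, fractions=config.fractions,
                       seed=config.seed)
    return pre.run(data)


def run_pipeline(config: RunConfig, data: LabeledDataset | None = None,
                 return_artifacts: bool = False):
    """Run every stage and return a JSON-serializable report.

    Without explicit ``data``, a synthetic dataset is generated from the
    config's generator settings.  The report carries the fitted ensemble
    weights, per-learner validation losses, and all eight classification
    metrics on the held-out test part.
    """
    t0 = time.time()
    if data is None:
        data = synthdata.make_dataset(config.synth_spec())
    log.info("stage=simulate seed=%d rows=%d", config.seed, len(data))

    t1 = time.time()
    splits = preprocess_dataset(data, config)
    log.info("stage=preprocess seed=%d train=%d valid=%d test=%d features=%d",
             config.seed, len(splits.y_train), len(splits.y_valid),
             len(splits.y_test), splits.X_train.shape[1])

    t2 = time.time()
    model = ensemble.fit(
        (splits.X_train, splits.y_train, splits.seq_train),
        (splits.X_valid, splits.y_valid, splits.seq_valid),
        config.caen_config())
    log.info("stage=train seed=%d weights=%s", config.seed,
             np.round(model.state.weights, 4).tolist())

    t3 = time.time()
    proba, labels = ensemble.predict(model, splits.X_test, splits.seq_test)
    cm = metrics.confusion(splits.y_test, labels)
    report = metrics.classification_report(cm)
    t4 = time.time()
    log.info("stage=evaluate seed=%d accuracy=%.4f", config.seed, report.accuracy)

    report = {
        "seed": config.seed,
        "n_rows": len(data),
        "split_sizes": {"train": int(len(splits.y_train)),
                        "valid": int(len(splits.y_valid)),
                        "test": int(len(splits.y_test))},
        "learners": model.names,
        "validation_losses": model.state.losses.tolist(),
        "ensemble_weights": model.state.weights.tolist(),
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "metrics": report.as_dict(),
        "durations_s": {"simulate": round(t1 - t0, 3),
                        "preprocess": round(t2 - t1, 3),
                        "train": round(t3 - t2, 3),
                        "evaluate": round(t4 - t3, 3)},
    }
    # metrics block sanity: NaN markers are serialized as null
    report["metrics"] = {k: (None if v != v else v)
                         for k, v in report["metrics"].items()}
    if return_artifacts:
        return report, model, splits
    return report
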