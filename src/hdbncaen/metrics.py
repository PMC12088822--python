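"""Classification and segmentation evaluation metrics.

Everything classification-side derives from a 2×2 confusion matrix: accuracy,
precision, recall, specificity, the error-rate family (FPR, FNR, FDR), and
the Matthews correlation coefficient.  Rates with a zero denominator return
NaN — an explicit undefined marker — rather than a fabricated 0; MCC alone
follows the field's convention of 0 when a denominator factor vanishes.

Segmentation-side metrics compare binary masks or grayscale grids: Dice
overlap, windowed structural similarity (standard constants K1=0.01, K2=0.03,
11×11 Gaussian window σ=1.5), and the proportion of non-overlapping tiles
whose pixelwise agreement meets a threshold (tile 16, threshold 0.9 by
default — a pragmatic operationalization, see docs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

__all__ = [
    "ConfusionMatrix", "ClassificationReport", "SegmentationReport",
    "confusion", "basic_rates", "error_rates", "mcc",
    "dice", "ssim", "patch_proportion", "classification_report",
    "round_half_up",
]

UNDEFINED = float("nan")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero (display convention)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    fpr: float
    fnr: float
    fdr: float
    mcc: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SegmentationReport:
    dice: float
    ssim: float
    patch_proportion: float


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Counts of a binary prediction against truth (positive class = 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size and not (np.isin(y_true, (0, 1)).all()
                            and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def basic_rates(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, specificity)."""
    return (
        _ratio(cm.tp + cm.tn, cm.total),
        _ratio(cm.tp, cm.tp + cm.fp),
        _ratio(cm.tp, cm.tp + cm.fn),
        _ratio(cm.tn, cm.tn + cm.fp),
    )


def error_rates(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(FPR, FNR, FDR) = (FP/(FP+TN), FN/(FN+TP), FP/(FP+TP))."""
    return (
        _ratio(cm.fp, cm.fp + cm.tn),
        _ratio(cm.fn, cm.fn + cm.tp),
        _ratio(cm.fp, cm.fp + cm.tp),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [−1, 1] (0 on a degenerate matrix)."""
    tp, fp, fn, tn = (float(cm.tp), float(cm.fp), float(cm.fn), float(cm.tn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def classification_report(cm: ConfusionMatrix) -> ClassificationReport:
    acc, prec, rec, spec = basic_rates(cm)
    fpr, fnr, fdr = error_rates(cm)
    return ClassificationReport(acc, prec, rec, spec, fpr, fnr, fdr, mcc(cm))


# ---------------------------------------------------------------------------
# segmentation / image metrics

def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError("inputs must have the same shape")


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks count as identical."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    _check_shapes(a, b)
    size = a.sum() + b.sum()
    if size == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / size)


def ssim(img_a, img_b) -> float:
    """Mean local structural similarity with Gaussian 11×11 window, σ=1.5."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    _check_shapes(a, b)
    if min(a.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    rng = max(a.max(), b.max()) - min(a.min(), b.min())
    if rng == 0:
        return 1.0
    return float(_skimage_ssim(a, b, gaussian_weights=True, sigma=1.5,
                               use_sample_covariance=False, data_range=rng))


def patch_proportion(mask_a, mask_b, patch_size: int = 16,
                     agreement_threshold: float = 0.9) -> float:
    """Fraction of non-overlapping tiles whose pixel agreement ≥ threshold.

    Masks are zero-padded on the bottom/right so tiles cover them exactly.
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    _check_shapes(a, b)
    h, w = a.shape
    H = -(-h // patch_size) * patch_size
    W = -(-w // patch_size) * patch_size
    pa = np.zeros((H, W), dtype=bool)
    pb = np.zeros((H, W), dtype=bool)
    pa[:h, :w] = a
    pb[:h, :w] = b
    agree = (pa == pb).reshape(H // patch_size, patch_size,
                               W // patch_size, patch_size)
    frac = agree.mean(axis=(1, 3))
    return float((frac >= agreement_threshold).mean())
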