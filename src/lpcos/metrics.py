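"""Segmentation evaluation, global and restricted to small vessels.

Global metrics are the usual pixel-wise sensitivity Se = TP/(TP+FN),
specificity Sp = TN/(TN+FP), accuracy and ROC/AUC, counted over
field-of-view pixels only.

Small vessels (width under 65 um) are isolated from the ground truth by
morphological opening with a disk of that diameter: the opening removes
every structure thinner than the disk, so the small-vessel ground truth
is exactly gt AND NOT opening(gt).  Sensitivity on those pixels is

    Se_sv = TP_sv / (TP_sv + FN_sv),

and the small-vessel ROC plots Se_sv against the *global* false positive
rate 1 - Sp over thresholds, with AUC_sv its trapezoidal area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import opening as _sk_opening, disk
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import BinaryMask, ProbabilityMap

__all__ = [
    "ConfusionCounts",
    "SmallVesselCounts",
    "ROCCurve",
    "confusion_counts",
    "roc_curve",
    "small_vessel_gt",
    "small_vessel_metrics",
    "um_to_px",
    "EvalReport",
    "evaluate",
]


def _pix(m) -> np.ndarray:
    if isinstance(m, BinaryMask):
        return m.pixels
    if isinstance(m, ProbabilityMap):
        return m.pixels
    return np.asarray(m)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


@dataclass
class SmallVesselCounts:
    tp_sv: int
    fn_sv: int

    @property
    def sensitivity(self) -> float:
        total = self.tp_sv + self.fn_sv
        return self.tp_sv / total if total else float("nan")


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion_counts(pred, gt, fov) -> ConfusionCounts:
    """Pixel-wise confusion counts over in-FOV pixels."""
    pred, gt, fov = _pix(pred).astype(bool), _pix(gt).astype(bool), _pix(fov).astype(bool)
    if not (pred.shape == gt.shape == fov.shape):
        raise ValueError("prediction, ground truth and FOV shapes must match")
    if not fov.any():
        raise ValueError("empty FOV")
    p, g = pred[fov], gt[fov]
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, tn, fp, fn)


def roc_curve(prob, gt, fov) -> ROCCurve:
    """ROC over in-FOV pixels with trapezoidal AUC."""
    scores = _pix(prob)
    gt, fov = _pix(gt).astype(bool), _pix(fov).astype(bool)
    if not (scores.shape == gt.shape == fov.shape):
        raise ValueError("score, ground truth and FOV shapes must match")
    y = gt[fov].ravel()
    s = scores[fov].ravel().astype(np.float64)
    if y.all() or not y.any():
        missing = "negative" if y.all() else "positive"
        raise ValueError(f"ground truth has no {missing} pixels inside the FOV")
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thr, fpr, tpr, auc)


def um_to_px(diameter_um: float, pixel_size_um: float | None) -> int:
    """Physical kernel diameter to the nearest odd pixel count (>= 1)."""
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError(
            "pixel size in um is unknown; pass an explicit kernel size in px"
        )
    ratio = diameter_um / pixel_size_um
    # nearest odd integer, at least 1
    odd = int(2 * round((ratio - 1) / 2) + 1)
    return max(odd, 1)


def small_vessel_gt(gt, kernel_diameter_px: int) -> np.ndarray:
    """Ground-truth pixels removed by opening with a disk of that diameter."""
    gt = _pix(gt).astype(bool)
    if kernel_diameter_px < 1:
        raise ValueError("kernel diameter must be >= 1 px")
    if kernel_diameter_px % 2 == 0:
        raise ValueError("kernel diameter must be odd for a symmetric disk")
    if kernel_diameter_px == 1:
        return np.zeros_like(gt)  # opening with a single pixel is identity
    radius = (kernel_diameter_px - 1) // 2
    opened = _sk_opening(gt, disk(radius))
    return gt & ~opened


def _sv_sweep(
    scores: np.ndarray, is_sv: np.ndarray, is_neg: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Se_sv and global FPR at every distinct score threshold (descending)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    sv = is_sv[order].astype(np.int64)
    neg = is_neg[order].astype(np.int64)
    csv = np.cumsum(sv)
    cneg = np.cumsum(neg)
    # last index of each tied block of equal scores
    last = np.nonzero(np.diff(s, append=-np.inf))[0]
    tpr_sv = csv[last] / max(int(sv.sum()), 1)
    fpr = cneg[last] / max(int(neg.sum()), 1)
    thr = s[last]
    # prepend the (0, 0) endpoint at threshold above the maximum
    return (
        np.concatenate([[thr[0] + 1], thr]),
        np.concatenate([[0.0], fpr]),
        np.concatenate([[0.0], tpr_sv]),
    )


def small_vessel_metrics(
    prob_or_pred,
    gt,
    fov,
    kernel_diameter_px: int,
    thresholds: np.ndarray | None = None,
    open_prediction: bool = False,
) -> tuple[SmallVesselCounts, float, ROCCurve | None, float | None]:
    """Small-vessel sensitivity and, for score inputs, the ROC_sv/AUC_sv.

    Returns ``(counts, se_sv, roc_sv, auc_sv)``.  For a binary prediction
    the ROC entries are ``None``.  ``open_prediction`` additionally removes
    the opening of the prediction before matching, i.e. credits only
    predicted-thin structure.
    """
    gt_b = _pix(gt).astype(bool)
    fov_b = _pix(fov).astype(bool)
    sv = small_vessel_gt(gt_b, kernel_diameter_px) & fov_b
    if not sv.any():
        raise ValueError(
            "small-vessel ground truth is empty; use a larger opening kernel"
        )
    arr = _pix(prob_or_pred)
    is_binary = arr.dtype == bool

    def counts_for(pred: np.ndarray) -> SmallVesselCounts:
        if open_prediction:
            pred = pred & ~_sk_opening(pred, disk((kernel_diameter_px - 1) // 2))
        tp_sv = int(np.count_nonzero(pred & sv))
        return SmallVesselCounts(tp_sv, int(sv.sum()) - tp_sv)

    if is_binary:
        c = counts_for(arr & fov_b)
        return c, c.sensitivity, None, None

    scores = arr[fov_b].ravel().astype(np.float64)
    sv_flat = sv[fov_b].ravel()
    neg_flat = ~gt_b[fov_b].ravel()
    if open_prediction:
        # threshold sweep with per-threshold opening is quadratic; evaluate
        # on a decimated threshold grid instead
        uniq = np.unique(scores)[::-1]
        if thresholds is None:
            thresholds = uniq if uniq.size <= 64 else np.linspace(1, 0, 65)
        tprs, fprs = [0.0], [0.0]
        for t in thresholds:
            pred = (arr >= t) & fov_b
            c = counts_for(pred)
            tprs.append(c.sensitivity)
            fprs.append(np.count_nonzero(pred & ~gt_b & fov_b) / max(int(neg_flat.sum()), 1))
        order = np.argsort(fprs, kind="stable")
        fpr = np.asarray(fprs)[order]
        tpr = np.asarray(tprs)[order]
        thr = np.concatenate([[np.inf], thresholds])[order]
    else:
        thr, fpr, tpr = _sv_sweep(scores, sv_flat, neg_flat)
    # close the curve at (1, 1)
    if fpr[-1] < 1.0 or tpr[-1] < 1.0:
        fpr = np.concatenate([fpr, [1.0]])
        tpr = np.concatenate([tpr, [1.0]])
        thr = np.concatenate([thr, [-np.inf]])
    auc_sv = float(np.trapezoid(tpr, fpr))
    roc = ROCCurve(thr, fpr, tpr, auc_sv)
    # counts at the conventional 0.5 threshold
    c = counts_for((arr >= 0.5) & fov_b)
    return c, c.sensitivity, roc, auc_sv


@dataclass
class EvalReport:
    """Aggregate evaluation of one probability map against ground truth."""

    confusion: ConfusionCounts
    se: float
    sp: float
    acc: float
    auc: float
    se_sv: float | None
    auc_sv: float | None
    threshold: float
    kernel_diameter_px: int | None

    def to_dict(self) -> dict:
        return {
            "schema": "lpcos-eval-1",
            "tp": self.confusion.tp,
            "tn": self.confusion.tn,
            "fp": self.confusion.fp,
            "fn": self.confusion.fn,
            "Se": self.se,
            "Sp": self.sp,
            "Acc": self.acc,
            "AUC": self.auc,
            "Se_sv": self.se_sv,
            "AUC_sv": self.auc_sv,
            "threshold": self.threshold,
            "kernel_diameter_px": self.kernel_diameter_px,
        }


def evaluate(
    prob,
    gt,
    fov,
    threshold: float = 0.5,
    kernel_diameter_px: int | None = None,
) -> EvalReport:
    """Full report: global Se/Sp/Acc/AUC plus small-vessel Se_sv/AUC_sv."""
    scores = _pix(prob)
    pred = scores >= threshold
    cc = confusion_counts(pred, gt, fov)
    roc = roc_curve(prob, gt, fov)
    se_sv = auc_sv = None
    if kernel_diameter_px is not None:
        counts, se_at_t, _, auc_sv = small_vessel_metrics(
            prob, gt, fov, kernel_diameter_px
        )
        pred_counts = small_vessel_metrics(pred, gt, fov, kernel_diameter_px)[0]
        se_sv = pred_counts.sensitivity
    return EvalReport(
        cc,
        cc.sensitivity,
        cc.specificity,
        cc.accuracy,
        roc.auc,
        se_sv,
        auc_sv,
        threshold,
        kernel_diameter_px,
    )
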