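"""Pixel- and image-level anomaly evaluation.

Implements the full metric protocol: AUROC (rank / Mann-Whitney form, via
scikit-learn), AUPRC (stepwise precision-recall integration), PRO
(per-region overlap integrated over the false-positive rate up to a cap,
default 0.3), and maximum Dice over all thresholds — which equals the maximum
F1 score; both sweeps are coded independently here and their equality is
asserted on every run. Specificity, accuracy and precision are reported at
the F1-optimal threshold (binarization convention: score >= threshold is
positive).

Pixel-level evaluation normalizes scores within each volume, computes the
metrics per volume and averages them across volumes; image (slice)-level
evaluation normalizes across the whole dataset, reduces each slice to its
maximum pixel score, and pools all slices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from sklearn.metrics import average_precision_score, roc_auc_score

from .pipeline import AnomalyMap

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "best_f1_threshold",
    "max_dice",
    "threshold_metrics",
    "auroc",
    "auprc",
    "pro_score",
    "evaluate_pixel_level",
    "evaluate_image_level",
]


@dataclass
class EvalReport:
    level: str                      # "pixel" or "image"
    auroc: float
    auprc: float
    max_dice: float                 # == max F1 (asserted at computation time)
    f1: float
    specificity: float
    accuracy: float
    precision: float
    f1_threshold: float
    pro: float | None = None        # pixel level only
    n_volumes: int = 0
    n_excluded: int = 0
    per_volume_breakdown: list[dict] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).ravel()
    uniq = np.unique(labels)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"labels must be binary 0/1, found values {uniq}")
    return labels.astype(np.int64)


def best_f1_threshold(scores, labels) -> tuple[float, float]:
    """Exhaustive F1 sweep over the distinct score values.

    Descending cumulative-sum sweep; ties in F1 break toward the smallest
    threshold. Requires at least one positive label.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = _check_labels(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("best_f1_threshold requires at least one positive label")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp_cum = np.cumsum(l_sorted)
    # last index of each run of equal scores = the point where 'scores >= t'
    # includes the whole run
    last = np.nonzero(np.r_[np.diff(s_sorted) != 0, True])[0]
    tp = tp_cum[last].astype(np.float64)
    k = (last + 1).astype(np.float64)       # number predicted positive
    fp = k - tp
    fn = n_pos - tp
    f1 = 2 * tp / (2 * tp + fp + fn)
    best = f1.max()
    # thresholds descend with k; the largest k achieving the max is the
    # smallest threshold
    idx = np.nonzero(f1 == best)[0][-1]
    return float(s_sorted[last[idx]]), float(best)


def max_dice(scores, labels) -> float:
    """Maximum Dice coefficient over all thresholds.

    Independently coded from :func:`best_f1_threshold` (ascending sweep with
    suffix sums); the two agree exactly because Dice == F1 at every threshold.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = _check_labels(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("max_dice requires at least one positive label")
    order = np.argsort(scores, kind="stable")  # ascending
    s_sorted = scores[order]
    l_sorted = labels[order]
    n = len(s_sorted)
    # suffix sums: positives with score >= s_sorted[i]
    tp_suffix = np.cumsum(l_sorted[::-1])[::-1].astype(np.float64)
    first = np.nonzero(np.r_[True, np.diff(s_sorted) != 0])[0]  # first of each run
    tp = tp_suffix[first]
    pred_pos = (n - first).astype(np.float64)
    dice = 2 * tp / (pred_pos + n_pos)  # 2TP / (2TP + FP + FN)
    return float(dice.max())


def threshold_metrics(scores, labels, threshold: float) -> tuple[float, float, float, float]:
    """(specificity, accuracy, precision, f1) binarizing at score >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = _check_labels(labels)
    pred = scores >= threshold
    pos = labels == 1
    tp = float(np.count_nonzero(pred & pos))
    fp = float(np.count_nonzero(pred & ~pos))
    fn = float(np.count_nonzero(~pred & pos))
    tn = float(np.count_nonzero(~pred & ~pos))

    def _safe(num, den, name):
        if den == 0:
            logger.warning("zero division in %s; returning 0", name)
            return 0.0
        return num / den

    specificity = _safe(tn, tn + fp, "specificity")
    accuracy = _safe(tp + tn, tp + tn + fp + fn, "accuracy")
    precision = _safe(tp, tp + fp, "precision")
    f1 = _safe(2 * tp, 2 * tp + fp + fn, "f1")
    return specificity, accuracy, precision, f1


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney rank formulation)."""
    labels = _check_labels(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64).ravel()))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (stepwise integration)."""
    labels = _check_labels(labels)
    if labels.min() == 1:  # all positive: any threshold has precision 1
        return 1.0
    if labels.max() == 0:
        raise ValueError("AUPRC requires at least one positive label")
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64).ravel()))


def _pro_curve_points(score_list, mask_list, max_thresholds: int = 2048):
    """(fpr, pro) points over a descending threshold sweep, pooled volumes."""
    neg_scores = []
    region_scores = []
    for scores, mask in zip(score_list, mask_list):
        scores = np.asarray(scores, dtype=np.float64)
        mask = np.asarray(mask).astype(bool)
        labeled, n_regions = ndimage.label(mask)
        for r in range(1, n_regions + 1):
            region_scores.append(np.sort(scores[labeled == r]))
        neg_scores.append(scores[~mask].ravel())
    if not region_scores:
        raise ValueError("PRO requires at least one connected anomalous region")
    neg_sorted = np.sort(np.concatenate(neg_scores))
    all_scores = np.unique(np.concatenate([np.unique(s) for s in region_scores] + [np.unique(neg_sorted)]))
    if all_scores.size > max_thresholds:
        qs = np.linspace(0.0, 1.0, max_thresholds)
        thresholds = np.unique(np.quantile(all_scores, qs))
    else:
        thresholds = all_scores
    thresholds = thresholds[::-1]  # descending: FPR grows along the sweep
    n_neg = len(neg_sorted)
    fpr = (n_neg - np.searchsorted(neg_sorted, thresholds, side="left")) / max(n_neg, 1)
    pro = np.zeros_like(thresholds)
    for rs in region_scores:
        pro += (len(rs) - np.searchsorted(rs, thresholds, side="left")) / len(rs)
    pro /= len(region_scores)
    return fpr, pro


def pro_score(score_maps, masks, fpr_cap: float = 0.3) -> float:
    """Per-region overlap integrated over FPR in [0, cap], normalized by cap.

    Mean recall over connected ground-truth regions as the threshold sweeps
    from high to low, integrated against the pooled false-positive rate.
    """
    if isinstance(score_maps, np.ndarray) and isinstance(masks, np.ndarray):
        score_maps, masks = [score_maps], [masks]
    if not any(np.any(np.asarray(m) > 0) for m in masks):
        raise ValueError("PRO requires at least one non-empty mask")
    fpr, pro = _pro_curve_points(list(score_maps), list(masks))
    # prepend the empty-prediction point and integrate up to the cap
    fpr = np.r_[0.0, fpr]
    pro = np.r_[0.0, pro]
    order = np.argsort(fpr, kind="stable")
    fpr, pro = fpr[order], pro[order]
    if fpr[-1] < fpr_cap:  # curve ends before the cap: extend flat
        fpr = np.r_[fpr, fpr_cap]
        pro = np.r_[pro, pro[-1]]
    pro_cap = np.interp(fpr_cap, fpr, pro)
    keep = fpr <= fpr_cap
    xs = np.r_[fpr[keep], fpr_cap]
    ys = np.r_[pro[keep], pro_cap]
    return float(np.trapezoid(ys, xs) / fpr_cap)


def _working_array(m) -> np.ndarray:
    """Rank-equivalent score array for metric computation.

    For flow-produced maps the log-likelihood is used (negated, so larger =
    more anomalous): it orders voxels exactly as the anomaly score
    1 - exp(log p) but stays in a numerically benign range, whereas the
    exponentiated score spans hundreds of orders of magnitude and would
    collapse to ties under min-max normalization in floating point. Plain
    arrays are used as given.
    """
    if isinstance(m, AnomalyMap):
        return -m.logp if m.logp is not None else m.scores
    return np.asarray(m, dtype=np.float64)


def _metric_bundle(scores: np.ndarray, labels: np.ndarray) -> dict:
    thr, f1_best = best_f1_threshold(scores, labels)
    dice = max_dice(scores, labels)
    # Dice == F1 at every threshold, so the two independent sweeps must agree
    assert dice == f1_best, f"max-Dice {dice} != max-F1 {f1_best}"
    spec, acc, prec, f1_at = threshold_metrics(scores, labels, thr)
    return dict(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        max_dice=dice,
        f1=f1_at,
        specificity=spec,
        accuracy=acc,
        precision=prec,
        f1_threshold=thr,
    )


def evaluate_pixel_level(maps, masks) -> EvalReport:
    """Per-volume normalization -> per-volume metrics -> mean across volumes.

    Volumes with empty masks carry no pixel-level anomaly signal and are
    excluded from the averages (their count is logged and reported).
    """
    if len(maps) != len(masks):
        raise ValueError(f"{len(maps)} maps vs {len(masks)} masks")
    arrays = [_working_array(m) for m in maps]
    for i, (m, g) in enumerate(zip(arrays, masks)):
        if m.shape != np.asarray(g).shape:
            raise ValueError(
                f"volume {i}: map shape {m.shape} != mask shape {np.asarray(g).shape}"
            )
    rows = []
    excluded = 0
    for m, g in zip(arrays, masks):
        g = np.asarray(g).astype(np.int64)
        if g.max() == 0:
            excluded += 1
            continue
        lo, hi = float(m.min()), float(m.max())  # per-volume normalization
        scores = np.zeros_like(m) if hi == lo else (m - lo) / (hi - lo)
        row = _metric_bundle(scores.ravel(), g.ravel())
        row["pro"] = pro_score(scores, g)
        rows.append(row)
    if excluded:
        logger.info("excluded %d volume(s) with empty masks from pixel-level averaging", excluded)
    if not rows:
        raise ValueError("no volume with a non-empty mask to evaluate")
    mean = {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}
    return EvalReport(
        level="pixel",
        auroc=mean["auroc"],
        auprc=mean["auprc"],
        max_dice=mean["max_dice"],
        f1=mean["f1"],
        specificity=mean["specificity"],
        accuracy=mean["accuracy"],
        precision=mean["precision"],
        f1_threshold=mean["f1_threshold"],
        pro=mean["pro"],
        n_volumes=len(rows),
        n_excluded=excluded,
        per_volume_breakdown=rows,
    )


def evaluate_image_level(maps, slice_labels) -> EvalReport:
    """Dataset-level normalization -> per-slice max scores -> pooled metrics.

    ``slice_labels`` holds one 0/1 label per axial slice of each volume (a
    slice is anomalous iff its mask contains at least one anomalous voxel).
    """
    if len(maps) != len(slice_labels):
        raise ValueError(f"{len(maps)} maps vs {len(slice_labels)} label vectors")
    arrays = [_working_array(m) for m in maps]
    labels = [np.asarray(l).ravel() for l in slice_labels]
    for i, (m, l) in enumerate(zip(arrays, labels)):
        if m.shape[0] != l.shape[0]:
            raise ValueError(f"volume {i}: {m.shape[0]} slices but {l.shape[0]} labels")
    lo = min(float(m.min()) for m in arrays)  # dataset-level normalization
    hi = max(float(m.max()) for m in arrays)
    normed = [np.zeros_like(m) if hi == lo else (m - lo) / (hi - lo) for m in arrays]
    scores = np.concatenate([m.reshape(m.shape[0], -1).max(axis=1) for m in normed])
    pooled = np.concatenate(labels)
    bundle = _metric_bundle(scores, pooled)
    return EvalReport(
        level="image",
        n_volumes=len(maps),
        pro=None,
        **bundle,
    )
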