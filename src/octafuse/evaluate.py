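"""Inference and evaluation: N-times random-crop prediction with severest
aggregation, cumulative binary-task scores, tie-aware AUC and Cohen's kappa.

Severity grading is ordinal over six levels (no DR, mild NPDR, moderate NPDR,
severe NPDR, PDR, PRP).  Besides the 6-class prediction, four cumulative
binary tasks are scored: task k is "grade >= k+1", so task 0 detects any DR
and task 3 detects proliferative/treated disease.  The task-k score of a
probability vector is the total probability mass at grades >= k+1, which is
non-increasing in k by construction.

A volume is predicted from N random crops; per task the aggregated score is
the maximum over crops (the severest prediction), and the reported discrete
grade is the severest argmax grade across crops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import nn
from .preprocess import random_crop, center_crop
from .synthetic import N_GRADES, ValidationError

N_TASKS = 4
# default crop counts at nominal scale; chosen so widefield volumes, with
# roughly twice the patch-traversal count, get twice the crops
DEFAULT_N_CROPS = {"hr6": 10, "uwf15": 20}


class UndefinedMetricError(ValueError):
    """Metric is undefined for the given inputs (single class, degenerate)."""


@dataclass
class EyePrediction:
    crop_probs: np.ndarray              # (N, 6)
    prob: np.ndarray                    # aggregated (6,)
    task_scores: np.ndarray             # (4,)
    grade: int


@dataclass
class EvalReport:
    kappa: float
    auc: np.ndarray                     # (4,) AUC0..AUC3, nan if undefined
    confusion: np.ndarray               # (6, 6) rows = true grade
    n_eyes: int
    per_task_n_pos: np.ndarray = field(default=None)

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.auc))


# ---------------------------------------------------------------------------
# task scores and severest aggregation
# ---------------------------------------------------------------------------

def _check_prob(p) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (N_GRADES,) or np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-5:
        raise ValidationError("not a valid 6-class probability vector")
    return p


def task_score(p, task_k: int) -> float:
    """Probability of grade >= task_k + 1 (task 3 sums PDR and PRP mass)."""
    if not 0 <= task_k < N_TASKS:
        raise ValidationError(f"task index must be in 0..{N_TASKS - 1}")
    return float(_check_prob(p)[task_k + 1:].sum())


def task_scores(p) -> np.ndarray:
    p = _check_prob(p)
    return np.array([p[k + 1:].sum() for k in range(N_TASKS)])


def aggregate_severest(crop_probs) -> tuple[np.ndarray, np.ndarray, int]:
    """Severest-prediction aggregation over a list of per-crop probabilities.

    Per task the aggregated score is the max over crops of the cumulative
    task score; the aggregated grade is the severest argmax grade, and the
    reported probability vector is that of the crop attaining it (ties broken
    by higher probability of that grade).  Permutation invariant, and adding
    a crop can only raise task scores.
    """
    mat = np.asarray([_check_prob(p) for p in crop_probs])
    if mat.shape[0] < 1:
        raise ValidationError("need at least one crop prediction")
    per_crop_scores = np.stack([np.array([row[k + 1:].sum() for k in range(N_TASKS)])
                                for row in mat])
    agg_scores = per_crop_scores.max(axis=0)
    argmaxes = mat.argmax(axis=1)
    grade = int(argmaxes.max())
    candidates = np.flatnonzero(argmaxes == grade)
    best = candidates[mat[candidates, grade].argmax()]
    return mat[best], agg_scores, grade


# ---------------------------------------------------------------------------
# eye-level prediction
# ---------------------------------------------------------------------------

def _to_input(patch_data: np.ndarray) -> np.ndarray:
    """(X, Y, Z, C) domain patch -> (C, X, Y, Z) network layout."""
    return np.ascontiguousarray(patch_data.transpose(3, 0, 1, 2))


def predict_eye(model, volume, n_crops: int, patch_shape,
                rng: np.random.Generator) -> EyePrediction:
    """Predict one volume from ``n_crops`` random crops, severest-aggregated."""
    if n_crops < 1:
        raise ValidationError("n_crops must be >= 1")
    patches = [random_crop(volume, patch_shape, rng).data for _ in range(n_crops)]
    batch = np.stack([_to_input(p) for p in patches])
    probs = model.predict_proba(batch)
    prob, scores, grade = aggregate_severest(list(probs))
    return EyePrediction(crop_probs=probs, prob=prob, task_scores=scores,
                         grade=grade)


def predict_eye_center(model, volume, patch_shape) -> EyePrediction:
    """Deterministic single center-crop prediction (used for validation)."""
    patch = center_crop(volume, patch_shape).data
    probs = model.predict_proba(_to_input(patch)[None])
    prob, scores, grade = aggregate_severest(list(probs))
    return EyePrediction(crop_probs=probs, prob=prob, task_scores=scores,
                         grade=grade)


def predict_eye_hybrid(hybrid, volumes: dict, patch_shapes: dict,
                       n_crops: dict, rng: np.random.Generator) -> EyePrediction:
    """Aggregate crops within each acquisition, then decision-fuse across.

    ``hybrid`` is a :class:`~octafuse.fusion.HybridModel`; fusion operates on
    the per-acquisition aggregated probability and task-score vectors.
    """
    acqs = hybrid.available(volumes)
    probs_by_acq, scores_by_acq, crop_rows = {}, {}, []
    for acq in acqs:
        pred = predict_eye(hybrid.models[acq], volumes[acq], n_crops[acq],
                           patch_shapes[acq], rng)
        probs_by_acq[acq] = pred.prob
        scores_by_acq[acq] = pred.task_scores
        crop_rows.append(pred.crop_probs)
    fused_p, fused_s = hybrid.fuse(probs_by_acq, scores_by_acq)
    return EyePrediction(crop_probs=np.concatenate(crop_rows),
                         prob=fused_p, task_scores=fused_s,
                         grade=int(np.argmax(fused_p)))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Area under the ROC curve via the tie-aware Mann-Whitney statistic.

    Equals the fraction of (positive, negative) pairs ranked correctly, with
    half credit for ties — ties are frequent for max-aggregated crop scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be aligned 1-D arrays")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: only one class present")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def cohens_kappa(confusion) -> float:
    """Chance-corrected agreement kappa = (p0 - pe) / (1 - pe).

    ``p0`` is the observed accuracy (trace over total) and ``pe`` the chance
    agreement implied by the row/column marginals.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or np.any(cm < 0):
        raise ValidationError("confusion must be a square nonnegative matrix")
    total = cm.sum()
    if total <= 0:
        raise ValidationError("confusion matrix is empty")
    p0 = np.trace(cm) / total
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total ** 2
    if abs(1.0 - pe) < 1e-12:
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    return float((p0 - pe) / (1.0 - pe))


def confusion_matrix(y_true, y_pred, n_classes: int = N_GRADES) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def evaluate_model(predictions, labels) -> EvalReport:
    """Score eye-level predictions: AUC per cumulative task plus 6-class kappa.

    AUC_k compares ``task_scores[k]`` against the binarised label
    (grade >= k+1); tasks with a single class present get NaN.
    """
    if len(predictions) != len(labels):
        raise ValidationError("predictions and labels length mismatch")
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.stack([p.task_scores for p in predictions])
    grades = np.array([p.grade for p in predictions])
    aucs = np.full(N_TASKS, np.nan)
    n_pos = np.zeros(N_TASKS, dtype=np.int64)
    for k in range(N_TASKS):
        binary = (labels >= k + 1).astype(np.int64)
        n_pos[k] = binary.sum()
        try:
            aucs[k] = auc(scores[:, k], binary)
        except UndefinedMetricError:
            pass
    cm = confusion_matrix(labels, grades)
    try:
        kappa = cohens_kappa(cm)
    except UndefinedMetricError:
        kappa = float("nan")
    return EvalReport(kappa=kappa, auc=aucs, confusion=cm,
                      n_eyes=len(labels), per_task_n_pos=n_pos)
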