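"""Confusion-matrix metrics, ROC curves and AUC for two-class predictions.

Accuracy, sensitivity and specificity follow the standard clinical
definitions (in percent):

    accuracy    = (TP + TN) / (TP + FP + TN + FN) * 100
    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100

The ROC curve is a threshold sweep over the continuous discriminant score
(tied scores collapse into a single step); AUC is the trapezoidal area,
which equals the normalised Mann-Whitney U statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray | None  # (m, 2) of (FPR, TPR)
    auc: float | None
    positive_class: str
    dataset_tag: str = "validation"
    patient_level: dict | None = None  # same metrics after per-patient majority vote

    def metrics_row(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion(
    labels_true,
    labels_pred,
    positive_class: str,
) -> tuple[int, int, int, int]:
    """Two-class confusion counts (tp, fp, tn, fn) w.r.t. ``positive_class``."""
    yt = np.asarray(labels_true, dtype=object)
    yp = np.asarray(labels_pred, dtype=object)
    if yt.shape != yp.shape:
        raise ValueError("label sequences differ in length")
    present = set(yt) | set(yp)
    if positive_class not in present:
        present = present | {positive_class}
    if len(present) > 2:
        raise ValueError(f"more than two distinct labels: {sorted(present)}")
    pos_t = yt == positive_class
    pos_p = yp == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    return tp, fp, tn, fn


def metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """(accuracy %, sensitivity %, specificity %); undefined ratios are NaN."""
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("no observations")
    accuracy = 100.0 * (tp + tn) / total
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn > 0 else float("nan")
    specificity = 100.0 * tn / (tn + fp) if tn + fp > 0 else float("nan")
    return accuracy, sensitivity, specificity


def roc_auc(
    scores,
    labels_true,
    positive_class: str,
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from (0,0) to (1,1) and the trapezoidal AUC.

    Thresholds sweep the unique score values from high to low; equal scores
    form a single ROC step.
    """
    s = np.asarray(scores, dtype=float)
    yt = np.asarray(labels_true, dtype=object)
    pos = yt == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # keep only the last index of each tied-score run
    last = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), s.size - 1]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def majority_vote(patient_ids, labels_pred) -> tuple[list[str], list[str]]:
    """Per-patient majority label over that patient's spectra.

    Ties break to the lexicographically larger label (deterministic).
    Returns (patients in first-appearance order, voted labels).
    """
    pids = np.asarray(patient_ids, dtype=object)
    yp = np.asarray(labels_pred, dtype=object)
    patients: list[str] = []
    votes: list[str] = []
    seen: dict[str, None] = {}
    for p in pids:
        seen.setdefault(p, None)
    for p in seen:
        labs = yp[pids == p]
        uniq, counts = np.unique(labs.astype(str), return_counts=True)
        best = counts.max()
        winner = sorted(u for u, c in zip(uniq, counts) if c == best)[-1]
        patients.append(str(p))
        votes.append(winner)
    return patients, votes


def evaluate(
    labels_true,
    labels_pred,
    scores,
    positive_class: str,
    dataset_tag: str = "validation",
    patient_ids=None,
) -> EvaluationReport:
    """Full evaluation: counts, percent metrics, ROC/AUC, and (when
    ``patient_ids`` is given) the same metrics after per-patient majority
    vote."""
    tp, fp, tn, fn = confusion(labels_true, labels_pred, positive_class)
    accuracy, sensitivity, specificity = metrics(tp, fp, tn, fn)
    roc_points: np.ndarray | None = None
    auc: float | None = None
    if scores is not None:
        yt = np.asarray(labels_true, dtype=object)
        if len(set(yt)) == 2:
            roc_points, auc = roc_auc(scores, labels_true, positive_class)

    patient_level = None
    if patient_ids is not None:
        pids = np.asarray(patient_ids, dtype=object)
        yt = np.asarray(labels_true, dtype=object)
        true_by_patient = {p: l for p, l in zip(pids, yt)}
        patients, votes = majority_vote(pids, labels_pred)
        p_true = [true_by_patient[p] for p in patients]
        ptp, pfp, ptn, pfn = confusion(p_true, votes, positive_class)
        pa, ps, pspec = metrics(ptp, pfp, ptn, pfn)
        patient_level = {
            "tp": ptp, "fp": pfp, "tn": ptn, "fn": pfn,
            "accuracy": pa, "sensitivity": ps, "specificity": pspec,
        }

    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        roc_points=roc_points, auc=auc,
        positive_class=positive_class, dataset_tag=dataset_tag,
        patient_level=patient_level,
    )
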