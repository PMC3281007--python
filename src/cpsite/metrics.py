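"""Binary-classification evaluation: ROC/AUC, MCC, PPF and retrieval tables.

The decision threshold convention throughout the package is inclusive:
a residue is predicted viable when its score is >= the threshold.  The
predicted positive fraction (PPF) is the share of all residues called
viable at a threshold; fixing PPF = 0.5 provides a fair basis for
comparing features on datasets without negative labels, where a random
predictor theoretically attains sensitivity 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger("cpsite")


def _validate(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    return scores, labels


def roc_auc(scores, labels) -> Tuple[pd.DataFrame, float]:
    """ROC points (threshold sweep over unique scores, ties grouped) and
    trapezoidal AUC.  Raises on single-class labels."""
    scores, labels = _validate(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return points, auc


def optimal_threshold(roc_points: pd.DataFrame) -> float:
    """Score threshold whose (FPR, TPR) lies nearest to the (0, 1) corner.

    Ties resolve to the higher threshold.  The sweep's sentinel point at
    +inf (no positives predicted) maps back to the maximum finite
    threshold.
    """
    if len(roc_points) == 0:
        raise ValueError("empty ROC")
    d2 = roc_points["fpr"] ** 2 + (1.0 - roc_points["tpr"]) ** 2
    best = d2.min()
    candidates = roc_points.loc[d2 <= best + 1e-15, "threshold"]
    thr = float(candidates.max())
    if math.isinf(thr):
        finite = roc_points["threshold"][np.isfinite(roc_points["threshold"])]
        thr = float(finite.max())
        logger.warning("degenerate ROC; threshold clamped to %g", thr)
    return thr


def confusion_counts(scores, labels, threshold: float) -> Dict[str, int]:
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return {
        "TP": int(np.sum(pred & pos)),
        "FP": int(np.sum(pred & ~pos)),
        "TN": int(np.sum(~pred & ~pos)),
        "FN": int(np.sum(~pred & pos)),
    }


def mcc_from_counts(c: Dict[str, int]) -> float:
    tp, fp, tn, fn = c["TP"], c["FP"], c["TN"], c["FN"]
    denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def mcc_at(scores, labels, threshold: float) -> Tuple[float, Dict[str, int]]:
    """Matthews correlation coefficient at an inclusive threshold."""
    c = confusion_counts(scores, labels, threshold)
    return mcc_from_counts(c), c


def ppf(scores, threshold: float) -> float:
    """Predicted positive fraction: #{score >= threshold} / total."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) == 0:
        raise ValueError("no scores")
    return float(np.mean(scores >= threshold))


def threshold_at_ppf(scores, target_ppf: float) -> Tuple[float, float]:
    """Largest threshold whose PPF is at least the target.

    Returns (threshold, achieved PPF); under score ties the achieved
    fraction may overshoot the target and is reported alongside.
    """
    if not 0 < target_ppf < 1:
        raise ValueError("target PPF must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)[::-1]  # descending
    n = len(scores)
    for t in uniq:
        frac = np.sum(scores >= t) / n
        if frac >= target_ppf:
            achieved = float(frac)
            if achieved > target_ppf:
                logger.info(
                    "PPF overshoot under ties: target %.3f achieved %.3f",
                    target_ppf, achieved,
                )
            return float(t), achieved
    return float(uniq[-1]), 1.0


def retrieval_table(
    scores,
    labels,
    cutoffs: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Retrieval performance at fixed probability-score cutoffs.

    One row per cutoff: PPF, recall, precision, number of viable sites among
    the retrieved residues and total retrieved.  When nothing is retrieved,
    precision is reported as 1.0 with ``empty_retrieval`` flagged so tables
    stay printable.
    """
    if cutoffs is None:
        cutoffs = [0.80, 0.75, 0.70, 0.60, 0.50, 0.40, 0.30, 0.20, 0.10, 0.00]
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    rows = []
    for c in cutoffs:
        pred = scores >= c
        retrieved = int(pred.sum())
        hits = int((pred & (labels == 1)).sum())
        rows.append(
            {
                "cutoff": c,
                "ppf": retrieved / len(scores),
                "recall": hits / n_pos if n_pos else 0.0,
                "precision": hits / retrieved if retrieved else 1.0,
                "empty_retrieval": retrieved == 0,
                "n_viable_retrieved": hits,
                "n_retrieved": retrieved,
            }
        )
    return pd.DataFrame(rows)


def stratified_folds(
    labels, n_folds: int = 10, seed: int = 0
) -> list:
    """Seeded, class-stratified fold index arrays partitioning the data."""
    labels = np.asarray(labels).astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


@dataclass
class EvalReport:
    auc: float
    mcc: float
    sensitivity: float
    specificity: float
    false_positive_rate: float
    decision_threshold: float
    ppf: float
    counts: Dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items() if k != "counts"}
        d.update(self.counts)
        return pd.DataFrame([d])


def evaluate(scores, labels, threshold: Optional[float] = None) -> EvalReport:
    """Full report; the threshold defaults to the ROC point nearest (0, 1)."""
    points, auc = roc_auc(scores, labels)
    if threshold is None:
        threshold = optimal_threshold(points)
    mcc, c = mcc_at(scores, labels, threshold)
    tp, fp, tn, fn = c["TP"], c["FP"], c["TN"], c["FN"]
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return EvalReport(
        auc=auc,
        mcc=mcc,
        sensitivity=sens,
        specificity=spec,
        false_positive_rate=1.0 - spec,
        decision_threshold=float(threshold),
        ppf=ppf(scores, threshold),
        counts=c,
    )
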