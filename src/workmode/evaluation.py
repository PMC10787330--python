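"""Evaluation protocol: masked accuracy, per-participant AUC, baselines.

Accuracy and ROC analyses exclude the *transition area* — the 15 minutes
before and after every GPS on/off switch — because the geofence dwell rule
makes GPS labels unreliable right at the boundary.  On-working predictions
are probabilities above 0.5.  The "9-to-5" reference predictor labels
09:00-17:00 as work on every day regardless of day class and is evaluated
on all minutes (no transition mask: the baseline has no model transitions
to protect).

Per-participant AUC pools all evaluated days; holidays contribute only
negatives and therefore have no AUC of their own.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .grid import EVAL_START_MIN, N_EVAL_MINUTES
from .stage1_gbt import train_stage1, predict_proba


def transition_mask(gps: np.ndarray, excl_min: int = 15) -> np.ndarray:
    """Boolean mask, False within +/- ``excl_min`` minutes of a 0/1 switch.

    A switch at minute i (first minute of the new state) masks minutes
    i-excl_min .. i+excl_min inclusive (31 minutes at the default).
    """
    gps = np.asarray(gps).astype(int)
    mask = np.ones(len(gps), dtype=bool)
    switches = np.flatnonzero(np.diff(gps) != 0) + 1
    for i in switches:
        mask[max(0, i - excl_min):i + excl_min + 1] = False
    return mask


def day_accuracy(probs: np.ndarray, gps: np.ndarray, mask: np.ndarray | None = None,
                 threshold: float = 0.5) -> float:
    """Fraction of unmasked minutes where (p > threshold) matches GPS."""
    probs = np.asarray(probs, dtype=float)
    gps = np.asarray(gps).astype(int)
    if mask is None:
        mask = np.ones(len(gps), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if probs.shape != gps.shape or gps.shape != mask.shape:
        raise ValueError("series must be aligned")
    if not mask.any():
        raise ValueError("no unmasked minutes to evaluate")
    pred = (probs > threshold).astype(int)
    return float(np.mean(pred[mask] == gps[mask]))


def participant_auc(probs: np.ndarray, labels: np.ndarray,
                    mask: np.ndarray | None = None) -> float | None:
    """Rank-based AUC over unmasked minutes (ties credited 0.5).

    Returns None when only one class survives masking — holidays alone
    carry no positives, so no AUC exists for them.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if mask is None:
        mask = np.ones(len(labels), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    p, l = probs[mask], labels[mask]
    if len(np.unique(l)) < 2:
        return None
    return float(roc_auc_score(l, p))


def reference_accuracy_9to5(gps: np.ndarray) -> float:
    """Accuracy of the fixed 09:00-17:00 predictor on the 05:45-24:00 grid."""
    gps = np.asarray(gps).astype(int)
    if len(gps) != N_EVAL_MINUTES:
        raise ValueError("expected the 1095-minute evaluation grid")
    minutes = np.arange(EVAL_START_MIN, EVAL_START_MIN + N_EVAL_MINUTES)
    pred = ((minutes >= 9 * 60) & (minutes < 17 * 60)).astype(int)
    return float(np.mean(pred == gps))


def sensitivity_specificity(probs: np.ndarray, gps: np.ndarray,
                            mask: np.ndarray | None = None,
                            threshold: float = 0.5):
    """(sensitivity, specificity) over unmasked minutes; None when undefined.

    A true positive is a minute called on-working by both the probability
    and GPS.
    """
    probs = np.asarray(probs, dtype=float)
    gps = np.asarray(gps).astype(int)
    if mask is None:
        mask = np.ones(len(gps), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    pred = (probs[mask] > threshold).astype(int)
    truth = gps[mask]
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    return sens, spec


def paired_t(a, b):
    """Two-sided paired t test; returns (t, p, df).

    Errors on length mismatch or zero-variance differences (the statistic
    is undefined there).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0, len(a) - 1
        raise ValueError("differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), len(a) - 1


def stability_curve(X, y, day_ids, X_eval, y_eval, day_counts,
                    seed: int = 0, k: int = 5, min_days: int = 5) -> dict:
    """Held-out stage-1 AUC as a function of the number of training days.

    For each count n the classifier is retrained on the first n distinct
    days (chronological order) and scored on a fixed evaluation set; the
    evaluation set never changes across counts.
    """
    day_ids = np.asarray(day_ids)
    days = sorted(set(day_ids))
    out = {}
    for n in sorted(day_counts):
        if n < min_days:
            raise ValueError(f"day count {n} below the minimum of {min_days}")
        if n > len(days):
            raise ValueError(f"day count {n} exceeds available days ({len(days)})")
        keep = np.isin(day_ids, days[:n])
        model, _ = train_stage1(X.loc[keep].reset_index(drop=True), y[keep],
                                day_ids[keep], k=min(k, n), seed=seed)
        probs = predict_proba(model, X_eval)
        out[n] = float(roc_auc_score(y_eval, probs))
    return out
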