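"""Classification and regression metrics, computed from their definitions.

Scores any (true, predicted) pairing the way the neuropathy-severity
classifiers are scored: multiclass precision/recall/F1/Jaccard with
macro, micro or weighted averaging, Hamming loss (fraction of
misclassified samples), multiclass Matthews correlation from the
confusion matrix, and the regression error family MAE/MSE/RMSE/R²/
RMSLE/SMAPE. Per-class ratios with zero denominators are reported as 0
with a logged warning so every report stays total; SMAPE uses the
symmetric 0–200% formulation and is reported in percent.
"""

from __future__ import annotations

import logging
import math

import numpy as np

__all__ = [
    "confusion_matrix",
    "classification_report",
    "regression_report",
]

logger = logging.getLogger("pedopress")

AVERAGING_MODES = ("macro", "micro", "weighted")


def _validate_pairs(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    if y_true.size == 0:
        raise ValueError("empty label arrays")
    return y_true, y_pred


def confusion_matrix(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    """(k×k count matrix, class array); rows = true class, cols = predicted."""
    y_true, y_pred = _validate_pairs(y_true, y_pred)
    classes = np.unique(y_true)
    unseen = np.setdiff1d(np.unique(y_pred), classes)
    if unseen.size:
        raise ValueError(f"predicted label(s) {unseen.tolist()} not in the known class set")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((classes.size, classes.size), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm, classes


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; reporting 0", what)
        return 0.0
    return num / den


def _aggregate(per_class: np.ndarray, weights: np.ndarray, averaging: str) -> float:
    if averaging == "macro":
        return float(per_class.mean())
    if averaging == "weighted":
        return float((per_class * weights).sum() / weights.sum())
    raise AssertionError(averaging)


def classification_report(y_true, y_pred, averaging: str = "macro") -> dict:
    """Precision, recall, F1, Hamming loss, Jaccard score and MCC.

    Per-class scores are aggregated by the chosen averaging mode
    (macro by default; micro pools all decisions first). The averaging
    mode is echoed in the returned table.
    """
    if averaging not in AVERAGING_MODES:
        raise ValueError(f"unknown averaging {averaging!r}; expected one of {AVERAGING_MODES}")
    y_true, y_pred = _validate_pairs(y_true, y_pred)
    cm, classes = confusion_matrix(y_true, y_pred)
    n = y_true.size
    tp = np.diag(cm).astype(np.float64)
    support = cm.sum(axis=1).astype(np.float64)  # true counts per class
    predicted = cm.sum(axis=0).astype(np.float64)

    if averaging == "micro":
        # pooled one-vs-rest decisions: precision = recall = accuracy for single-label data
        total_tp = tp.sum()
        precision = _safe_div(total_tp, predicted.sum(), "micro precision")
        recall = _safe_div(total_tp, support.sum(), "micro recall")
        f1 = _safe_div(2 * precision * recall, precision + recall, "micro f1")
        jaccard = _safe_div(total_tp, support.sum() + predicted.sum() - total_tp, "micro jaccard")
    else:
        prec_c = np.array(
            [_safe_div(tp[i], predicted[i], f"precision of class {classes[i]}") for i in range(len(classes))]
        )
        rec_c = np.array(
            [_safe_div(tp[i], support[i], f"recall of class {classes[i]}") for i in range(len(classes))]
        )
        f1_c = np.array(
            [
                _safe_div(2 * prec_c[i] * rec_c[i], prec_c[i] + rec_c[i], f"f1 of class {classes[i]}")
                for i in range(len(classes))
            ]
        )
        jac_c = np.array(
            [
                _safe_div(tp[i], support[i] + predicted[i] - tp[i], f"jaccard of class {classes[i]}")
                for i in range(len(classes))
            ]
        )
        precision = _aggregate(prec_c, support, averaging)
        recall = _aggregate(rec_c, support, averaging)
        f1 = _aggregate(f1_c, support, averaging)
        jaccard = _aggregate(jac_c, support, averaging)

    hamming = float((y_true != y_pred).mean())

    # multiclass Matthews correlation from the confusion matrix
    s = float(n)
    c = float(tp.sum())
    num = c * s - float(predicted @ support)
    den = math.sqrt(s * s - float(predicted @ predicted)) * math.sqrt(
        s * s - float(support @ support)
    )
    mcc = min(1.0, max(-1.0, _safe_div(num, den, "matthews correlation")))

    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "hamming_loss": hamming,
        "jaccard_score": jaccard,
        "mcc": mcc,
        "averaging": averaging,
        "n": int(n),
        "classes": classes.tolist(),
    }


def regression_report(y_true, y_pred) -> dict:
    """MAE, MSE, RMSE, R², RMSLE and SMAPE (percent) for value pairs.

    RMSLE works on log(1+x) and requires every value > −1; R² needs at
    least two samples and non-constant truth; SMAPE terms with
    |pred| + |true| = 0 are defined as 0.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    if y_true.size == 0:
        raise ValueError("empty value arrays")
    err = y_pred - y_true
    mae = float(np.abs(err).mean())
    mse = float((err**2).mean())
    rmse = math.sqrt(mse)

    if y_true.size < 2:
        r2 = math.nan
    else:
        sst = float(((y_true - y_true.mean()) ** 2).sum())
        if sst == 0:
            raise ValueError("y_true is constant; R^2 undefined (degenerate variance)")
        r2 = 1.0 - float((err**2).sum()) / sst

    if (y_true <= -1).any() or (y_pred <= -1).any():
        raise ValueError("RMSLE requires all values > -1")
    rmsle = math.sqrt(float(((np.log1p(y_pred) - np.log1p(y_true)) ** 2).mean()))

    denom = np.abs(y_pred) + np.abs(y_true)
    terms = np.zeros_like(denom)
    nz = denom > 0
    terms[nz] = 2.0 * np.abs(err[nz]) / denom[nz]
    smape = float(100.0 * terms.mean())

    return {
        "mae": mae,
        "mse": mse,
        "rmse": rmse,
        "r2": r2,
        "rmsle": rmsle,
        "smape": smape,
        "n": int(y_true.size),
    }
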