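"""Detector scoring: beat-level matching and burden-category performance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..rhythm import categorize, EXERCISE_CATEGORIES, RECOVERY_CATEGORIES

__all__ = ["match_beats", "evaluate_categories", "CategoryPerformance", "macro_f1"]


def match_beats(
    truth_samples: np.ndarray,
    called_samples: np.ndarray,
    fs: float,
    tolerance_ms: float = 75.0,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of called to true beats within tolerance.

    Returns (true positives, false negatives, false positives).
    """
    tol = tolerance_ms / 1000.0 * fs
    truth = np.sort(np.asarray(truth_samples))
    called = np.sort(np.asarray(called_samples))
    ti = ci = tp = 0
    while ti < len(truth) and ci < len(called):
        d = called[ci] - truth[ti]
        if abs(d) <= tol:
            tp += 1
            ti += 1
            ci += 1
        elif d < 0:
            ci += 1
        else:
            ti += 1
    return tp, len(truth) - tp, len(called) - tp


def macro_f1(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 3) -> float:
    """Unweighted mean of per-class F1 scores over per-sample labels."""
    f1s = []
    for c in range(n_classes):
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else np.nan)
    return float(np.nanmean(f1s))


@dataclass
class CategoryPerformance:
    """Confusion matrix over PVC-count categories, with summary metrics.

    ``sensitivity`` and ``ppv`` are per-category and reported only for
    categories that are non-empty on the relevant margin (truth for
    sensitivity, calls for PPV); empty categories are absent, not zero.
    """

    confusion: pd.DataFrame  # rows: truth, columns: called
    accuracy: float
    sensitivity: dict
    ppv: dict


def evaluate_categories(truth_counts, called_counts, phase: str = "exercise") -> CategoryPerformance:
    """Score per-recording PVC counts at the burden-category level."""
    truth_counts = np.asarray(truth_counts)
    called_counts = np.asarray(called_counts)
    if truth_counts.shape != called_counts.shape:
        raise ValueError("count lists must be paired (equal length)")
    if np.any(truth_counts < 0) or np.any(called_counts < 0):
        raise ValueError("PVC counts must be non-negative")
    cats = list(EXERCISE_CATEGORIES if phase == "exercise" else RECOVERY_CATEGORIES)
    t = pd.Categorical([categorize(int(c), phase) for c in truth_counts], categories=cats)
    p = pd.Categorical([categorize(int(c), phase) for c in called_counts], categories=cats)
    confusion = pd.crosstab(t, p, rownames=["truth"], colnames=["called"], dropna=False)
    confusion = confusion.reindex(index=cats, columns=cats, fill_value=0)
    m = confusion.to_numpy()
    accuracy = float(np.trace(m) / m.sum()) if m.sum() else float("nan")
    sensitivity = {c: float(m[i, i] / m[i].sum()) for i, c in enumerate(cats) if m[i].sum() > 0}
    ppv = {c: float(m[i, i] / m[:, i].sum()) for i, c in enumerate(cats) if m[:, i].sum() > 0}
    return CategoryPerformance(confusion, accuracy, sensitivity, ppv)
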