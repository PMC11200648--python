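"""Classification figures of merit for two-class (GDM vs NGT) models.

Specificity and sensitivity are the per-class accuracies of the control and
case class; their mean is the non-error rate (NER, balanced accuracy), the
model-selection metric throughout. AUROC is computed by the rank/pair
(Mann-Whitney) formulation — the probability that a random case outscores a
random control, ties counted one half — which equals the trapezoidal area
under the empirical ROC and handles ties exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "confusion_from_labels",
    "sp_se_ner",
    "binary_rule_eval",
    "auroc",
    "roc_curve_points",
    "average_roc",
    "prevalence",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table; positive class = GDM."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    return ConfusionCounts(
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
    )


def sp_se_ner(c: ConfusionCounts) -> tuple[float, float, float]:
    """Specificity TN/(TN+FP), sensitivity TP/(TP+FN), NER = (Sp+Se)/2."""
    if c.tn + c.fp == 0 or c.fn + c.tp == 0:
        raise ValueError("both classes must be represented")
    sp = c.tn / (c.tn + c.fp)
    se = c.tp / (c.tp + c.fn)
    return sp, se, (sp + se) / 2


def binary_rule_eval(
    pos_in_cases: int, n_cases: int, pos_in_controls: int, n_controls: int
) -> ConfusionCounts:
    """Confusion of the rule "predict GDM iff the binary variable is positive".

    Takes the published per-class positive counts of a single binary
    covariate (e.g. history of GDM in a prior pregnancy) and derives the
    counts of the deterministic single-variable classifier.
    """
    if pos_in_cases > n_cases or pos_in_controls > n_controls:
        raise ValueError("positive counts exceed class sizes")
    return ConfusionCounts(
        tn=n_controls - pos_in_controls,
        fp=pos_in_controls,
        fn=n_cases - pos_in_cases,
        tp=pos_in_cases,
    )


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC; higher score = more GDM-like; ties count 1/2."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n0 * n1))


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC (FPR, TPR) with tied scores collapsed; starts (0,0)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # collapse ties: step only at the last occurrence of each distinct score
    distinct = np.r_[np.diff(s) != 0, True]
    tps = np.cumsum(y == 1)[distinct]
    fps = np.cumsum(y == 0)[distinct]
    tpr = np.r_[0.0, tps / max(1, tps[-1])]
    fpr = np.r_[0.0, fps / max(1, fps[-1])]
    return fpr, tpr


def average_roc(
    per_repetition: list[tuple[np.ndarray, np.ndarray]],
    n_grid: int = 101,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertically average repetition ROC curves on a fixed FPR grid.

    Parameters
    ----------
    per_repetition
        List of (scores, labels) pairs, one per repetition.
    n_grid
        Number of FPR grid points in [0, 1].

    Returns ``(fpr_grid, mean_tpr, tpr_matrix)`` with endpoints pinned to
    (0, 0) and (1, 1) and one row of `tpr_matrix` per repetition.
    """
    if not per_repetition:
        raise ValueError("at least one repetition required")
    grid = np.linspace(0.0, 1.0, n_grid)
    curves = np.empty((len(per_repetition), n_grid))
    for i, (scores, labels) in enumerate(per_repetition):
        fpr, tpr = roc_curve_points(scores, labels)
        curves[i] = np.interp(grid, fpr, tpr)
    curves[:, 0] = 0.0
    curves[:, -1] = 1.0
    return grid, curves.mean(axis=0), curves


def prevalence(labels: np.ndarray) -> float:
    """Percentage of cases, rounded to one decimal (e.g. 15/82 -> 18.3)."""
    labels = np.asarray(labels).ravel()
    if labels.size == 0:
        raise ValueError("empty label vector")
    return round(100.0 * float((labels == 1).sum()) / labels.size, 1)
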