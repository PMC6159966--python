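"""Biomarker performance and survival summaries for dMMR assay comparison.

ROC/AUC by the Mann-Whitney identity, the Youden-index optimal cutoff under a
uniform "score >= cutoff is positive" convention, sensitivity/specificity at
any cutoff, and Kaplan-Meier medians with a two-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import roc_auc_score

__all__ = [
    "RocResult",
    "roc_auc",
    "youden_cutoff",
    "sens_spec_at",
    "km_median_and_logrank",
]


@dataclass
class RocResult:
    auc: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    j: float  # Youden's J = sensitivity + specificity - 1


def _validate(scores, truth):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if truth.all() or not truth.any():
        raise ValueError("ROC needs both classes present")
    return scores, truth


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve (ties counted half, per the Mann-Whitney
    U identity; equals trapezoidal integration of the empirical curve)."""
    scores, truth = _validate(scores, truth)
    return float(roc_auc_score(truth, scores))


def sens_spec_at(scores, truth, cutoff: float) -> tuple[float, float]:
    """Sensitivity and specificity of the rule `score >= cutoff → positive`."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    called = scores >= cutoff
    tp = np.sum(called & truth)
    fn = np.sum(~called & truth)
    tn = np.sum(~called & ~truth)
    fp = np.sum(called & ~truth)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return float(sens), float(spec)


def youden_cutoff(scores, truth, prefer: str = "sensitivity") -> RocResult:
    """Optimal cutoff maximizing Youden's J = sensitivity + specificity - 1.

    J is evaluated at every distinct observed score (rule: score >= cutoff is
    positive) plus an everything-negative cutoff above the maximum, so J >= 0
    always.  Ties are broken toward the lowest cutoff (favoring sensitivity);
    ``prefer='specificity'`` breaks toward the highest instead.
    """
    scores, truth = _validate(scores, truth)
    if prefer not in ("sensitivity", "specificity"):
        raise ValueError("prefer must be 'sensitivity' or 'specificity'")
    candidates = np.concatenate([np.unique(scores), [np.inf]])
    best = None
    for cut in candidates:
        sens, spec = sens_spec_at(scores, truth, cut)
        j = sens + spec - 1.0
        better = best is None or j > best[0] + 1e-12
        if prefer == "specificity":
            tie = best is not None and abs(j - best[0]) <= 1e-12
            better = better or tie  # later (higher) cutoff wins ties
        if better:
            best = (j, cut, sens, spec)
    j, cut, sens, spec = best
    return RocResult(auc=roc_auc(scores, truth), optimal_cutoff=float(cut),
                     sensitivity=sens, specificity=spec, j=j)


def km_median_and_logrank(times, events, groups):
    """Kaplan-Meier median per group and the one-degree log-rank test.

    Returns ``(medians, statistic, p)`` where ``medians`` maps group label to
    the product-limit median (first time survival drops to <= 0.5; NaN when
    never reached).  Requires at least one event per group.
    """
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events).astype(bool),
        "group": np.asarray(groups),
    })
    medians = {}
    for label, sub in df.groupby("group", sort=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {label!r}")
        if not sub["event"].any():
            raise ValueError(f"group {label!r} has no events; log-rank undefined")
        kmf = KaplanMeierFitter().fit(sub["time"], sub["event"])
        medians[label] = float(kmf.median_survival_time_)
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return medians, float(res.test_statistic), float(res.p_value)
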