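"""Empirical ROC analysis with Mann-Whitney AUC, DeLong CIs and the Youden
cut-off.

A score classifies a lesion as positive when ``score >= threshold``; the
threshold grid is the set of observed scores.  The AUC is computed through
the Mann-Whitney identity (probability that a random positive outscores a
random negative, ties counting one half), which equals the trapezoidal area
under the empirical staircase.  The optimal cut-off maximises the Youden
index J = sensitivity + specificity - 1 over observed scores, ties broken
toward the smallest score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "RocResult",
    "empirical_roc",
    "mann_whitney_auc",
    "trapezoidal_auc",
    "delong_auc_variance",
    "youden_cutoff",
]


@dataclass
class RocResult:
    """ROC curve plus scalar summaries for one score."""

    thresholds: np.ndarray  # descending observed scores
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_se: float
    auc_ci_95: tuple[float, float]
    youden_cutoff: float
    youden_j: float
    sens_at_cutoff: float
    spec_at_cutoff: float

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificities

    @property
    def tpr(self) -> np.ndarray:
        return self.sensitivities


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D arrays")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = scores[labels == uniq.max()]
    neg = scores[labels == uniq.min()]
    return pos, neg


def mann_whitney_auc(scores, labels) -> float:
    """AUC via the U-statistic: mean over (pos, neg) pairs of
    [pos > neg] + 0.5 [pos == neg]."""
    pos, neg = _split(scores, labels)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def delong_auc_variance(scores, labels) -> float:
    """DeLong variance of the empirical AUC from placement values."""
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v01 = (all_ranks[:m] - rankdata(pos)) / n  # placements of positives
    v10 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(s01 / m + s10 / n)


def trapezoidal_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under the empirical curve by the trapezoid rule (cross-check
    identity: equals the Mann-Whitney AUC on the same data)."""
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(np.asarray(tpr)[order], np.asarray(fpr)[order]))


def _bootstrap_ci(scores, labels, n_boot: int, rng: np.random.Generator):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    idx_pos = np.flatnonzero(labels == labels.max())
    idx_neg = np.flatnonzero(labels == labels.min())
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx_pos, len(idx_pos)), rng.choice(idx_neg, len(idx_neg))]
        )
        aucs[b] = mann_whitney_auc(scores[take], labels[take])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(aucs.std(ddof=1)), (float(lo), float(hi))


def empirical_roc(
    scores,
    labels,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """Full ROC analysis of one score against binary labels.

    The larger label value is the positive class.  ``ci_method`` selects the
    95% CI for the AUC: "delong" (normal approximation with the DeLong
    variance) or "bootstrap" (percentile over ``n_boot`` seeded resamples).
    """
    scores_arr = np.asarray(scores, dtype=float)
    labels_arr = np.asarray(labels)
    pos, neg = _split(scores_arr, labels_arr)
    thresholds = np.unique(scores_arr)[::-1]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    auc = mann_whitney_auc(scores_arr, labels_arr)
    if ci_method == "delong":
        se = float(np.sqrt(delong_auc_variance(scores_arr, labels_arr)))
        z = norm.ppf(0.975)
        ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        se, ci = _bootstrap_ci(scores_arr, labels_arr, n_boot, rng)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    j = sens + spec - 1.0
    best_j = j.max()
    # ties toward the smallest score: thresholds are descending
    candidates = thresholds[np.isclose(j, best_j)]
    cutoff = float(candidates.min())
    at = int(np.flatnonzero(thresholds == cutoff)[0])
    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_se=se,
        auc_ci_95=ci,
        youden_cutoff=cutoff,
        youden_j=float(j[at]),
        sens_at_cutoff=float(sens[at]),
        spec_at_cutoff=float(spec[at]),
    )


def youden_cutoff(roc: RocResult) -> dict:
    """Cut-off summary from an existing ROC result."""
    return {
        "cutoff": roc.youden_cutoff,
        "sens": roc.sens_at_cutoff,
        "spec": roc.spec_at_cutoff,
        "youden_j": roc.youden_j,
    }
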