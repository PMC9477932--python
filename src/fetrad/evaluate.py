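"""ROC analysis, AUC confidence intervals, and auxiliary group tests.

The positive class is tumor progression throughout, so sensitivity is the
progression-detection rate.  The decision cutoff is chosen where the
product of sensitivity and specificity is maximal (ties resolved toward
higher specificity — conservative against over-calling progression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "ROCResult",
    "roc_auc",
    "optimal_cutoff",
    "auc_ci",
    "delong_variance",
    "mann_whitney",
    "fisher_exact",
    "sens_spec_at_cutoff",
]


@dataclass
class ROCResult:
    """AUC, 95% CI, product-optimal cutoff, and the full ROC curve."""

    auc: float
    ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    fpr: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    tpr: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    thresholds: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    ci_method: str = "delong"
    degenerate_cutoff: bool = False

    def summary(self) -> dict:
        return {"auc": self.auc, "ci_low": self.ci[0], "ci_high": self.ci[1],
                "cutoff": self.cutoff,
                "sensitivity_pct": 100.0 * self.sensitivity,
                "specificity_pct": 100.0 * self.specificity,
                "ci_method": self.ci_method}


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1D arrays")
    classes = np.unique(labels)
    if not np.isin(classes, [0, 1]).all() or classes.size < 2:
        raise ValueError("labels must contain both classes 0 and 1")
    return scores, labels.astype(int)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank / Mann-Whitney identity; ties count one half."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_auc(scores, labels, ci_level: float = 0.95,
            ci_method: str | None = "delong", seed: int = 0) -> ROCResult:
    """Full ROC analysis of per-subject scores against binary labels.

    ``ci_method=None`` skips the confidence interval (useful inside
    simulation loops); the stored interval is then the trivial [0, 1].
    """
    scores, labels = _check_scores_labels(scores, labels)
    auc = _rank_auc(scores, labels)
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    cutoff, sens, spec, degenerate = optimal_cutoff(fpr, tpr, thresholds)
    if ci_method is None:
        ci: tuple[float, float] = (0.0, 1.0)
        ci_method = "none"
    else:
        ci = auc_ci(scores, labels, level=ci_level, method=ci_method, seed=seed)
    return ROCResult(auc=auc, ci=ci, cutoff=cutoff, sensitivity=sens,
                     specificity=spec, fpr=fpr, tpr=tpr, thresholds=thresholds,
                     ci_method=ci_method, degenerate_cutoff=degenerate)


def optimal_cutoff(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray,
                   ) -> tuple[float, float, float, bool]:
    """Cutoff maximizing sensitivity x specificity on the ROC curve.

    Among ties the point with the higher specificity wins.  Returns
    ``(cutoff, sensitivity, specificity, degenerate)`` where *degenerate*
    flags a maximum attained only at a corner of the curve (all scores
    equal, or a useless classifier).
    """
    sens = np.asarray(tpr, dtype=float)
    spec = 1.0 - np.asarray(fpr, dtype=float)
    product = sens * spec
    best = product.max()
    ties = np.flatnonzero(product >= best - 1e-12)
    pick = ties[np.argmax(spec[ties])]
    cutoff = float(thresholds[pick])
    if np.isinf(cutoff):  # sklearn's synthetic first threshold
        cutoff = float(np.nextafter(thresholds[1], np.inf)) if thresholds.size > 1 \
            else 1.0
    degenerate = bool(best <= 1e-12 or (sens[pick] in (0.0,) or spec[pick] in (0.0,)))
    return cutoff, float(sens[pick]), float(spec[pick]), degenerate


def sens_spec_at_cutoff(scores, labels, cutoff: float) -> tuple[float, float]:
    """Sensitivity/specificity of the rule 'positive when score >= cutoff'."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores >= cutoff
    sens = float(pred[labels == 1].mean())
    spec = float((~pred[labels == 0]).mean())
    return sens, spec


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong's nonparametric AUC estimate and its variance.

    Uses the structural-component form: V10 over positives, V01 over
    negatives (midrank handling of ties), variance = var(V10)/m + var(V01)/n.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size

    def placement(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # fraction of b that each element of a beats (ties count one half)
        return np.array([(np.sum(x > b) + 0.5 * np.sum(x == b)) / b.size
                         for x in a])

    v10 = placement(pos, neg)
    v01 = 1.0 - placement(neg, pos)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def _bootstrap_ci(scores, labels, level, n_boot, seed):
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos_idx, pos_idx.size, replace=True),
                              rng.choice(neg_idx, neg_idx.size, replace=True)])
        aucs[b] = _rank_auc(scores[idx], labels[idx])
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1.0 - alpha))


def auc_ci(scores, labels, level: float = 0.95, method: str = "delong",
           n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Confidence interval for the AUC.

    ``method="delong"`` (default) uses the DeLong variance with a normal
    interval, clipped to [0, 1]; ``"bootstrap"`` uses a seeded stratified
    bootstrap percentile interval.  A degenerate AUC of exactly 0 or 1 has
    zero DeLong variance, so those cases fall back to the bootstrap with a
    warning.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if int(labels.sum()) < 2 or int((1 - labels).sum()) < 2:
        raise ValueError("both classes need at least 2 members for a CI")
    if method == "bootstrap":
        return _bootstrap_ci(scores, labels, level, n_boot, seed)
    if method != "delong":
        raise ValueError("method must be 'delong' or 'bootstrap'")
    auc, var = delong_variance(scores, labels)
    if auc in (0.0, 1.0) or var == 0.0:
        warnings.warn("degenerate AUC; falling back to bootstrap CI",
                      stacklevel=2)
        return _bootstrap_ci(scores, labels, level, n_boot, seed)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U with exact enumeration for small tie-free samples.

    Exact when both groups have <= 20 observations and no ties are present;
    otherwise the tie-corrected normal approximation (with continuity
    correction).  Returns ``(U, two-sided p)`` with U counted from the
    first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table.

    Sums hypergeometric probabilities not exceeding the observed table's.
    A zero margin makes the table uninformative; p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("need a 2x2 table of non-negative integers")
        t = np.round(t).astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
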