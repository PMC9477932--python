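"""Three-stage feature-selection cascade on the training split.

Stage 1 removes (near) zero-variance features, stage 2 greedily removes one
member of every highly correlated pair (|Pearson r| >= 0.9 by default), and
stage 3 runs stepwise forward selection under stratified cross-validated
AUC with logistic regression, stopping when the best candidate no longer
adds more than 0.005 to the mean CV AUC (strict comparison).

All stages accept only the training table; validation and test labels are
never read here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureTable",
    "SelectionResult",
    "split_cohort",
    "drop_near_zero_variance",
    "drop_correlated",
    "forward_select_cv",
    "run_selection_cascade",
]

LABEL_COL = "label"


@dataclass
class FeatureTable:
    """Subjects x named features with binary labels (TP = 1, TRC = 0).

    Wraps a DataFrame whose index holds subject ids and whose first column
    is ``label``; every other column is a feature.
    """

    frame: pd.DataFrame
    split: str | None = None  # train | validation | test

    def __post_init__(self) -> None:
        if LABEL_COL not in self.frame.columns:
            raise ValueError("feature table requires a 'label' column")
        labels = self.frame[LABEL_COL]
        if not labels.isin([0, 1]).all():
            raise ValueError("labels must be 0 (TRC) or 1 (TP)")
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate subject ids")
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @classmethod
    def from_csv(cls, path, split: str | None = None) -> "FeatureTable":
        return cls(pd.read_csv(path, index_col=0), split=split)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)

    @property
    def labels(self) -> np.ndarray:
        return self.frame[LABEL_COL].to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != LABEL_COL]

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_names]

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def subset_features(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(self.frame[[LABEL_COL, *names]], split=self.split)

    def subset_rows(self, index) -> "FeatureTable":
        return FeatureTable(self.frame.loc[index], split=self.split)


@dataclass
class SelectionResult:
    """Outcome of one stage (or the whole cascade): retained features plus a
    replayable elimination/addition log."""

    retained: list[str]
    eliminated: list[dict] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"retained": self.retained, "eliminated": self.eliminated,
             "trace": self.trace, "params": self.params}, indent=2))


def split_cohort(table: FeatureTable, ratio: float = 0.25, seed: int = 0,
                 ) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/validation split, holding out *ratio* per class.

    The held-out count per class is ``round(n_class * ratio)`` (half-up),
    so 93 TP + 31 TRC at ratio 1/4 gives a 23 TP + 8 TRC validation split.
    Assignment is a seeded per-class shuffle and is fully deterministic.
    """
    if not 0 < ratio < 1:
        raise ValueError("holdout ratio must lie in (0, 1)")
    y = table.labels
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        if members.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        n_val = int(np.floor(members.size * ratio + 0.5))
        n_val = min(max(n_val, 1), members.size - 1)
        rng.shuffle(members)
        val_idx.extend(members[:n_val])
    val_mask = np.zeros(table.n_subjects, dtype=bool)
    val_mask[val_idx] = True
    train = FeatureTable(table.frame.iloc[~val_mask].copy(), split="train")
    val = FeatureTable(table.frame.iloc[val_mask].copy(), split="validation")
    return train, val


def drop_near_zero_variance(table: FeatureTable, freq_ratio_cutoff: float = 19.0,
                            unique_percent_cutoff: float = 10.0) -> SelectionResult:
    """Remove constant and near-constant features.

    A feature is near-zero-variance when the ratio of the most common to the
    second most common value is >= *freq_ratio_cutoff* AND the fraction of
    distinct values is <= *unique_percent_cutoff* percent of the rows; exact
    constants are always removed.  Defaults mirror the common 95/5 + 10%
    convention.
    """
    if table.n_subjects < 2:
        raise ValueError("need at least 2 rows")
    retained, eliminated = [], []
    n = table.n_subjects
    for name in table.feature_names:
        col = table.frame[name].to_numpy()
        counts = pd.Series(col).value_counts().to_numpy()
        if counts.size == 1:
            eliminated.append({"feature": name, "stage": "near_zero_variance",
                               "reason": "constant", "statistic": 0.0})
            continue
        freq_ratio = counts[0] / counts[1]
        unique_pct = 100.0 * counts.size / n
        if freq_ratio >= freq_ratio_cutoff and unique_pct <= unique_percent_cutoff:
            eliminated.append({"feature": name, "stage": "near_zero_variance",
                               "reason": "near-zero variance",
                               "statistic": float(freq_ratio)})
        else:
            retained.append(name)
    return SelectionResult(retained=retained, eliminated=eliminated,
                           params={"freq_ratio_cutoff": freq_ratio_cutoff,
                                   "unique_percent_cutoff": unique_percent_cutoff})


def drop_correlated(table: FeatureTable, threshold: float = 0.9) -> SelectionResult:
    """Greedy removal of redundant features at |Pearson r| >= *threshold*.

    While any remaining pair reaches the threshold, take the strongest pair
    and drop the member with the larger mean absolute correlation against
    all remaining features (the more globally redundant one); ties break by
    name order (the lexicographically later name is dropped).
    """
    if table.n_subjects < 3:
        raise ValueError("need at least 3 rows for correlations")
    names = list(table.feature_names)
    eliminated = []
    if len(names) >= 2:
        corr = table.features.corr().abs().fillna(0.0)
        np.fill_diagonal(corr.values, 0.0)
        while True:
            active = corr.loc[names, names]
            max_r = active.values.max() if len(names) >= 2 else 0.0
            if max_r < threshold:
                break
            i, j = np.unravel_index(np.argmax(active.values), active.values.shape)
            a, b = sorted((active.index[i], active.columns[j]))
            mean_a = active.loc[a].mean()
            mean_b = active.loc[b].mean()
            drop = a if mean_a > mean_b else b if mean_b > mean_a else max(a, b)
            eliminated.append({"feature": drop, "stage": "correlation",
                               "reason": f"|r| = {max_r:.4f} with "
                                         f"{b if drop == a else a}",
                               "statistic": float(max_r)})
            names.remove(drop)
    return SelectionResult(retained=names, eliminated=eliminated,
                           params={"threshold": threshold})


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 25,
                   tol: float = 1e-8, ridge: float = 1e-8) -> np.ndarray:
    """Newton/IRLS fit of an (effectively) unpenalized logistic model.

    A vanishing ridge (1e-8) keeps the Hessian invertible under collinear
    or separated folds, and a coefficient cap stops the divergence that
    complete separation would otherwise cause; the fitted scores (all the
    CV scorer needs) are unaffected at this scale.
    """
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(Xd @ beta)))
        w = p * (1.0 - p)
        grad = Xd.T @ (y - p) - ridge * beta
        hess = (Xd * w[:, None]).T @ Xd + ridge * np.eye(Xd.shape[1])
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.abs(step).max() < tol or np.abs(beta).max() > 30.0:
            break
    return beta


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _cv_auc(X: np.ndarray, y: np.ndarray, folds) -> float:
    aucs = []
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("a CV fold lost one of the classes")
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        beta = _irls_logistic((X[tr] - mu) / sd, y[tr])
        scores = ((X[te] - mu) / sd) @ beta[1:] + beta[0]
        aucs.append(_rank_auc(scores, y[te]))
    return float(np.mean(aucs))


def forward_select_cv(table: FeatureTable, k_folds: int = 5,
                      delta: float = 0.005, seed: int = 0) -> SelectionResult:
    """Stepwise forward selection under stratified CV AUC.

    Starting from the empty set (baseline AUC 0.5), greedily add the
    candidate with the highest mean cross-validated AUC of an unpenalized
    logistic model; stop when the best improvement is not strictly greater
    than *delta* or candidates are exhausted.  Fold assignment is seeded and
    shared across all candidate evaluations of a run.
    """
    candidates = list(table.feature_names)
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    result = SelectionResult(retained=[], params={
        "k_folds": k_folds, "delta": delta, "seed": seed})
    if not candidates:
        return result
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    X_all = table.features.to_numpy()
    col = {name: i for i, name in enumerate(table.feature_names)}
    current: list[str] = []
    current_auc = 0.5
    while candidates:
        best_name, best_auc = None, -np.inf
        for name in candidates:
            X = X_all[:, [col[c] for c in [*current, name]]]
            auc = _cv_auc(X, y, folds)
            if auc > best_auc:
                best_name, best_auc = name, auc
        gain = best_auc - current_auc
        result.trace.append({"candidate": best_name, "cv_auc": best_auc,
                             "gain": gain, "accepted": gain > delta})
        if gain > delta:
            current.append(best_name)  # type: ignore[arg-type]
            candidates.remove(best_name)
            current_auc = best_auc
        else:
            break
    result.retained = current
    result.eliminated = [{"feature": f, "stage": "forward_cv",
                          "reason": "no CV-AUC gain", "statistic": None}
                         for f in table.feature_names if f not in current]
    return result


def run_selection_cascade(train: FeatureTable, corr_threshold: float = 0.9,
                          k_folds: int = 5, delta: float = 0.005,
                          seed: int = 0, freq_ratio_cutoff: float = 19.0,
                          unique_percent_cutoff: float = 10.0,
                          ) -> tuple[list[str], list[SelectionResult]]:
    """Run the full three-stage cascade on the training table."""
    s1 = drop_near_zero_variance(train, freq_ratio_cutoff, unique_percent_cutoff)
    s2 = drop_correlated(train.subset_features(s1.retained), corr_threshold)
    s3 = forward_select_cv(train.subset_features(s2.retained), k_folds=k_folds,
                           delta=delta, seed=seed)
    return s3.retained, [s1, s2, s3]
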