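"""Logistic-regression classifiers and the three-model study design.

Three unpenalized logistic models are fit on the training split only:
(a) the conventional PET model on TBR_mean and TBR_max, (b) the radiomics
model on the cascade-selected features, and (c) the combined model on
their union (joint refit).  Each model is applied to the held-out
validation split and to the independent test cohort, and reported in the
layout of a diagnostic-performance table (AUC, 95% CI, sensitivity %,
specificity % per model and dataset).

Features are standardized to the training mean/SD before fitting for
numerical stability; coefficients are reported on both scales.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .evaluate import ROCResult, roc_auc, sens_spec_at_cutoff
from .selection import FeatureTable, SelectionResult, run_selection_cascade

__all__ = [
    "LogisticModel",
    "StudyReport",
    "fit_logistic",
    "predict_prob",
    "run_study",
    "CONVENTIONAL_FEATURES",
]

#: The conventional static PET parameters.
CONVENTIONAL_FEATURES = ("tbr_mean", "tbr_max")

#: |standardized coefficient| beyond which a fit is treated as separated.
_SEPARATION_COEF = 15.0


@dataclass
class LogisticModel:
    """A fitted logistic model P(TP | x) = 1 / (1 + exp(-(b0 + b'x)))."""

    feature_names: list[str]
    intercept: float
    coef: np.ndarray  # on the standardized scale
    means: np.ndarray
    sds: np.ndarray
    converged: bool = True
    separation: bool = False
    ridge_fallback: bool = False
    n_iterations: int | None = None

    @property
    def raw_coef(self) -> np.ndarray:
        """Coefficients on the original feature scale."""
        return self.coef / self.sds

    @property
    def raw_intercept(self) -> float:
        return float(self.intercept - np.sum(self.coef * self.means / self.sds))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "feature_names": self.feature_names,
            "intercept": self.intercept,
            "coef_standardized": self.coef.tolist(),
            "coef_raw": self.raw_coef.tolist(),
            "intercept_raw": self.raw_intercept,
            "means": self.means.tolist(), "sds": self.sds.tolist(),
            "converged": self.converged, "separation": self.separation,
            "ridge_fallback": self.ridge_fallback}, indent=2))


def _design(table: FeatureTable, names: list[str]) -> pd.DataFrame:
    missing = [n for n in names if n not in table.frame.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    X = table.frame[names]
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("non-finite feature values")
    return X


def fit_logistic(train: FeatureTable, feature_names) -> LogisticModel:
    """Maximum-likelihood logistic fit on standardized training features.

    Unpenalized by default; complete separation is detected and flagged,
    and only then a ridge-penalized fallback provides usable (flagged)
    coefficients.
    """
    names = list(feature_names)
    y = train.labels
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 subjects per class")
    X = _design(train, names).to_numpy()
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    Z = (X - means) / sds

    separated = False
    converged = True
    ridge = False
    n_iter = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(Z, has_constant="add")).fit(
                disp=0, maxiter=200)
            params = np.asarray(res.params)
            converged = bool(res.mle_retvals.get("converged", True))
            n_iter = int(res.mle_retvals.get("iterations", 0))
            probs = res.predict()
            if (np.abs(params[1:]) > _SEPARATION_COEF).any() or \
                    np.logical_or(probs < 1e-10, probs > 1 - 1e-10).all() or \
                    not converged:
                separated = not converged or \
                    (np.abs(params[1:]) > _SEPARATION_COEF).any()
        except Exception:
            separated = True
            params = None
    if separated or params is None:
        from sklearn.linear_model import LogisticRegression

        ridge = True
        lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000).fit(Z, y)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        converged = True
    return LogisticModel(feature_names=names, intercept=float(params[0]),
                         coef=np.asarray(params[1:], dtype=float),
                         means=means, sds=sds, converged=converged,
                         separation=separated, ridge_fallback=ridge,
                         n_iterations=n_iter)


def predict_prob(model: LogisticModel, table: FeatureTable) -> np.ndarray:
    """Per-row probability of tumor progression, standardized with the
    *training* parameters only; missing feature columns are an error."""
    X = _design(table, model.feature_names).to_numpy()
    Z = (X - model.means) / model.sds
    eta = model.intercept + Z @ model.coef
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ModelEvaluation:
    model: LogisticModel
    validation: ROCResult
    test: ROCResult | None = None
    #: test-set sensitivity/specificity at the validation-derived cutoff
    test_at_validation_cutoff: tuple[float, float] | None = None


@dataclass
class StudyReport:
    """Fitted models and their validation/test ROC results."""

    models: dict[str, ModelEvaluation]
    selection_log: list[SelectionResult]
    selected_features: list[str]
    config: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Diagnostic-performance table: one row per model and dataset."""
        rows = []
        labels = {"conventional": "FET PET parameters",
                  "radiomics": "Radiomics features",
                  "combined": "FET PET parameters + radiomics features"}
        for ds in ("validation", "test"):
            for key, ev in self.models.items():
                roc = ev.validation if ds == "validation" else ev.test
                if roc is None:
                    continue
                if ds == "test" and ev.test_at_validation_cutoff is not None:
                    sens, spec = ev.test_at_validation_cutoff
                else:
                    sens, spec = roc.sensitivity, roc.specificity
                rows.append({
                    "dataset": ds, "model": labels.get(key, key),
                    "AUC": round(roc.auc, 2),
                    "95% CI": f"{roc.ci[0]:.2f}-{roc.ci[1]:.2f}",
                    "Sensitivity (%)": round(100 * sens),
                    "Specificity (%)": round(100 * spec)})
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {"selected_features": self.selected_features,
                   "config": self.config, "models": {}}
        for key, ev in self.models.items():
            entry = {"features": ev.model.feature_names,
                     "coef_raw": ev.model.raw_coef.tolist(),
                     "intercept_raw": ev.model.raw_intercept,
                     "separation": ev.model.separation,
                     "validation": ev.validation.summary()}
            if ev.test is not None:
                entry["test"] = ev.test.summary()
                if ev.test_at_validation_cutoff is not None:
                    s, p = ev.test_at_validation_cutoff
                    entry["test_at_validation_cutoff"] = {
                        "sensitivity_pct": 100 * s, "specificity_pct": 100 * p}
            payload["models"][key] = entry
        Path(path).write_text(json.dumps(payload, indent=2))


def _check_disjoint(*tables: FeatureTable | None) -> None:
    seen: set = set()
    for t in tables:
        if t is None:
            continue
        ids = set(t.frame.index)
        overlap = seen & ids
        if overlap:
            raise ValueError(f"subject leakage across splits: {sorted(overlap)[:5]}")
        seen |= ids


def run_study(train: FeatureTable, validation: FeatureTable,
              test: FeatureTable | None = None,
              conventional: tuple[str, ...] = CONVENTIONAL_FEATURES,
              corr_threshold: float = 0.9, k_folds: int = 5,
              delta: float = 0.005, seed: int = 0,
              ci_method: str = "delong") -> StudyReport:
    """Build and evaluate the conventional, radiomics, and combined models.

    The selection cascade sees only the training rows and only the
    radiomics pool (the conventional TBR parameters are reserved for the
    conventional model).  Test-set sensitivity/specificity are reported at
    the validation-derived cutoff (the clinically available one); the
    test-derived optimum is kept in the per-model ROC result.
    """
    _check_disjoint(train, validation, test)
    radiomics_pool = [c for c in train.feature_names if c not in conventional]
    selected, log = run_selection_cascade(
        train.subset_features(radiomics_pool), corr_threshold=corr_threshold,
        k_folds=k_folds, delta=delta, seed=seed)

    feature_sets = {"conventional": list(conventional),
                    "radiomics": selected if selected else list(conventional),
                    "combined": list(conventional) + selected}
    if not selected:
        warnings.warn("cascade selected no radiomics features; radiomics "
                      "model falls back to the conventional set", stacklevel=2)

    models: dict[str, ModelEvaluation] = {}
    for key, names in feature_sets.items():
        m = fit_logistic(train, names)
        val_roc = roc_auc(predict_prob(m, validation), validation.labels,
                          ci_method=ci_method, seed=seed)
        ev = ModelEvaluation(model=m, validation=val_roc)
        if test is not None:
            scores = predict_prob(m, test)
            ev.test = roc_auc(scores, test.labels, ci_method=ci_method,
                              seed=seed)
            ev.test_at_validation_cutoff = sens_spec_at_cutoff(
                scores, test.labels, val_roc.cutoff)
        models[key] = ev
    return StudyReport(models=models, selection_log=log,
                       selected_features=selected,
                       config={"conventional": list(conventional),
                               "corr_threshold": corr_threshold,
                               "k_folds": k_folds, "delta": delta,
                               "seed": seed, "ci_method": ci_method})
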