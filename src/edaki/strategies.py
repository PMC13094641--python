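"""Training-set construction under four missing-outcome strategies.

Only about a third of ED visits have a follow-up creatinine within 72 h, so
the AKI outcome is missing for the rest. Four strategies turn a labeled
cohort into a training set:

1. ``complete_case`` — keep only visits with an observed outcome.
2. ``assume_negative`` — keep every visit; missing outcomes become negative.
3. ``multiple_imputation`` — fit a preliminary risk model on complete
   cases, then give each incomplete visit ``m`` replicate rows with
   independent Bernoulli draws at its predicted probability, each at weight
   ``1/m`` so every encounter carries equal total representation.
4. ``ipw`` — keep only complete cases, weighted by the inverse of their
   estimated probability of being observed (a missingness propensity model
   fit on the full cohort), so the observed subset stands in for the whole
   population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .features import build_features

__all__ = [
    "StrategyConfig",
    "TrainingSet",
    "PropensityModel",
    "STRATEGIES",
    "build_complete_case",
    "build_assume_negative",
    "fit_preliminary_model",
    "impute_outcomes",
    "build_multiple_imputation",
    "fit_missingness_propensity",
    "build_ipw",
    "build_training_set",
]

STRATEGIES = ("complete_case", "assume_negative", "multiple_imputation", "ipw")

# compact settings for the auxiliary (preliminary / propensity) learners
AUX_PARAMS: Dict[str, object] = dict(
    n_estimators=150, max_depth=3, learning_rate=0.1,
    subsample=0.8, reg_lambda=1.0,
)


@dataclass
class StrategyConfig:
    strategy: str = "complete_case"
    m_imputations: int = 20
    propensity_clip: float = 0.01
    seed: int = 0
    aux_params: Dict[str, object] = field(default_factory=lambda: dict(AUX_PARAMS))

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be >= 1")
        if not 0.0 < self.propensity_clip < 1.0:
            raise ValueError("propensity_clip must lie in (0, 1)")


@dataclass
class TrainingSet:
    """Feature matrix, outcomes, per-row weights and provenance."""

    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray
    visit_ids: np.ndarray
    strategy: str
    target: str
    replicate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.X)
        if not (len(self.y) == len(self.weights) == len(self.visit_ids) == n):
            raise ValueError("feature matrix, outcomes, weights and ids must align")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def make_classifier(seed: int, **params) -> XGBClassifier:
    """Gradient-boosted tree classifier configured for this pipeline.

    Categorical features are consumed as pandas ``category`` columns;
    missing continuous values pass through to the learner's sparsity-aware
    split finding.
    """
    defaults = dict(
        tree_method="hist", enable_categorical=True, n_jobs=1,
        eval_metric="logloss", random_state=int(seed) % (2**31),
    )
    defaults.update(params)
    return XGBClassifier(**defaults)


def _extract(cohort: pd.DataFrame, labels: pd.DataFrame, target: str):
    X = build_features(cohort, labels)
    lab = labels.set_index("visit_id").loc[cohort["visit_id"]]
    observed = lab["outcome_observed"].to_numpy(dtype=bool)
    y = lab[target].to_numpy(dtype=float)  # NaN where unobserved
    ids = cohort["visit_id"].to_numpy()
    return X, y, observed, ids


def build_complete_case(cohort: pd.DataFrame, labels: pd.DataFrame,
                        target: str = "y_any") -> TrainingSet:
    """Outcome-observed visits only, all at weight 1."""
    X, y, observed, ids = _extract(cohort, labels, target)
    if not observed.any():
        raise ValueError("no complete cases: every outcome is missing")
    return TrainingSet(
        X[observed], y[observed].astype(bool), np.ones(observed.sum()),
        ids[observed], "complete_case", target,
    )


def build_assume_negative(cohort: pd.DataFrame, labels: pd.DataFrame,
                          target: str = "y_any") -> TrainingSet:
    """Every visit, with missing outcomes coded negative, all at weight 1."""
    X, y, observed, ids = _extract(cohort, labels, target)
    y_filled = np.where(observed, y, 0.0).astype(bool)
    return TrainingSet(X, y_filled, np.ones(len(X)), ids, "assume_negative", target)


def fit_preliminary_model(training: TrainingSet, seed: int = 0,
                          params: Optional[Dict[str, object]] = None):
    """Preliminary risk model on complete cases, used only for imputation."""
    y = np.asarray(training.y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate fit: training outcomes contain a single class")
    clf = make_classifier(seed, **(params or AUX_PARAMS))
    clf.fit(training.X, y, sample_weight=training.weights)
    return clf


def impute_outcomes(predictor, X_incomplete: pd.DataFrame,
                    incomplete_ids: np.ndarray, m_imputations: int,
                    seed: int, observed_set: TrainingSet) -> TrainingSet:
    """Replicate each incomplete visit ``m`` times with Bernoulli outcomes.

    Each replicate row carries weight ``1/m`` so every encounter — observed
    or imputed — contributes total weight 1 to the pooled fit.
    """
    if m_imputations < 1:
        raise ValueError("m_imputations must be >= 1")
    rng = np.random.default_rng(seed)
    m = int(m_imputations)
    n_inc = len(X_incomplete)
    if n_inc:
        p = np.asarray(predictor.predict_proba(X_incomplete)[:, 1], dtype=float)
        draws = rng.random((n_inc, m)) < p[:, None]  # independent per replicate
        X_rep = X_incomplete.iloc[np.repeat(np.arange(n_inc), m)]
        y_rep = draws.reshape(-1)
        ids_rep = np.repeat(incomplete_ids, m)
        rep_idx = np.tile(np.arange(m), n_inc)
        X_all = pd.concat([observed_set.X, X_rep], axis=0)
        y_all = np.concatenate([observed_set.y.astype(bool), y_rep])
        w_all = np.concatenate([observed_set.weights, np.full(n_inc * m, 1.0 / m)])
        ids_all = np.concatenate([observed_set.visit_ids, ids_rep])
        rep_all = np.concatenate([np.full(len(observed_set), -1), rep_idx])
    else:
        X_all, y_all = observed_set.X, observed_set.y.astype(bool)
        w_all, ids_all = observed_set.weights, observed_set.visit_ids
        rep_all = np.full(len(observed_set), -1)
    return TrainingSet(X_all, y_all, w_all, ids_all, "multiple_imputation",
                       observed_set.target, replicate=rep_all)


def build_multiple_imputation(cohort: pd.DataFrame, labels: pd.DataFrame,
                              target: str = "y_any",
                              config: Optional[StrategyConfig] = None) -> TrainingSet:
    config = config or StrategyConfig(strategy="multiple_imputation")
    cc = build_complete_case(cohort, labels, target)
    prelim = fit_preliminary_model(cc, seed=config.seed, params=config.aux_params)
    X, _, observed, ids = _extract(cohort, labels, target)
    return impute_outcomes(
        prelim, X[~observed], ids[~observed], config.m_imputations,
        seed=config.seed + 1, observed_set=cc,
    )


@dataclass
class PropensityModel:
    """Estimator of P(outcome observed | covariates), with clipping.

    ``oof`` holds out-of-fold predictions (indexed by visit_id) for the
    cohort the model was fit on: in-sample predictions are optimistically
    pulled toward the training labels, which systematically deflates
    inverse-probability weights, so weights for the fitting cohort should
    come from ``oof`` rather than from ``predict``.
    """

    model: XGBClassifier
    clip: float = 0.01
    feature_columns: tuple = ()
    oof: Optional[pd.Series] = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_schema(X)
        p = np.asarray(self.model.predict_proba(X)[:, 1], dtype=float)
        return np.clip(p, self.clip, 1.0 - 1e-12)

    def predict_logodds(self, X: pd.DataFrame) -> np.ndarray:
        """Raw margin f(X): the observation log-odds before any offset."""
        self._check_schema(X)
        return np.asarray(
            self.model.predict(X, output_margin=True), dtype=float
        )

    def _check_schema(self, X: pd.DataFrame) -> None:
        if self.feature_columns and tuple(X.columns) != tuple(self.feature_columns):
            raise ValueError("feature schema does not match the propensity model")


def fit_missingness_propensity(cohort: pd.DataFrame, labels: pd.DataFrame,
                               config: Optional[StrategyConfig] = None,
                               n_oof_folds: int = 5) -> PropensityModel:
    """Fit P(outcome observed | covariates) on the full cohort.

    Also computes cross-fitted (out-of-fold) predictions for the fitting
    cohort itself, stored on the returned model for weight construction.
    """
    config = config or StrategyConfig(strategy="ipw")
    X, _, observed, ids = _extract(cohort, labels, "y_any")
    if observed.all() or not observed.any():
        raise ValueError("degenerate fit: cohort is all-observed or all-missing")
    clf = make_classifier(config.seed + 2, **config.aux_params)
    clf.fit(X, observed.astype(int))

    oof = np.empty(len(X))
    folds = np.arange(len(X)) % n_oof_folds
    for f in range(n_oof_folds):
        tr = folds != f
        cv_clf = make_classifier(config.seed + 2, **config.aux_params)
        cv_clf.fit(X[tr], observed[tr].astype(int))
        oof[~tr] = cv_clf.predict_proba(X[~tr])[:, 1]
    oof = np.clip(oof, config.propensity_clip, 1.0 - 1e-12)
    return PropensityModel(clf, clip=config.propensity_clip,
                           feature_columns=tuple(X.columns),
                           oof=pd.Series(oof, index=ids))


def build_ipw(cohort: pd.DataFrame, labels: pd.DataFrame,
              propensity: PropensityModel, target: str = "y_any") -> TrainingSet:
    """Complete cases weighted by inverse observation probability.

    Uses the propensity model's out-of-fold predictions where they cover
    the cohort (i.e. when weighting the cohort it was fit on), falling back
    to plain predictions otherwise.
    """
    X, y, observed, ids = _extract(cohort, labels, target)
    if not observed.any():
        raise ValueError("no complete cases: every outcome is missing")
    obs_ids = ids[observed]
    if propensity.oof is not None and propensity.oof.index.isin(obs_ids).sum() == len(obs_ids):
        p = np.clip(propensity.oof.loc[obs_ids].to_numpy(), propensity.clip,
                    1.0 - 1e-12)
    else:
        p = propensity.predict(X[observed])
    return TrainingSet(
        X[observed], y[observed].astype(bool), 1.0 / p, ids[observed],
        "ipw", target,
    )


def build_training_set(cohort: pd.DataFrame, labels: pd.DataFrame,
                       target: str = "y_any",
                       config: Optional[StrategyConfig] = None) -> TrainingSet:
    """Dispatch to the configured strategy."""
    config = config or StrategyConfig()
    s = config.strategy
    if s == "complete_case":
        return build_complete_case(cohort, labels, target)
    if s == "assume_negative":
        return build_assume_negative(cohort, labels, target)
    if s == "multiple_imputation":
        return build_multiple_imputation(cohort, labels, target, config)
    if s == "ipw":
        propensity = fit_missingness_propensity(cohort, labels, config)
        return build_ipw(cohort, labels, propensity, target)
    raise ValueError(f"unknown strategy {s!r}")
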