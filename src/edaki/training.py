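"""Risk-model fitting: grid search, k-fold cross-validation, temporal split.

Two binary targets are modeled — any new-or-progressive AKI (``y_any``) and
progression reaching stage >= 2 (``y_severe``) — with a gradient-boosted
tree learner on any :class:`~edaki.strategies.TrainingSet`. Hyperparameters
are chosen by weighted log-loss on an inner 3-fold split; cross-validation
folds are grouped by patient so repeat visits never straddle train/test,
and test folds contain only outcome-observed visits.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss

from .strategies import (
    StrategyConfig,
    TrainingSet,
    build_training_set,
    make_classifier,
)

__all__ = [
    "RiskModel",
    "SplitConfig",
    "default_grid",
    "fit_risk_model",
    "cross_validate",
    "temporal_split",
]


def default_grid() -> List[Dict[str, object]]:
    """Modest grid over depth, boosting rounds and learning rate."""
    combos = itertools.product([3, 5], [100, 300], [0.05, 0.1])
    return [
        dict(max_depth=d, n_estimators=n, learning_rate=lr,
             subsample=0.8, reg_lambda=1.0)
        for d, n, lr in combos
    ]


@dataclass
class SplitConfig:
    k_folds: int = 10
    temporal_cutoff: pd.Timestamp = pd.Timestamp("2023-01-01")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class RiskModel:
    """Fitted probability predictor with provenance."""

    model: object
    target: str
    strategy: str
    params: Dict[str, object]
    seed: int
    feature_columns: tuple = ()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.feature_columns and tuple(X.columns) != tuple(self.feature_columns):
            raise ValueError("feature schema does not match the risk model")
        p = np.asarray(self.model.predict_proba(X)[:, 1], dtype=float)
        return np.clip(p, 1e-12, 1.0 - 1e-12)


def _normalize_weights(w: np.ndarray) -> np.ndarray:
    """Scale weights to mean 1: tree regularization terms are absolute, so
    predictions stay invariant to the overall weight scale."""
    w = np.asarray(w, dtype=float)
    return w / w.mean()


def _weighted_inner_cv_loss(training: TrainingSet, params: Dict[str, object],
                            seed: int, n_inner: int = 3) -> float:
    """Weighted log-loss over a deterministic inner k-fold split."""
    n = len(training)
    folds = np.arange(n) % n_inner
    y = np.asarray(training.y, dtype=int)
    w_all = _normalize_weights(training.weights)
    losses, weights = [], []
    for f in range(n_inner):
        tr, te = folds != f, folds == f
        if len(np.unique(y[tr])) < 2 or te.sum() == 0:
            continue
        clf = make_classifier(seed, **params)
        clf.fit(training.X[tr], y[tr], sample_weight=w_all[tr])
        p = clf.predict_proba(training.X[te])[:, 1]
        w = w_all[te]
        losses.append(log_loss(y[te], p, sample_weight=w, labels=[0, 1]))
        weights.append(w.sum())
    if not losses:
        raise ValueError("inner cross-validation degenerate: single-class folds")
    return float(np.average(losses, weights=weights))


def fit_risk_model(training: TrainingSet, target: Optional[str] = None,
                   grid: Optional[Sequence[Dict[str, object]]] = None,
                   seed: int = 0) -> RiskModel:
    """Fit the learner on a training set, selecting hyperparameters by grid search.

    A single-point grid skips the inner cross-validation. Missing continuous
    covariates pass through to the learner's native sparsity handling;
    categorical covariates already carry an explicit "null" level.
    """
    target = target or training.target
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    y = np.asarray(training.y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate fit: training outcomes contain a single class")

    if len(grid) == 1:
        best = grid[0]
    else:
        losses = [_weighted_inner_cv_loss(training, params, seed) for params in grid]
        best = grid[int(np.argmin(losses))]

    clf = make_classifier(seed, **best)
    clf.fit(training.X, y, sample_weight=_normalize_weights(training.weights))
    return RiskModel(clf, target, training.strategy, dict(best), seed,
                     feature_columns=tuple(training.X.columns))


def _patient_fold(patient_ids: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic, order-invariant, patient-grouped fold assignment."""
    out = np.empty(len(patient_ids), dtype=np.int64)
    cache: Dict[str, int] = {}
    for i, pid in enumerate(patient_ids):
        f = cache.get(pid)
        if f is None:
            h = hashlib.md5(f"{seed}:{pid}".encode()).digest()
            f = cache[pid] = int.from_bytes(h[:8], "little") % k
        out[i] = f
    return out


def cross_validate(cohort: pd.DataFrame, labels: pd.DataFrame,
                   strategy_config: StrategyConfig, split: SplitConfig,
                   target: str = "y_any",
                   grid: Optional[Sequence[Dict[str, object]]] = None) -> pd.DataFrame:
    """Out-of-fold predictions for every outcome-observed visit.

    Strategy construction (propensity fitting, outcome imputation) is rerun
    inside each training fold so no information leaks from a test fold.
    Returns a table (visit_id, target, prediction, fold).
    """
    if len(cohort) < split.k_folds:
        raise ValueError("cohort smaller than the number of folds")
    order = np.argsort(cohort["visit_id"].to_numpy())
    cohort = cohort.iloc[order].reset_index(drop=True)
    fold = _patient_fold(cohort["patient_id"].to_numpy(), split.k_folds, split.seed)

    lab_idx = labels.set_index("visit_id").loc[cohort["visit_id"]]
    observed = lab_idx["outcome_observed"].to_numpy(dtype=bool)

    rows = []
    for f in range(split.k_folds):
        tr_mask = fold != f
        te_mask = (fold == f) & observed
        if not te_mask.any():
            continue
        tr_cohort = cohort[tr_mask].reset_index(drop=True)
        training = build_training_set(tr_cohort, labels, target, strategy_config)
        if len(np.unique(np.asarray(training.y, dtype=int))) < 2:
            raise ValueError(f"fold {f} degenerate: single-class training outcomes")
        model = fit_risk_model(training, target, grid, seed=strategy_config.seed)
        from .features import build_features

        X_te = build_features(cohort[te_mask].reset_index(drop=True), labels)
        p = model.predict(X_te)
        rows.append(pd.DataFrame({
            "visit_id": cohort.loc[te_mask, "visit_id"].to_numpy(),
            "target": target,
            "prediction": p,
            "fold": f,
        }))
    out = pd.concat(rows, ignore_index=True).sort_values("visit_id")
    return out.reset_index(drop=True)


def temporal_split(cohort: pd.DataFrame, cutoff) -> tuple:
    """Partition by arrival time: development strictly before the cutoff."""
    cutoff = pd.Timestamp(cutoff)
    dev_mask = cohort["arrival_time"] < cutoff
    dev = cohort[dev_mask].reset_index(drop=True)
    val = cohort[~dev_mask].reset_index(drop=True)
    if len(dev) == 0 or len(val) == 0:
        warnings.warn("temporal split left one side empty", stacklevel=2)
    return dev, val
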