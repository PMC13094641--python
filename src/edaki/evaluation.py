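"""Model evaluation: discrimination, calibration, thresholds, rate comparison.

Two complementary assessments:

* standard out-of-sample metrics on visits whose outcome was observed —
  ROC AUC with DeLong confidence intervals and paired tests, the
  precision-recall curve, decile calibration with the Brier score, and a
  threshold operating table;
* an observed-versus-expected rate comparison over the *whole* cohort: mean
  predicted probabilities in the outcome-observed and outcome-missing
  strata are set against the observed outcome rate and, for the missing
  stratum, an expected rate taken as a fixed fraction (default 0.36, from
  published relative follow-up kidney-outcome frequencies after discharge
  vs hospitalization) of the observed-stratum rate.

The DeLong variance uses the structural-components estimator with
half-weight for ties; ``roc_auc_delong`` agrees exactly with brute-force
pair counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import average_precision_score, precision_recall_curve as _sk_pr

__all__ = [
    "ExpectedRateConfig",
    "roc_auc_delong",
    "delong_paired_test",
    "precision_recall_curve",
    "calibration_and_brier",
    "threshold_metrics",
    "expected_rate",
    "expected_rate_comparison",
]


@dataclass(frozen=True)
class ExpectedRateConfig:
    """Relative outcome rate assumed for visits without a follow-up sCr."""

    relative_rate_ratio: float = 0.36

    def __post_init__(self) -> None:
        if self.relative_rate_ratio <= 0:
            raise ValueError("relative_rate_ratio must be > 0")


def _check_binary(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValueError("AUC undefined: outcomes contain a single class")


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based), ties averaged."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _delong_components(y: np.ndarray, p: np.ndarray):
    """AUC and per-subject structural components (V10 positives, V01 negatives)."""
    pos = p[y == 1]
    neg = p[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def roc_auc_delong(outcomes, predictions, alpha: float = 0.05):
    """ROC AUC (Mann-Whitney, ties half-credit) with a DeLong CI.

    Returns ``(auc, (ci_low, ci_high))``; the interval is truncated to [0,1].
    """
    y = np.asarray(outcomes, dtype=int)
    p = np.asarray(predictions, dtype=float)
    _check_binary(y)
    auc, v10, v01 = _delong_components(y, p)
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) + (
        np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0
    )
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def delong_paired_test(outcomes, predictions_a, predictions_b):
    """Paired DeLong test for the AUC difference of two models on the same visits.

    Returns ``(auc_a - auc_b, z statistic, two-sided p-value)``. The variance
    of the difference accounts for the pairing through the covariance of the
    shared structural components.
    """
    y = np.asarray(outcomes, dtype=int)
    pa = np.asarray(predictions_a, dtype=float)
    pb = np.asarray(predictions_b, dtype=float)
    if len(pa) != len(y) or len(pb) != len(y):
        raise ValueError("both prediction vectors must score the same visits")
    _check_binary(y)
    auc_a, v10_a, v01_a = _delong_components(y, pa)
    auc_b, v10_b, v01_b = _delong_components(y, pb)
    m, n = len(v10_a), len(v01_a)

    def _cov(u, v):
        return np.cov(u, v, ddof=1) if len(u) > 1 else np.zeros((2, 2))

    s10 = _cov(v10_a, v10_b)
    s01 = _cov(v01_a, v01_b)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0
        pval = 1.0 if np.isclose(diff, 0.0) else 0.0
    else:
        z = diff / np.sqrt(var)
        pval = 2.0 * norm.sf(abs(z))
    return float(diff), float(z), float(pval)


def precision_recall_curve(outcomes, predictions):
    """PR curve with step-interpolated area and the prevalence baseline.

    Returns ``(table, area, prevalence)`` where table has columns
    precision/recall/threshold and the area is the step-wise integral
    (average precision), never the optimistic linear interpolation.
    """
    y = np.asarray(outcomes, dtype=int)
    p = np.asarray(predictions, dtype=float)
    if y.sum() == 0:
        raise ValueError("precision-recall undefined: no positive outcomes")
    precision, recall, thresholds = _sk_pr(y, p)
    area = float(average_precision_score(y, p))
    table = pd.DataFrame({
        "precision": precision,
        "recall": recall,
        "threshold": np.append(thresholds, np.nan),
    })
    return table, area, float(y.mean())


def calibration_and_brier(outcomes, predictions, n_bins: int = 10):
    """Equal-frequency calibration bins and the Brier score.

    Returns ``(table, brier)``; table columns are bin, mean_predicted,
    observed_rate, count (counts sum to n).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(predictions, dtype=float)
    brier = float(np.mean((p - y) ** 2))
    # rank-based equal-frequency binning; robust to heavily tied predictions
    ranks = np.argsort(np.argsort(p, kind="mergesort"), kind="mergesort")
    bins = (ranks * n_bins) // len(p)
    table = (
        pd.DataFrame({"bin": bins, "p": p, "y": y})
        .groupby("bin")
        .agg(mean_predicted=("p", "mean"), observed_rate=("y", "mean"),
             count=("y", "size"))
        .reset_index()
    )
    return table, brier


def threshold_metrics(outcomes, predictions, thresholds: Sequence[float]):
    """Operating characteristics at each threshold (flag iff p >= t).

    Undefined cells (PPV with no flags, NPV with no negatives called) are
    NaN, never zero.
    """
    y = np.asarray(outcomes, dtype=bool)
    p = np.asarray(predictions, dtype=float)
    rows = []
    npos, nneg = int(y.sum()), int((~y).sum())
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
        flag = p >= t
        tp = int((flag & y).sum())
        fp = int((flag & ~y).sum())
        fn = npos - tp
        tn = nneg - fp
        sens = tp / npos if npos else np.nan
        spec = tn / nneg if nneg else np.nan
        ppv = tp / (tp + fp) if (tp + fp) else np.nan
        npv = tn / (tn + fn) if (tn + fn) else np.nan
        f1 = (2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) else np.nan
        rows.append(dict(threshold=t, flag_rate=flag.mean(), sensitivity=sens,
                         specificity=spec, ppv=ppv, npv=npv, f1=f1,
                         tp=tp, fp=fp, fn=fn, tn=tn))
    return pd.DataFrame(rows)


def expected_rate(observed_rate: float, ratio: float = 0.36) -> float:
    """Expected outcome rate in the unmeasured stratum: observed rate x ratio."""
    return float(observed_rate) * float(ratio)


def _mean_ci(x: np.ndarray, alpha: float = 0.05) -> Tuple[float, float, float]:
    m = float(x.mean())
    if len(x) > 1:
        half = norm.ppf(1 - alpha / 2) * x.std(ddof=1) / np.sqrt(len(x))
    else:
        half = np.nan
    return m, m - half, m + half


def expected_rate_comparison(predictions, observed_flags, observed_outcomes,
                             config: ExpectedRateConfig = ExpectedRateConfig()):
    """Mean predicted probability vs observed/expected outcome rate, by stratum.

    ``predictions`` scores every visit; ``observed_flags`` marks the
    outcome-observed stratum; ``observed_outcomes`` are the outcomes of that
    stratum (aligned to its order of appearance). Returns one row per
    stratum with the mean predicted probability (normal-approximation 95%
    CI) and the observed or expected outcome rate.
    """
    p = np.asarray(predictions, dtype=float)
    obs = np.asarray(observed_flags, dtype=bool)
    y = np.asarray(observed_outcomes, dtype=float)
    if not obs.any() or obs.all():
        raise ValueError("both an observed and a missing stratum are required")
    if len(y) != int(obs.sum()):
        raise ValueError("observed_outcomes must align with the observed stratum")

    observed_rate = float(y.mean())
    rows = []
    for name, mask in (("complete", obs), ("incomplete", ~obs)):
        m, lo, hi = _mean_ci(p[mask])
        rate = observed_rate if name == "complete" else expected_rate(
            observed_rate, config.relative_rate_ratio
        )
        rows.append(dict(
            stratum=name, n=int(mask.sum()), outcome_rate=rate,
            rate_kind="observed" if name == "complete" else "expected",
            mean_predicted=m, ci_low=lo, ci_high=hi,
        ))
    return pd.DataFrame(rows)
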