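"""KDIGO creatinine-based AKI staging and outcome labeling.

Acute kidney injury (AKI) is staged from the ratio and absolute rise of
serum creatinine (sCr) over a patient-specific baseline:

* stage 1 — absolute rise >= 0.3 mg/dL or >= 1.5x baseline,
* stage 2 — 2.0-2.9x baseline,
* stage 3 — >= 3.0x baseline, initiation of renal replacement therapy
  (RRT), or sCr reaching >= 4.0 mg/dL with an acute stage-1 rise.

Baseline sCr is the median of measurements in a 180-day lookback (the sole
measurement if only one exists); with no history it is back-calculated from
the 2021 race-free CKD-EPI equation at a reference eGFR. An encounter's
outcome is *new or progressive AKI*: the peak stage within 72 h of ED
departure exceeds the stage on arrival. Visits without any follow-up sCr in
that window have an unobservable outcome and are flagged missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "StagingRules",
    "OutcomeLabel",
    "ckd_epi_egfr",
    "invert_ckd_epi",
    "compute_baseline",
    "stage_aki",
    "label_visit",
    "label_cohort",
    "apply_exclusions",
]


@dataclass(frozen=True)
class StagingRules:
    """Thresholds of the creatinine-based staging criteria.

    Defaults are the consensus KDIGO values; ``reference_egfr`` is the
    eGFR (mL/min/1.73 m^2) assumed when back-calculating a baseline for
    patients with no creatinine history.
    """

    abs_increase_stage1: float = 0.3  # mg/dL
    ratio_stage1: float = 1.5
    ratio_stage2_low: float = 2.0
    ratio_stage3: float = 3.0
    abs_level_stage3: float = 4.0  # mg/dL
    lookback_days: float = 180.0
    outcome_window_hours: float = 72.0
    exclusion_baseline: float = 4.0  # mg/dL
    reference_egfr: float = 75.0

    def __post_init__(self) -> None:
        if not (0 < self.ratio_stage1 < self.ratio_stage2_low < self.ratio_stage3):
            raise ValueError("stage ratio thresholds must be positive and increasing")
        for name in ("abs_increase_stage1", "abs_level_stage3", "lookback_days",
                     "outcome_window_hours", "exclusion_baseline", "reference_egfr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class OutcomeLabel:
    """Per-visit label: baseline, arrival stage, peak stage and outcome flags.

    ``y_any`` / ``y_severe`` are ``None`` exactly when the outcome is
    unobserved (no follow-up creatinine and no RRT within the window).
    """

    baseline_scr: float
    baseline_source: str  # historical_median | historical_single | imputed_ckd_epi
    initial_stage: int
    outcome_observed: bool
    peak_stage: Optional[int] = None
    y_any: Optional[bool] = None
    y_severe: Optional[bool] = None


# ---------------------------------------------------------------------------
# CKD-EPI (2021 race-free) forward equation and its inversion
# ---------------------------------------------------------------------------

# 2021 CKD-EPI creatinine constants: sex -> (kappa, alpha)
_CKD_EPI = {"F": (0.7, -0.241), "M": (0.9, -0.302)}
_EXP_HIGH = -1.200
_AGE_FACTOR = 0.9938
_SCALE = 142.0
_FEMALE_MULT = 1.012


def _sex_params(sex: str) -> Tuple[float, float, float]:
    s = str(sex).upper()[:1]
    if s == "F":
        kappa, alpha = _CKD_EPI["F"]
        return kappa, alpha, _FEMALE_MULT
    if s == "M":
        kappa, alpha = _CKD_EPI["M"]
        return kappa, alpha, 1.0
    raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")


def ckd_epi_egfr(scr, age, sex):
    """Estimated GFR (mL/min/1.73 m^2) from the 2021 race-free equation.

    ``scr`` in mg/dL; vectorized over ``scr`` and ``age`` for a fixed sex.
    """
    kappa, alpha, mult = _sex_params(sex)
    scr = np.asarray(scr, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be > 0")
    r = scr / kappa
    egfr = (
        _SCALE
        * np.minimum(r, 1.0) ** alpha
        * np.maximum(r, 1.0) ** _EXP_HIGH
        * _AGE_FACTOR ** np.asarray(age, dtype=float)
        * mult
    )
    return egfr if egfr.ndim else float(egfr)


def invert_ckd_epi(age, sex, reference_egfr: float = 75.0):
    """Back-calculate the sCr (mg/dL) yielding ``reference_egfr`` for age/sex.

    The forward equation is a continuous, strictly decreasing piecewise
    power law in sCr, so the inverse has a closed form: on each branch
    solve ``g = C * (scr/kappa)**e`` for scr and keep the branch whose
    solution is admissible.  The round trip satisfies
    ``ckd_epi_egfr(invert_ckd_epi(a, s, g), a, s) == g`` to <1e-12 relative.
    """
    if np.any(np.asarray(reference_egfr) <= 0):
        raise ValueError("reference_egfr must be > 0")
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 18):
        raise ValueError("age must be >= 18 years")
    kappa, alpha, mult = _sex_params(sex)
    c = _SCALE * _AGE_FACTOR ** age_arr * mult
    ratio = np.asarray(reference_egfr, dtype=float) / c
    # ratio >= 1 -> sCr <= kappa branch (exponent alpha), else the -1.2 branch
    scr = np.where(
        ratio >= 1.0,
        kappa * np.power(np.maximum(ratio, 1e-300), 1.0 / alpha),
        kappa * np.power(np.maximum(ratio, 1e-300), 1.0 / _EXP_HIGH),
    )
    if np.any((scr <= 0.1) | (scr >= 20.0)):
        raise ArithmeticError(
            "inverted sCr outside the admissible range (0.1, 20) mg/dL"
        )
    return scr if scr.ndim else float(scr)


# ---------------------------------------------------------------------------
# Baseline creatinine
# ---------------------------------------------------------------------------

def compute_baseline(
    prior_scr_series: Sequence[Tuple[object, float]] | Sequence[float],
    age: float,
    sex: str,
    rules: StagingRules = StagingRules(),
    arrival_time=None,
) -> Tuple[float, str]:
    """Baseline sCr and its provenance for one visit.

    ``prior_scr_series`` is a sequence of ``(timestamp, value)`` pairs (or
    bare values when no timestamps are available). With ``arrival_time``
    given, values timestamped outside the closed 180-day lookback are
    ignored. Two or more values give their median; exactly one gives that
    value; none triggers CKD-EPI back-calculation from age and sex.
    """
    values = []
    for item in prior_scr_series:
        if isinstance(item, (tuple, list)) and len(item) == 2:
            ts, val = item
        else:
            ts, val = None, item
        val = float(val)
        if val <= 0:
            raise ValueError("serum creatinine must be > 0")
        if arrival_time is not None and ts is not None:
            ts = pd.Timestamp(ts)
            ref = pd.Timestamp(arrival_time)
            if ts > ref or (ref - ts) > pd.Timedelta(days=rules.lookback_days):
                continue
        values.append(val)

    if len(values) >= 2:
        return float(np.median(values)), "historical_median"
    if len(values) == 1:
        return values[0], "historical_single"
    if age is None or sex is None or (isinstance(age, float) and math.isnan(age)):
        raise ValueError("age and sex are required to impute a baseline")
    return float(invert_ckd_epi(age, sex, rules.reference_egfr)), "imputed_ckd_epi"


# ---------------------------------------------------------------------------
# Staging
# ---------------------------------------------------------------------------

def _stage_array(baseline, current, rrt, rules: StagingRules) -> np.ndarray:
    baseline = np.asarray(baseline, dtype=float)
    current = np.asarray(current, dtype=float)
    rrt = np.asarray(rrt, dtype=bool)
    if np.any(baseline <= 0) or np.any(current <= 0):
        raise ValueError("baseline and current sCr must be > 0")
    ratio = current / baseline
    delta = current - baseline
    stage1_criterion = (ratio >= rules.ratio_stage1) | (delta >= rules.abs_increase_stage1)
    stage = np.zeros(np.broadcast(baseline, current, rrt).shape, dtype=np.int64)
    stage[stage1_criterion] = 1
    stage[(ratio >= rules.ratio_stage2_low) & (ratio < rules.ratio_stage3)] = 2
    # the >=4.0 mg/dL level counts as stage 3 only alongside an acute rise
    stage[(ratio >= rules.ratio_stage3)
          | ((current >= rules.abs_level_stage3) & stage1_criterion)] = 3
    stage[rrt] = 3
    return stage


def stage_aki(baseline: float, current: float, rrt: bool = False,
              rules: StagingRules = StagingRules()) -> int:
    """AKI stage (0-3) of ``current`` sCr relative to ``baseline``."""
    return int(_stage_array(baseline, current, rrt, rules)[()])


# ---------------------------------------------------------------------------
# Visit labeling
# ---------------------------------------------------------------------------

def label_visit(visit, rules: StagingRules = StagingRules()) -> OutcomeLabel:
    """Label one visit record (mapping-like with the cohort schema).

    Needs ``prior_scr_series``, ``first_scr``, ``followup_scr_series``,
    ``rrt_within_72h``, ``age``, ``sex``, and optionally ``arrival_time``.
    """
    baseline, source = compute_baseline(
        visit["prior_scr_series"], visit["age"], visit["sex"], rules,
        arrival_time=visit.get("arrival_time") if hasattr(visit, "get") else None,
    )
    initial = stage_aki(baseline, float(visit["first_scr"]), rrt=False, rules=rules)
    followups = [float(v) for _, v in _iter_series(visit["followup_scr_series"])]
    rrt = bool(visit["rrt_within_72h"])
    if not followups and not rrt:
        return OutcomeLabel(baseline, source, initial, outcome_observed=False)
    peak_scr = max(followups) if followups else float(visit["first_scr"])
    peak = stage_aki(baseline, peak_scr, rrt=rrt, rules=rules)
    y_any = peak > initial
    y_severe = (peak >= 2) and (peak > initial)
    return OutcomeLabel(baseline, source, initial, True, peak, y_any, y_severe)


def _iter_series(series) -> Iterable[Tuple[object, float]]:
    for item in series:
        if isinstance(item, (tuple, list)) and len(item) == 2:
            yield item
        else:
            yield (None, item)


def label_cohort(cohort: pd.DataFrame, rules: StagingRules = StagingRules()) -> pd.DataFrame:
    """Vectorized labeling of a cohort table; returns a label table.

    One row per visit, keyed by ``visit_id``, with every :class:`OutcomeLabel`
    field (missing peak/outcome fields as NaN).
    """
    n = len(cohort)
    baseline = np.empty(n)
    source = np.empty(n, dtype=object)
    arrivals = cohort["arrival_time"].to_numpy() if "arrival_time" in cohort else [None] * n
    ages = cohort["age"].to_numpy()
    sexes = cohort["sex"].to_numpy()

    priors = cohort["prior_scr_series"].to_numpy()
    # closed-form CKD-EPI inversion vectorizes; do the empty-history rows in bulk
    needs_imput = np.array([len(p) == 0 for p in priors])
    for i in np.flatnonzero(~needs_imput):
        baseline[i], source[i] = compute_baseline(
            priors[i], ages[i], sexes[i], rules, arrival_time=arrivals[i]
        )
    if needs_imput.any():
        for s in ("F", "M"):
            mask = needs_imput & (np.char.upper(sexes.astype(str)) == s)
            if mask.any():
                baseline[mask] = invert_ckd_epi(ages[mask], s, rules.reference_egfr)
                source[mask] = "imputed_ckd_epi"

    first = cohort["first_scr"].to_numpy(dtype=float)
    initial = _stage_array(baseline, first, False, rules)

    followups = cohort["followup_scr_series"].to_numpy()
    rrt = cohort["rrt_within_72h"].to_numpy(dtype=bool)
    peak_scr = np.array(
        [max((float(v) for _, v in _iter_series(s)), default=np.nan) for s in followups]
    )
    observed = ~np.isnan(peak_scr) | rrt
    peak_input = np.where(np.isnan(peak_scr), first, peak_scr)
    peak = _stage_array(baseline, peak_input, rrt, rules).astype(float)
    peak[~observed] = np.nan

    y_any = np.where(observed, peak > initial, np.nan)
    y_severe = np.where(observed, (peak >= 2) & (peak > initial), np.nan)

    return pd.DataFrame(
        {
            "visit_id": cohort["visit_id"].to_numpy(),
            "baseline_scr": baseline,
            "baseline_source": source,
            "initial_stage": initial,
            "outcome_observed": observed,
            "peak_stage": peak,
            "y_any": y_any,
            "y_severe": y_severe,
        }
    )


# ---------------------------------------------------------------------------
# Cohort exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(
    cohort: pd.DataFrame,
    labels: pd.DataFrame,
    rules: StagingRules = StagingRules(),
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply study exclusions; returns (cohort, labels, counts-by-reason).

    Removes visits with end-stage kidney disease / RRT dependence, baseline
    sCr >= 4.0 mg/dL, or severe (stage 3) AKI already present on arrival.
    Order of the retained rows is preserved.
    """
    lab = labels.set_index("visit_id").loc[cohort["visit_id"]]
    eskd = (
        cohort["eskd"].to_numpy(dtype=bool)
        if "eskd" in cohort
        else np.zeros(len(cohort), dtype=bool)
    )
    base_hi = lab["baseline_scr"].to_numpy() >= rules.exclusion_baseline
    stage3 = lab["initial_stage"].to_numpy() >= 3
    reason = np.full(len(cohort), "", dtype=object)
    reason[stage3] = "stage3_on_arrival"
    reason[base_hi] = "baseline_ge_4"
    reason[eskd] = "eskd_rrt_dependence"
    keep = reason == ""
    counts = {
        r: int((reason == r).sum())
        for r in ("eskd_rrt_dependence", "baseline_ge_4", "stage3_on_arrival")
        if (reason == r).any()
    }
    kept_ids = cohort.loc[keep, "visit_id"]
    return (
        cohort.loc[keep].reset_index(drop=True),
        labels[labels["visit_id"].isin(set(kept_ids))].reset_index(drop=True),
        counts,
    )
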