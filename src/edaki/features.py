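"""Predictor assembly shared by the risk, propensity and imputation models.

Predictors are restricted to information available when the first metabolic
panel results: demographics, site, chief complaint, triage vitals, routine
labs, comorbidity flags, the historical or imputed baseline creatinine, the
first in-ED creatinine, and the arrival AKI stage. Missing continuous
values stay NaN (the tree learner handles them natively); missing
categorical values map to an explicit ``"null"`` level.
"""

from __future__ import annotations

import pandas as pd

CONTINUOUS = [
    "age", "sbp", "hr", "bun", "sodium", "potassium", "hemoglobin",
    "baseline_scr", "first_scr", "initial_stage",
]
CATEGORICAL = ["sex", "site_id", "complaint"]
FLAGS = ["ckd", "diabetes", "chf"]

FEATURE_COLUMNS = CONTINUOUS + FLAGS + CATEGORICAL


def build_features(cohort: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Feature matrix aligned to ``cohort`` row order, indexed by visit_id."""
    lab = labels.set_index("visit_id").loc[cohort["visit_id"]]
    X = cohort.set_index("visit_id")[
        [c for c in CONTINUOUS if c in cohort] + FLAGS + CATEGORICAL
    ].copy()
    X["baseline_scr"] = lab["baseline_scr"].to_numpy()
    X["initial_stage"] = lab["initial_stage"].to_numpy(dtype=float)
    for col in CATEGORICAL:
        X[col] = (
            X[col].astype("object").where(X[col].notna(), "null").astype("category")
        )
    X[FLAGS] = X[FLAGS].astype(float)
    return X[FEATURE_COLUMNS]
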