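import numpy as np
import pandas as pd
import pytest

from edaki.kdigo import apply_exclusions, label_cohort
from edaki.simulate import SimulationConfig, simulate_cohort

# single-point grid used throughout the suite: the pipeline's default
# operating settings, skipping the inner grid search for speed
FAST_GRID = [dict(max_depth=3, n_estimators=150, learning_rate=0.1,
                  subsample=0.8, reg_lambda=1.0)]


@pytest.fixture(scope="session")
def small_cohort():
    """Labeled MAR cohort (n=4000) with exclusions applied, plus truth."""
    cfg = SimulationConfig(n_visits=4000, seed=11)
    cohort, truth = simulate_cohort(cfg)
    labels = label_cohort(cohort)
    cohort, labels, _ = apply_exclusions(cohort, labels)
    truth = truth[truth["visit_id"].isin(set(cohort["visit_id"]))].reset_index(drop=True)
    return cohort, labels, truth


@pytest.fixture(scope="session")
def midsize_cohort():
    """Labeled MAR cohort (n=20000) for recovery-style checks."""
    cfg = SimulationConfig(n_visits=20_000, seed=7)
    cohort, truth = simulate_cohort(cfg)
    labels = label_cohort(cohort)
    cohort, labels, _ = apply_exclusions(cohort, labels)
    truth = truth[truth["visit_id"].isin(set(cohort["visit_id"]))].reset_index(drop=True)
    return cohort, labels, truth


def align_truth(cohort: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    return truth.set_index("visit_id").loc[cohort["visit_id"]]


def observed_mask(cohort: pd.DataFrame, labels: pd.DataFrame) -> np.ndarray:
    lab = labels.set_index("visit_id").loc[cohort["visit_id"]]
    return lab["outcome_observed"].to_numpy(dtype=bool)
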