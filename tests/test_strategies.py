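"""Training-set construction under the four missing-outcome strategies."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from edaki.features import build_features
from edaki.strategies import (
    PropensityModel,
    StrategyConfig,
    build_assume_negative,
    build_complete_case,
    build_ipw,
    build_multiple_imputation,
    build_training_set,
    fit_missingness_propensity,
    fit_preliminary_model,
    impute_outcomes,
)
from tests.conftest import observed_mask


def test_complete_case_keeps_only_observed(small_cohort):
    cohort, labels, _ = small_cohort
    obs = observed_mask(cohort, labels)
    ts = build_complete_case(cohort, labels, "y_any")
    assert len(ts) == obs.sum()
    assert np.all(ts.weights == 1.0)
    assert set(ts.visit_ids) == set(cohort.loc[obs, "visit_id"])


def test_assume_negative_counts_and_dilution(small_cohort):
    cohort, labels, _ = small_cohort
    obs = observed_mask(cohort, labels)
    cc = build_complete_case(cohort, labels, "y_any")
    an = build_assume_negative(cohort, labels, "y_any")
    assert len(an) == len(cohort)
    assert an.y.sum() == cc.y.sum()  # positives only from observed visits
    # dilution: rate strictly below complete-case rate when outcomes missing
    assert an.y.mean() < cc.y.mean()
    # missing visits all coded negative
    missing_ids = set(cohort.loc[~obs, "visit_id"])
    assert not an.y[np.isin(an.visit_ids, list(missing_ids))].any()


def test_strategies_coincide_without_missingness():
    from edaki.kdigo import label_cohort
    from edaki.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_visits=800, seed=2,
                           missingness_coefficients={"intercept": 30.0})
    cohort, _ = simulate_cohort(cfg)
    labels = label_cohort(cohort)
    cc = build_complete_case(cohort, labels, "y_any")
    an = build_assume_negative(cohort, labels, "y_any")
    assert len(cc) == len(an) == len(cohort)
    np.testing.assert_array_equal(cc.y, an.y)


class _StubPredictor:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        p = np.full(len(X), self.p)
        return np.column_stack([1 - p, p])


def _toy_sets(n_obs=4, n_miss=6):
    X = pd.DataFrame({"x": np.arange(n_obs + n_miss, dtype=float)})
    obs_set_X = X.iloc[:n_obs]
    from edaki.strategies import TrainingSet

    obs = TrainingSet(obs_set_X, np.array([1, 0, 0, 1], dtype=bool)[:n_obs],
                      np.ones(n_obs), np.array([f"o{i}" for i in range(n_obs)]),
                      "complete_case", "y_any")
    return X.iloc[n_obs:], np.array([f"m{i}" for i in range(n_miss)]), obs


def test_impute_outcomes_degenerate_probabilities():
    X_miss, ids, obs = _toy_sets()
    for p, expect in ((0.0, False), (1.0, True)):
        ts = impute_outcomes(_StubPredictor(p), X_miss, ids, 20, 0, obs)
        imputed = ts.y[ts.replicate >= 0]
        assert len(imputed) == len(X_miss) * 20
        assert (imputed == expect).all()
        # equal representation: total weight = number of visits
        assert ts.total_weight == pytest.approx(len(obs) + len(X_miss))
        assert np.allclose(ts.weights[ts.replicate >= 0], 1 / 20)


def test_impute_outcomes_bernoulli_mean():
    n_miss = 10_000
    X_miss = pd.DataFrame({"x": np.zeros(n_miss)})
    ids = np.array([f"m{i}" for i in range(n_miss)])
    _, _, obs = _toy_sets()
    ts = impute_outcomes(_StubPredictor(0.3), X_miss, ids, 20, 5, obs)
    imputed = ts.y[ts.replicate >= 0].astype(float)
    se = np.sqrt(0.3 * 0.7 / (n_miss * 20))
    assert abs(imputed.mean() - 0.3) < 3 * se


def test_preliminary_model_recovers_conditional_rates():
    rng = np.random.default_rng(0)
    n = 20_000
    x = rng.integers(0, 2, n)
    y = rng.random(n) < np.where(x == 1, 0.30, 0.05)
    X = pd.DataFrame({"x": x.astype(float)})
    from edaki.strategies import TrainingSet

    ts = TrainingSet(X, y, np.ones(n), np.arange(n).astype(str),
                     "complete_case", "y_any")
    clf = fit_preliminary_model(ts, seed=1)
    p = clf.predict_proba(X)[:, 1]
    assert np.all((p > 0) & (p < 1))
    assert p[x == 1].mean() == pytest.approx(0.30, abs=0.02)
    assert p[x == 0].mean() == pytest.approx(0.05, abs=0.02)
    # determinism under fixed seed
    clf2 = fit_preliminary_model(ts, seed=1)
    np.testing.assert_array_equal(p, clf2.predict_proba(X)[:, 1])


def test_preliminary_model_single_class_errors():
    from edaki.strategies import TrainingSet

    X = pd.DataFrame({"x": [0.0, 1.0]})
    ts = TrainingSet(X, np.array([True, True]), np.ones(2),
                     np.array(["a", "b"]), "complete_case", "y_any")
    with pytest.raises(ValueError, match="single class"):
        fit_preliminary_model(ts)


def test_propensity_mean_matches_observed_fraction(midsize_cohort):
    cohort, labels, _ = midsize_cohort
    obs = observed_mask(cohort, labels)
    prop = fit_missingness_propensity(cohort, labels, StrategyConfig(strategy="ipw"))
    X = build_features(cohort, labels)
    p = prop.predict(X)
    assert np.all((p >= prop.clip) & (p < 1.0))
    assert abs(p.mean() - obs.mean()) < 0.02


def test_propensity_tracks_true_missingness_model(midsize_cohort):
    cohort, labels, truth = midsize_cohort
    prop = fit_missingness_propensity(cohort, labels, StrategyConfig(strategy="ipw"))
    p_hat = prop.predict(build_features(cohort, labels))
    p_true = truth.set_index("visit_id").loc[cohort["visit_id"], "p_observed"]
    rho = spearmanr(p_hat, p_true).statistic
    assert rho > 0.9


def test_propensity_flat_when_missingness_covariate_free():
    from edaki.kdigo import label_cohort
    from edaki.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_visits=8000, seed=6,
                           missingness_coefficients={"intercept": 0.0})
    cohort, _ = simulate_cohort(cfg)
    labels = label_cohort(cohort)
    prop = fit_missingness_propensity(cohort, labels, StrategyConfig(strategy="ipw"))
    p = prop.predict(build_features(cohort, labels))
    assert abs(p.mean() - 0.5) < 0.03
    assert p.std() < 0.08  # near-constant: no covariate signal to exploit


def test_ipw_weights_and_horvitz_thompson(midsize_cohort):
    cohort, labels, _ = midsize_cohort
    prop = fit_missingness_propensity(cohort, labels, StrategyConfig(strategy="ipw"))
    ts = build_ipw(cohort, labels, prop, "y_any")
    assert np.all(ts.weights >= 1.0)
    # Horvitz-Thompson: weights over observed visits recover the cohort size
    assert abs(ts.total_weight - len(cohort)) / len(cohort) < 0.05


class _ConstantPropensity(PropensityModel):
    def __init__(self, p):
        super().__init__(model=None, clip=0.01, feature_columns=())
        self._p = p

    def predict(self, X):
        return np.full(len(X), self._p)


def test_ipw_reciprocal_and_reduction_to_complete_case(small_cohort):
    cohort, labels, _ = small_cohort
    ts_half = build_ipw(cohort, labels, _ConstantPropensity(0.5), "y_any")
    assert np.allclose(ts_half.weights, 2.0)
    ts_one = build_ipw(cohort, labels, _ConstantPropensity(1.0 - 1e-13), "y_any")
    cc = build_complete_case(cohort, labels, "y_any")
    assert len(ts_one) == len(cc)
    np.testing.assert_allclose(ts_one.weights, 1.0, rtol=1e-9)


def test_strategy_dispatch_and_determinism(small_cohort):
    cohort, labels, _ = small_cohort
    for strat in ("complete_case", "assume_negative", "multiple_imputation", "ipw"):
        cfg = StrategyConfig(strategy=strat, seed=9)
        a = build_training_set(cohort, labels, "y_any", cfg)
        b = build_training_set(cohort, labels, "y_any", cfg)
        assert a.strategy == strat
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_allclose(a.weights, b.weights)
        # total-weight invariant per strategy
        n_obs = observed_mask(cohort, labels).sum()
        if strat == "complete_case":
            assert a.total_weight == n_obs
        elif strat in ("assume_negative", "multiple_imputation"):
            assert a.total_weight == pytest.approx(len(cohort))


def test_strategy_config_validation():
    with pytest.raises(ValueError):
        StrategyConfig(strategy="nope")
    with pytest.raises(ValueError):
        StrategyConfig(m_imputations=0)
    with pytest.raises(ValueError):
        StrategyConfig(propensity_clip=1.5)


def test_propensity_schema_mismatch_rejected(small_cohort):
    cohort, labels, _ = small_cohort
    prop = fit_missingness_propensity(cohort, labels, StrategyConfig(strategy="ipw"))
    X = build_features(cohort, labels).rename(columns={"age": "years"})
    with pytest.raises(ValueError, match="schema"):
        prop.predict(X)
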