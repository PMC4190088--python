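import json

import numpy as np
import pytest
from scipy.special import expit, logit

from readmit import (CohortSimParams, EncodedCohort, RiskModel,
                     apply_recalibration, calibrate_risk_groups, compute_auc,
                     encode_features, fit_lasso_logistic, generate_cohort,
                     platt_recalibrate, predict_risk, reclassification_matrix,
                     simulation_encoding_spec)
from readmit.errors import ConfigurationError, ModelFitError, UndefinedAUCError
from readmit.models import _sklearn_l1, assign_groups

from conftest import RECOVERY_PARAMS


def toy_cohort(n=400, seed=0, beta=(1.2, -0.8), intercept=-1.0):
    """Two binary features with known logistic truth (overlapping classes)."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, 2)) < 0.4).astype(np.uint8)
    p = expit(intercept + X @ np.asarray(beta))
    y = (rng.random(n) < p).astype(int)
    return EncodedCohort(features=X, outcome=y, feature_names=["f0", "f1"],
                         visit_ids=[f"V{i}" for i in range(n)])


def newton_logistic(X, y, tol=1e-12, max_iter=100):
    """Independent unpenalized MLE oracle (IRLS with explicit intercept)."""
    Xd = np.column_stack([np.ones(len(y)), X])
    w = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        p = expit(Xd @ w)
        grad = Xd.T @ (y - p)
        hess = Xd.T @ (Xd * (p * (1 - p))[:, None])
        step = np.linalg.solve(hess, grad)
        w = w + step
        if np.abs(step).max() < tol:
            break
    return w  # [intercept, beta...]


# ------------------------------------------------------------------ LASSO fit

def test_full_penalty_limit_gives_intercept_only_model():
    cohort = toy_cohort(n=500, seed=1)
    model = fit_lasso_logistic(cohort, lambda_grid=[1e6], k_folds=3, seed=0)
    assert model.selected_count == 0
    prevalence = cohort.outcome.mean()
    assert model.intercept == pytest.approx(logit(prevalence), abs=1e-2)


def test_unpenalized_fit_matches_newton_oracle():
    cohort = toy_cohort(n=600, seed=2)
    model = fit_lasso_logistic(cohort, lambda_grid=[0.0], k_folds=3, seed=0)
    w = newton_logistic(cohort.features.astype(float), cohort.outcome)
    assert model.intercept == pytest.approx(w[0], abs=1e-4)
    coef = [model.coefficients.get(n, 0.0) for n in cohort.feature_names]
    assert coef == pytest.approx(list(w[1:]), abs=1e-4)


def test_sparse_selection_recovers_planted_features(recovery_study):
    """With the 1-SE rule at this sample size, most selected coefficients
    correspond to truly active features with the correct sign."""
    model = recovery_study["model"]
    beta = recovery_study["truth"]["beta"]
    active = {j: beta[j] for j in recovery_study["truth"]["active_indices"]}
    true_pos = 0
    for name, coef in model.coefficients.items():
        if name.startswith("diag:SYN"):
            j = int(name.rsplit("SYN", 1)[1])
            if j in active and np.sign(coef) == np.sign(active[j]):
                true_pos += 1
    assert model.selected_count > 0
    assert true_pos / model.selected_count >= 0.70


def test_selection_count_nonincreasing_along_penalty_path():
    params = CohortSimParams(n_visits=500, n_features=30, n_active_features=8,
                             feature_density=0.15, coef_scale=0.8, seed=3)
    cohort = generate_cohort(params)
    enc = encode_features(cohort, simulation_encoding_spec(30))
    X, y = enc.features.astype(float), enc.outcome
    counts = [int((_sklearn_l1(X, y, lam).coef_.ravel() != 0).sum())
              for lam in np.logspace(-3, 0, 8)]
    assert counts == sorted(counts, reverse=True)


def test_fit_requires_both_classes_and_enough_folds():
    cohort = toy_cohort(n=100)
    cohort.outcome[:] = 0
    with pytest.raises(ModelFitError):
        fit_lasso_logistic(cohort, lambda_grid=[0.01], k_folds=3)
    with pytest.raises(ConfigurationError):
        fit_lasso_logistic(toy_cohort(), lambda_grid=[0.01], k_folds=1)


def test_cv_stats_recorded():
    model = fit_lasso_logistic(toy_cohort(n=500, seed=4),
                               lambda_grid=[1e-3, 1e-2], k_folds=4, seed=1)
    assert 0.0 < model.cv_auc_mean < 1.0
    assert model.cv_auc_se > 0.0


# ------------------------------------------------------------------ prediction

def test_predict_risk_trivial_models():
    cohort = toy_cohort(n=10)
    flat = RiskModel(intercept=0.0, coefficients={}, lambda_=0.1)
    assert predict_risk(flat, cohort) == pytest.approx([0.5] * 10)
    base = RiskModel(intercept=float(logit(0.25)), coefficients={}, lambda_=0.1)
    assert predict_risk(base, cohort) == pytest.approx([0.25] * 10)


def test_predict_risk_handworked_dot_product():
    cohort = EncodedCohort(features=[[1, 0, 1]], outcome=[0],
                           feature_names=["a", "b", "c"], visit_ids=["V0"])
    model = RiskModel(intercept=-0.7, coefficients={"a": 0.3, "b": 5.0, "c": -0.1},
                      lambda_=0.0)
    expected = expit(-0.7 + 0.3 - 0.1)
    assert predict_risk(model, cohort)[0] == pytest.approx(expected, abs=1e-12)


def test_predict_risk_missing_feature_treated_as_zero():
    cohort = EncodedCohort(features=[[1]], outcome=[0], feature_names=["a"],
                           visit_ids=["V0"])
    model = RiskModel(intercept=0.0, coefficients={"a": 1.0, "ghost": 9.0},
                      lambda_=0.0)
    assert predict_risk(model, cohort)[0] == pytest.approx(expit(1.0))


# ------------------------------------------------------------------------- AUC

def test_auc_matches_brute_force_pair_counting():
    rng = np.random.default_rng(7)
    p = rng.random(60).round(1)  # rounding forces ties
    y = rng.integers(0, 2, 60)
    pos, neg = p[y == 1], p[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
    assert compute_auc(p, y) == pytest.approx(oracle, abs=1e-12)


@pytest.mark.parametrize("transform", [
    lambda p: 2 * p, lambda p: p**3, lambda p: expit(5 * p - 1),
    lambda p: np.log(p + 1e-9),
])
def test_auc_invariant_under_strictly_monotone_transforms(transform):
    rng = np.random.default_rng(11)
    p = rng.random(200)
    y = rng.integers(0, 2, 200)
    assert compute_auc(transform(p), y) == pytest.approx(compute_auc(p, y))


def test_auc_undefined_for_single_class():
    with pytest.raises(UndefinedAUCError):
        compute_auc([0.1, 0.9], [1, 1])


# ----------------------------------------------------------------- risk groups

def test_two_se_check_has_nominal_coverage_under_calibration_null():
    """Under the calibration null (y ~ Bernoulli(p)) the observed tertile
    rate falls within two binomial SEs of the predicted mean about 95% of
    the time; checked as coverage over replicates rather than a single draw."""
    rng = np.random.default_rng(21)
    hits = trials = 0
    for _ in range(40):
        p = rng.uniform(0.05, 0.6, 5000)
        y = (rng.random(5000) < p).astype(int)
        groups = calibrate_risk_groups(p, y)
        gap = (groups.table["observed_rate"] - groups.table["predicted_mean"]).abs()
        hits += int((gap < 2 * groups.table["se"]).sum())
        trials += 3
        assert groups.table["count"].sum() == 5000
    assert hits / trials >= 0.85


def test_constant_predictions_degenerate_tertiles():
    with pytest.raises(ConfigurationError):
        calibrate_risk_groups([0.3] * 100, [0] * 50 + [1] * 50)


def test_user_cutpoints_match_manual_binning():
    p = [0.05, 0.2, 0.25, 0.35, 0.41, 0.9]
    y = [0, 0, 1, 0, 1, 1]
    groups = calibrate_risk_groups(p, y, cutpoints=(0.2, 0.4))
    assert list(groups.labels) == ["low", "low", "moderate", "moderate",
                                   "high", "high"]
    assert groups.table.loc["high", "observed_rate"] == pytest.approx(1.0)


def test_empty_group_under_user_cutpoints_errors():
    with pytest.raises(ConfigurationError):
        calibrate_risk_groups([0.9, 0.8, 0.95], [1, 0, 1], cutpoints=(0.2, 0.4))


def test_platt_recalibration_recovers_distortion():
    rng = np.random.default_rng(5)
    p_true = rng.uniform(0.05, 0.7, 30_000)
    y = (rng.random(30_000) < p_true).astype(int)
    distorted = expit(0.8 + 1.7 * logit(p_true))  # known (a, b) distortion
    a, b = platt_recalibrate(distorted, y)
    # inverting the distortion: a + b*(0.8 + 1.7 z) ≈ z
    assert b * 1.7 == pytest.approx(1.0, abs=0.1)
    assert a + b * 0.8 == pytest.approx(0.0, abs=0.05)
    fixed = apply_recalibration(distorted, (a, b))
    groups = calibrate_risk_groups(fixed, y)
    gap = (groups.table["observed_rate"] - groups.table["predicted_mean"]).abs()
    assert (gap < 2 * groups.table["se"]).all()


# ------------------------------------------------------------ reclassification

def test_identical_labelings_have_zero_reclassification():
    labels = ["low"] * 5 + ["moderate"] * 5 + ["high"] * 5
    m = reclassification_matrix(labels, labels)
    assert np.diag(m.row_percent) == pytest.approx([100.0] * 3)
    assert m.total_reclassified_percent.tolist() == pytest.approx([0.0] * 3)


def test_disjoint_labelings_fully_reclassified():
    m = reclassification_matrix(["low"] * 4, ["high"] * 4)
    assert m.row_percent.loc["low", "high"] == pytest.approx(100.0)
    assert m.total_reclassified_percent["low"] == pytest.approx(100.0)


def test_reclassification_matches_brute_force_crosstab():
    rng = np.random.default_rng(13)
    labels = np.array(["low", "moderate", "high"])
    a = labels[rng.integers(0, 3, 300)]
    b = labels[rng.integers(0, 3, 300)]
    m = reclassification_matrix(a, b)
    for gi in labels:
        row_n = (a == gi).sum()
        for gj in labels:
            expected = 100.0 * ((a == gi) & (b == gj)).sum() / row_n
            assert m.row_percent.loc[gi, gj] == pytest.approx(expected)
        assert m.row_percent.loc[gi].sum() == pytest.approx(100.0, abs=0.1)


def test_reclassification_rejects_unknown_labels():
    with pytest.raises(ValueError):
        reclassification_matrix(["low", "banana"], ["low", "high"])


# -------------------------------------------------------------- serialization

def test_risk_model_json_round_trip(tmp_path):
    model = RiskModel(intercept=-1.5, coefficients={"a": 0.3, "b": -0.2},
                      lambda_=0.01, cv_auc_mean=0.7, cv_auc_se=0.02)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = RiskModel.from_json(path)
    assert loaded == model
    payload = json.loads(path.read_text())
    assert payload["selected_count"] == 2


def test_assign_groups_boundaries_half_open():
    labels = assign_groups([0.1, 0.2, 0.21, 0.4, 0.41], (0.2, 0.4))
    assert list(labels) == ["low", "low", "moderate", "moderate", "high"]
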