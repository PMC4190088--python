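import datetime as dt

import numpy as np
import pytest

from readmit import (CohortSimParams, DERIVATION_WINDOW, VALIDATION_WINDOW,
                     VisitRecord, apply_recalibration, encode_features,
                     fit_lasso_logistic, generate_cohort,
                     out_of_fold_predictions, platt_recalibrate, predict_risk,
                     simulation_encoding_spec, split_cohorts)

# Frozen recovery-study conditions: a planted sparse logistic truth that a
# LASSO fit at this sample size should largely recover. The dense λ grid plus
# the one-standard-error rule is the sparse-selection configuration whose
# behaviour the selection test asserts.
RECOVERY_PARAMS = dict(
    n_visits=4000, derivation_fraction=0.667, n_features=200,
    n_active_features=20, feature_density=0.1, coef_scale=0.8, seed=7,
)
RECOVERY_GRID = tuple(np.logspace(-3, -1, 9))
RECOVERY_FOLDS = 5


@pytest.fixture(scope="session")
def recovery_study():
    """Simulate, split, encode and fit once; shared by recovery/calibration tests."""
    params = CohortSimParams(**RECOVERY_PARAMS)
    cohort, truth = generate_cohort(params, return_truth=True)
    derivation, validation = split_cohorts(cohort, DERIVATION_WINDOW,
                                           VALIDATION_WINDOW)
    spec = simulation_encoding_spec(params.n_features)
    enc_der = encode_features(derivation, spec)
    enc_val = encode_features(validation, spec)
    model = fit_lasso_logistic(enc_der, lambda_grid=RECOVERY_GRID,
                               k_folds=RECOVERY_FOLDS, seed=params.seed,
                               one_se_rule=True)
    oof = out_of_fold_predictions(enc_der, model.lambda_,
                                  k_folds=RECOVERY_FOLDS, seed=params.seed)
    recal = platt_recalibrate(oof, enc_der.outcome)
    p_val = apply_recalibration(predict_risk(model, enc_val), recal)
    return {
        "params": params, "truth": truth, "cohort": cohort,
        "derivation": derivation, "validation": validation,
        "enc_der": enc_der, "enc_val": enc_val,
        "model": model, "p_val": p_val, "recalibration": recal,
    }


def make_visit(**overrides) -> VisitRecord:
    """A minimal valid visit; override any field."""
    base = dict(
        visit_id="V1", patient_id="P1",
        admit_date=dt.date(2008, 1, 1), discharge_date=dt.date(2008, 1, 4),
        visit_type="inpatient", admit_source="referral",
        age=70.0, gender="F", marital_status="married", family_support="yes",
        diagnoses=[], labs=[], lab_variation=[], medications=[],
        er_visits_6mo=0, admissions_6mo=0, admissions_12mo=0,
        isolated_room=False,
        exclusion_flags={}, outcome_R=0, readmit_cost=0.0,
        readmit_outside=False, true_p=None,
    )
    base.update(overrides)
    return VisitRecord(**base)


@pytest.fixture
def visit_factory():
    return make_visit
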