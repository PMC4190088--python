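"""End-to-end seeded workflow: simulate → prep → fit → calibrate → decide → sweep.

``run_pipeline`` drives every stage from one config mapping and writes a
report bundle (model JSON, prediction/allocation CSVs, risk-group,
reclassification and policy-comparison tables, sensitivity surfaces, and a
manifest with the config hash, seed and library versions). The same config
and seed always produce an identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .decisions import DecisionParams, allocate
from .errors import ConfigurationError
from .evaluate import sensitivity_grid, table4_report
from .lace import calibrate_lace, lace_score
from .models import (apply_recalibration, assign_groups, calibrate_risk_groups,
                     compute_auc, fit_lasso_logistic, out_of_fold_predictions,
                     platt_recalibrate, predict_risk, reclassification_matrix)
from .prep import (DEFAULT_ICD9_PREFIXES, apply_cms_exclusions, encode_features,
                   simulation_encoding_spec, split_cohorts)
from .simulate import (DERIVATION_WINDOW, SYNTH_CODE_PREFIX, VALIDATION_WINDOW,
                       CohortSimParams, generate_cohort)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "default_config", "infer_simulation_spec"]


def default_config() -> dict:
    """A small, fast demonstration configuration."""
    return {
        "seed": 0,
        "simulate": {
            "n_visits": 1200,
            "n_features": 300,
            "n_active_features": 30,
            "feature_density": 0.1,
            "coef_scale": 0.5,
            "exclusion_rates": {rule: 0.0 for rule in
                                ("non_FFS", "died_in_hospital", "left_AMA",
                                 "transferred_acute", "is_readmission_of_index")},
        },
        "fit": {"k_folds": 5, "one_se_rule": False},
        "decision": {"intervention_cost": 1300.0, "efficacy": 0.35,
                     "readmission_cost": None},
        "evaluate": {"mode": "observed",
                     "cost_values": [300.0, 800.0, 1300.0, 1800.0],
                     "efficacy_values": [0.25, 0.35]},
        "sweep": {"cost_axis": {"start": 0.0, "stop": 2500.0, "num": 12},
                  "efficacy_axis": {"start": 0.05, "stop": 0.60, "num": 12},
                  "mode": "expected"},
    }


def infer_simulation_spec(cohort):
    """Rebuild the simulator-aware encoding spec from the codes in a cohort."""
    top = -1
    for v in cohort:
        for j in v.synthetic_codes():
            top = max(top, j)
    if top < 0:
        from .prep import default_encoding_spec

        return default_encoding_spec()
    return simulation_encoding_spec(top + 1)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _axis(spec: dict) -> np.ndarray:
    return np.linspace(float(spec["start"]), float(spec["stop"]), int(spec["num"]))


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full workflow; returns a summary dict (also in manifest).

    Stage order: simulate, CMS exclusions, date split, binary encoding,
    LASSO fit with CV λ selection, Platt recalibration of scores on the
    derivation cohort, LACE scoring + calibration, risk grouping and
    reclassification on validation, threshold allocation, policy-comparison
    table, and the cost × efficacy sensitivity sweep.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    seed = int(cfg.get("seed", 0))

    def stamp(stage):
        logger.info("[%7.2fs] %s", time.time() - t0, stage)

    sim_cfg = dict(cfg["simulate"])
    sim_cfg["exclusion_rates"] = dict(sim_cfg.get("exclusion_rates", {}))
    params = CohortSimParams(seed=seed, **sim_cfg)
    cohort = generate_cohort(params)
    io.write_cohort_csv(cohort, out / "cohort.csv")
    stamp(f"simulate: {len(cohort)} visits")

    eligible, excl_log = apply_cms_exclusions(cohort)
    (out / "exclusions.json").write_text(json.dumps(excl_log, indent=1))
    derivation, validation = split_cohorts(eligible, DERIVATION_WINDOW,
                                           VALIDATION_WINDOW)
    if not derivation or not validation:
        raise ConfigurationError("empty derivation or validation cohort")
    stamp(f"prep: {len(eligible)} eligible → {len(derivation)}/{len(validation)}")

    spec = simulation_encoding_spec(params.n_features)
    enc_der = encode_features(derivation, spec)
    enc_val = encode_features(validation, spec)
    stamp(f"encode: {len(enc_der.feature_names)} binary features")

    fit_cfg = cfg["fit"]
    model = fit_lasso_logistic(enc_der,
                               k_folds=int(fit_cfg.get("k_folds", 10)),
                               seed=seed,
                               one_se_rule=bool(fit_cfg.get("one_se_rule", False)))
    model.to_json(out / "model.json")
    stamp(f"fit: λ={model.lambda_:.3g}, {model.selected_count} features selected")

    # honest recalibration: Platt fit on out-of-fold derivation predictions
    p_der_oof = out_of_fold_predictions(enc_der, model.lambda_,
                                        k_folds=int(fit_cfg.get("k_folds", 10)),
                                        seed=seed)
    p_val_raw = predict_risk(model, enc_val)
    recal = platt_recalibrate(p_der_oof, enc_der.outcome)
    p_der = apply_recalibration(p_der_oof, recal)
    p_val = apply_recalibration(p_val_raw, recal)

    lace_der = np.array([lace_score(v).total for v in derivation])
    lace_val = np.array([lace_score(v).total for v in validation])
    lace_cal = calibrate_lace(lace_der, enc_der.outcome)
    p_lace_der = lace_cal.predict(lace_der)
    p_lace_val = lace_cal.predict(lace_val)

    pd.DataFrame({
        "visit_id": enc_val.visit_ids, "p_raw": p_val_raw, "p": p_val,
        "lace_total": lace_val, "p_lace": p_lace_val,
        "outcome": enc_val.outcome,
    }).to_csv(out / "predictions_validation.csv", index=False)

    auc_val = compute_auc(p_val, enc_val.outcome)
    auc_lace = compute_auc(p_lace_val, enc_val.outcome)
    stamp(f"score: validation AUC classifier={auc_val:.3f} LACE={auc_lace:.3f}")

    groups_der = calibrate_risk_groups(p_der, enc_der.outcome)
    groups_val = calibrate_risk_groups(p_val, enc_val.outcome,
                                       cutpoints=groups_der.boundaries)
    groups_val.table.to_csv(out / "risk_groups_validation.csv")

    lace_cuts = tuple(np.quantile(p_lace_der, [1 / 3, 2 / 3]))
    if lace_cuts[0] < lace_cuts[1]:
        lace_groups_val = assign_groups(p_lace_val, lace_cuts)
        recls = reclassification_matrix(lace_groups_val, groups_val.labels)
        recls.to_csv(out / "reclassification.csv")

    dec_cfg = cfg["decision"]
    C = dec_cfg.get("readmission_cost")
    if C is None:
        costs_der = [v.readmit_cost for v in derivation if v.outcome_R == 1]
        C = float(np.mean(costs_der))
    dparams = DecisionParams(float(dec_cfg["intervention_cost"]),
                             float(dec_cfg["efficacy"]), float(C))
    policy = allocate(p_val, dparams)
    pd.DataFrame({
        "visit_id": enc_val.visit_ids, "p": p_val,
        "p_star": policy.threshold_p_star, "intervene": policy.intervene.astype(int),
    }).to_csv(out / "allocation.csv", index=False)
    stamp(f"decide: p*={policy.threshold_p_star:.4f}, "
          f"{policy.n_treated}/{len(validation)} treated")

    y_val = enc_val.outcome
    costs_val = np.array([v.readmit_cost for v in validation])
    ev_cfg = cfg["evaluate"]
    for mode in ("observed", "expected"):
        table = table4_report(p_val, p_lace_val, y_val, costs_val,
                              cost_values=ev_cfg["cost_values"],
                              efficacy_values=ev_cfg["efficacy_values"],
                              C=dparams.readmission_cost_C, mode=mode)
        table.to_csv(out / f"policy_comparison_{mode}.csv", index=False)
    stamp("evaluate: policy comparison tables written")

    sw_cfg = cfg["sweep"]
    grid = sensitivity_grid(p_val, p_lace_val, y_val, costs_val,
                            cost_axis=_axis(sw_cfg["cost_axis"]),
                            efficacy_axis=_axis(sw_cfg["efficacy_axis"]),
                            C=dparams.readmission_cost_C,
                            mode=sw_cfg.get("mode", "expected"))
    grid.to_long_dataframe().to_csv(out / "sensitivity.csv", index=False)
    stamp("sweep: sensitivity surfaces written")

    import sklearn

    summary = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "versions": {"readmit": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "sklearn": sklearn.__version__},
        "n_visits": len(cohort),
        "n_eligible": len(eligible),
        "n_derivation": len(derivation),
        "n_validation": len(validation),
        "exclusions": excl_log,
        "lambda": model.lambda_,
        "selected_count": model.selected_count,
        "cv_auc_mean": model.cv_auc_mean,
        "cv_auc_se": model.cv_auc_se,
        "validation_auc_classifier": auc_val,
        "validation_auc_lace": auc_lace,
        "readmission_cost_C": dparams.readmission_cost_C,
        "p_star": policy.threshold_p_star,
        "n_treated": policy.n_treated,
        "runtime_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    stamp("done")
    return summary
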