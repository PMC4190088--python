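"""L1-penalized logistic readmission classifier and its evaluation.

The classifier minimizes (1/n)·Σ log-loss + λ‖β‖₁ with an unpenalized
intercept; λ is chosen from a grid to maximize mean out-of-fold AUC under
seeded, outcome-stratified k-fold cross-validation. Evaluation utilities
cover discrimination (Mann–Whitney AUC), calibration by risk group
(tertiles by default), Platt-style score recalibration, and risk-group
reclassification between two scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, ModelFitError, UndefinedAUCError
from .prep import EncodedCohort

logger = logging.getLogger(__name__)

__all__ = [
    "RiskModel",
    "RiskGroups",
    "ReclassificationMatrix",
    "fit_lasso_logistic",
    "predict_risk",
    "compute_auc",
    "calibrate_risk_groups",
    "platt_recalibrate",
    "reclassification_matrix",
    "DEFAULT_LAMBDA_GRID",
]

GROUP_LABELS = ("low", "moderate", "high")

#: Default λ grid (log-spaced). The strong end zeroes every coefficient at
#: cohort sizes in the hundreds-to-thousands range; the weak end is close to
#: unpenalized and already selects nearly every feature, so going lower only
#: slows the solver without changing the CV choice.
DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-3.5, -1, 7))


@dataclass
class RiskModel:
    """Sparse logistic model: intercept plus named nonzero log-odds coefficients."""

    intercept: float
    coefficients: dict[str, float]
    lambda_: float
    cv_auc_mean: float | None = None
    cv_auc_se: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be nonnegative")
        self.coefficients = {k: float(v) for k, v in self.coefficients.items()
                             if v != 0.0}

    @property
    def selected_count(self) -> int:
        return len(self.coefficients)

    def to_json(self, path=None) -> str:
        payload = {
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_se": self.cv_auc_se,
            "selected_count": self.selected_count,
            "coefficients": self.coefficients,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "RiskModel":
        try:
            payload = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            intercept=payload["intercept"],
            coefficients=payload["coefficients"],
            lambda_=payload["lambda"],
            cv_auc_mean=payload.get("cv_auc_mean"),
            cv_auc_se=payload.get("cv_auc_se"),
        )


def _sklearn_l1(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    """Fit (1/n)Σlogloss + λ‖β‖₁ via scikit-learn's C = 1/(nλ) convention."""
    if lam > 0:
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (lam * len(y)), solver="saga",
            max_iter=20000, tol=1e-5, random_state=0)
    else:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000,
                                 tol=1e-10)
    clf.fit(X, y)
    _polish_intercept(clf, X, y)
    return clf


def _polish_intercept(clf: LogisticRegression, X, y) -> None:
    """Exact 1-D Newton on the unpenalized intercept, coefficients fixed.

    saga converges slowly in the intercept when the penalty is strong; this
    coordinate step is exact for the smooth part of the objective and leaves
    the penalized coordinates untouched.
    """
    eta_x = X @ clf.coef_.ravel()
    b = float(clf.intercept_[0])
    for _ in range(50):
        p = expit(b + eta_x)
        grad = float((p - y).sum())
        hess = float((p * (1 - p)).sum())
        if hess <= 0:
            break
        step = grad / hess
        b -= step
        if abs(step) < 1e-12:
            break
    clf.intercept_[0] = b


def _cv_auc(X, y, lam, k_folds, seed) -> tuple[float, float]:
    """Mean and SE of out-of-fold AUC at one λ; refolds on single-class folds."""
    for attempt in range(3):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=seed + attempt)
        aucs = []
        try:
            for train, test in skf.split(X, y):
                if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                    raise ModelFitError("single-class fold")
                clf = _sklearn_l1(X[train], y[train], lam)
                p = clf.predict_proba(X[test])[:, 1]
                aucs.append(roc_auc_score(y[test], p))
        except ModelFitError:
            continue
        aucs = np.asarray(aucs)
        return float(aucs.mean()), float(aucs.std(ddof=1) / np.sqrt(len(aucs)))
    raise ModelFitError(
        f"could not build {k_folds} stratified folds with both classes "
        "after 3 attempts")


def fit_lasso_logistic(
    cohort: EncodedCohort,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    k_folds: int = 10,
    seed: int = 0,
    one_se_rule: bool = False,
) -> RiskModel:
    """Fit the L1 logistic classifier, selecting λ by out-of-fold AUC.

    Ties in mean AUC break toward the larger (sparser) λ. With
    ``one_se_rule`` the largest λ whose mean AUC is within one standard
    error of the best is chosen instead — a sparser model at statistically
    indistinguishable discrimination.
    """
    X = cohort.features.astype(np.float64)
    y = cohort.outcome
    if len(np.unique(y)) < 2:
        raise ModelFitError("both outcome classes required to fit")
    if k_folds < 2:
        raise ConfigurationError("k_folds must be at least 2")
    lambda_grid = sorted(set(float(l) for l in lambda_grid))
    stats = {lam: _cv_auc(X, y, lam, k_folds, seed) for lam in lambda_grid}
    best_lam = max(stats, key=lambda l: (stats[l][0], l))
    if one_se_rule:
        floor = stats[best_lam][0] - stats[best_lam][1]
        best_lam = max(l for l in lambda_grid if stats[l][0] >= floor)
    mean, se = stats[best_lam]

    clf = _sklearn_l1(X, y, best_lam)
    coefs = clf.coef_.ravel()
    model = RiskModel(
        intercept=float(clf.intercept_[0]),
        coefficients={name: float(c) for name, c in zip(cohort.feature_names, coefs)
                      if c != 0.0},
        lambda_=best_lam,
        cv_auc_mean=mean,
        cv_auc_se=se,
    )
    logger.info("fit_lasso_logistic: lambda=%.3g selected %d/%d features, "
                "cv AUC %.3f±%.3f", best_lam, model.selected_count,
                len(cohort.feature_names), mean, se)
    return model


def out_of_fold_predictions(
    cohort: EncodedCohort, lambda_: float, k_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Out-of-fold probabilities at a fixed λ (stratified, seeded folds).

    In-sample predictions of a model this flexible are optimistic; use these
    for honest recalibration and risk-group cutpoints on the derivation
    cohort.
    """
    X = cohort.features.astype(np.float64)
    y = cohort.outcome
    oof = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        clf = _sklearn_l1(X[train], y[train], lambda_)
        oof[test] = clf.predict_proba(X[test])[:, 1]
    return oof


def predict_risk(model: RiskModel, cohort: EncodedCohort) -> np.ndarray:
    """p_i = logistic(intercept + x_iᵀβ); model features absent from the
    cohort are treated as zero (logged)."""
    index = {name: j for j, name in enumerate(cohort.feature_names)}
    eta = np.full(cohort.n_visits, model.intercept, dtype=float)
    missing = []
    for name, coef in model.coefficients.items():
        j = index.get(name)
        if j is None:
            missing.append(name)
            continue
        eta += coef * cohort.features[:, j]
    if missing:
        logger.warning("predict_risk: %d model features absent from cohort "
                       "(treated as 0): %s ...", len(missing), missing[:5])
    return expit(eta)


def compute_auc(p, y) -> float:
    """Mann–Whitney AUC (ties count one half)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise UndefinedAUCError("both outcome classes required for AUC")
    return float(roc_auc_score(y, np.asarray(p, dtype=float)))


@dataclass
class RiskGroups:
    """Three-way risk grouping with per-group calibration statistics."""

    boundaries: tuple[float, float]
    labels: np.ndarray  # per-visit label in {'low','moderate','high'}
    table: pd.DataFrame = field(repr=False)  # index=group; count, observed_rate,
    #                                          predicted_mean, se

    def __post_init__(self) -> None:
        b1, b2 = self.boundaries
        if not (0.0 < b1 < b2 < 1.0):
            raise ValueError("boundaries must be strictly increasing in (0,1)")


def assign_groups(p, boundaries: tuple[float, float]) -> np.ndarray:
    """low: p ≤ b1; moderate: b1 < p ≤ b2; high: p > b2."""
    p = np.asarray(p, dtype=float)
    b1, b2 = boundaries
    out = np.where(p <= b1, "low", np.where(p <= b2, "moderate", "high"))
    return out.astype(object)


def calibrate_risk_groups(
    p, y, cutpoints: tuple[float, float] | None = None, n_groups: int = 3
) -> RiskGroups:
    """Group visits by predicted risk and compare observed vs predicted rates.

    Default cutpoints are the tertiles of ``p`` (intended to be computed on
    the derivation cohort and reused on validation via explicit
    ``cutpoints``). The per-group SE is the binomial standard error of the
    observed rate at the predicted mean.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if n_groups != 3:
        raise ConfigurationError("three risk groups are supported")
    if len(p) < n_groups:
        raise ConfigurationError("need at least one visit per group")
    if cutpoints is None:
        b1, b2 = np.quantile(p, [1 / 3, 2 / 3])
        if not b1 < b2:
            raise ConfigurationError(
                "degenerate tertiles: predicted risks are (nearly) constant; "
                "pass explicit cutpoints")
        cutpoints = (float(b1), float(b2))
    labels = assign_groups(p, cutpoints)
    rows = []
    for g in GROUP_LABELS:
        mask = labels == g
        n = int(mask.sum())
        if n == 0:
            raise ConfigurationError(f"risk group '{g}' is empty under these cutpoints")
        pred = float(p[mask].mean())
        obs = float(y[mask].mean())
        rows.append({"group": g, "count": n, "observed_rate": obs,
                     "predicted_mean": pred,
                     "se": float(np.sqrt(pred * (1 - pred) / n))})
    table = pd.DataFrame(rows).set_index("group")
    return RiskGroups(boundaries=cutpoints, labels=labels, table=table)


def platt_recalibrate(p, y) -> tuple[float, float]:
    """Fit y ~ logistic(a + b·logit(p)); returns (a, b).

    Standard score recalibration: apply with ``apply_recalibration`` to map
    raw classifier scores onto the outcome scale of a reference cohort.
    """
    z = logit(np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12))
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ModelFitError("both outcome classes required to recalibrate")
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    clf.fit(z.reshape(-1, 1), y)
    return float(clf.intercept_[0]), float(clf.coef_[0, 0])


def apply_recalibration(p, ab: tuple[float, float]) -> np.ndarray:
    a, b = ab
    z = logit(np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12))
    return expit(a + b * z)


@dataclass
class ReclassificationMatrix:
    """Row-percent cross-tabulation of risk groups under two scores."""

    row_percent: pd.DataFrame  # 3x3, rows = source groups, columns = target
    total_reclassified_percent: pd.Series  # per source row: 100 - diagonal

    def to_csv(self, path) -> None:
        out = self.row_percent.copy()
        out["total_reclassified_percent"] = self.total_reclassified_percent
        out.to_csv(path)


def reclassification_matrix(groups_from, groups_to) -> ReclassificationMatrix:
    """Cross-tabulate group labels (e.g. LACE → classifier), row-normalized to %."""
    a = np.asarray(groups_from, dtype=object)
    b = np.asarray(groups_to, dtype=object)
    if len(a) != len(b):
        raise ValueError("labelings must cover the same visits")
    bad = (set(np.unique(a)) | set(np.unique(b))) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(map(str, bad))}")
    counts = pd.crosstab(pd.Categorical(a, categories=GROUP_LABELS),
                         pd.Categorical(b, categories=GROUP_LABELS), dropna=False)
    counts.index.name, counts.columns.name = "from", "to"
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        pct = counts.div(totals, axis=0) * 100.0
    diag = pd.Series(np.diag(pct), index=pct.index)
    return ReclassificationMatrix(row_percent=pct,
                                  total_reclassified_percent=100.0 - diag)
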