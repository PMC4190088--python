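"""Seeded synthetic cohort generator.

Hospital EHR extracts behind published readmission studies are rarely
deposited, so every downstream stage of this pipeline is exercised against
synthetic cohorts with the statistical structure the analysis assumes:

* a sparse binary feature matrix (latent "synthetic diagnosis" codes) in
  which a small subset of features carries true log-odds signal,
* a Bernoulli 30-day readmission outcome whose intercept is tuned by
  bisection to hit a target prevalence,
* right-skewed (lognormal, moment-matched) readmission costs,
* CMS-style exclusion flags drawn independently at configurable rates,
* LACE ingredients (length of stay, acuity, comorbidities, ED visits) that
  are only weakly coupled to the true risk, so a learned classifier can
  outperform the manual score,
* a configurable fraction of readmissions that occur at outside hospitals.

Each record's ground-truth readmission probability is kept on the record
(``true_p``) so recovery tests can compare fitted models to an oracle.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .errors import InterceptTuningError, UndefinedAUCError

__all__ = [
    "CohortSimParams",
    "VisitRecord",
    "generate_cohort",
    "true_auc",
    "DERIVATION_WINDOW",
    "VALIDATION_WINDOW",
    "EXCLUSION_RULES",
    "SYNTH_CODE_PREFIX",
]

#: Date windows of the derivation / validation cohorts (admit-date based).
DERIVATION_WINDOW = (dt.date(2007, 7, 1), dt.date(2009, 6, 30))
VALIDATION_WINDOW = (dt.date(2009, 8, 1), dt.date(2010, 6, 30))

#: CMS-style exclusion rules, in attribution order.
EXCLUSION_RULES = (
    "non_FFS",
    "died_in_hospital",
    "left_AMA",
    "transferred_acute",
    "is_readmission_of_index",
)

#: Latent simulator features surface as diagnosis codes with this prefix.
SYNTH_CODE_PREFIX = "SYN"

_LAB_PANEL = ("BUN", "Glucose", "Hematocrit", "BNP", "Chloride", "Magnesium")
_VARIATION_PANEL = ("TSH", "CO2", "RDW", "MCV")
_MEDICATIONS = ("digoxin", "furosemide", "lisinopril", "carvedilol", "spironolactone")
_MARITAL = ("married", "single", "widowed", "divorced")
_SUPPORT = ("yes", "no", "unknown")

# Charlson-relevant ICD-9 codes the simulator may plant (comorbidity signal
# for LACE); normalized, no dots.
_CHARLSON_CODES = ("4280", "25000", "496", "5853", "410", "1629")


@dataclass
class CohortSimParams:
    """Parameters of the synthetic cohort.

    Defaults emulate the published study conditions: 1,172 eligible visits
    (793 derivation / 379 validation), 3,388 sparse binary features of which
    253 carry signal, ~25% readmission prevalence, mean readmission cost
    $13,679, and outside-hospital readmission fractions of 35.2% / 47.9% in
    the derivation / validation windows.
    """

    n_visits: int = 1172
    derivation_fraction: float = 793 / 1172
    n_features: int = 3388
    n_active_features: int = 253
    coef_scale: float = 0.35
    feature_density: float = 0.02
    base_rate: float = 0.25
    cost_mean: float = 13679.0
    cost_sd: float = 12000.0
    outside_readmit_fraction: tuple[float, float] = (0.352, 0.479)
    exclusion_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    # correlation structure: equicorrelated blocks (0.0 = i.i.d. features)
    feature_correlation: float = 0.0
    block_size: int = 10
    # strength of the coupling between true risk and the LACE ingredients
    lace_signal: float = 0.3
    # observe outside readmissions as non-events (label hiding); default off
    hide_outside_labels: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.outside_readmit_fraction, (int, float)):
            f = float(self.outside_readmit_fraction)
            self.outside_readmit_fraction = (f, f)
        props = {
            "derivation_fraction": self.derivation_fraction,
            "feature_density": self.feature_density,
            "base_rate": self.base_rate,
            "feature_correlation": self.feature_correlation,
            "lace_signal": self.lace_signal,
            **{f"outside_readmit_fraction[{i}]": v
               for i, v in enumerate(self.outside_readmit_fraction)},
            **{f"exclusion_rates[{k}]": v for k, v in self.exclusion_rates.items()},
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if not 0.0 < self.derivation_fraction < 1.0:
            raise ValueError("derivation_fraction must be in (0, 1)")
        if self.n_active_features > self.n_features:
            raise ValueError("n_active_features must not exceed n_features")
        if self.cost_mean <= 0 or self.cost_sd <= 0:
            raise ValueError("cost_mean and cost_sd must be positive")
        unknown = set(self.exclusion_rates) - set(EXCLUSION_RULES)
        if unknown:
            raise ValueError(f"unknown exclusion rules: {sorted(unknown)}")


@dataclass
class VisitRecord:
    """One hospital visit with clinical/administrative fields and outcome."""

    visit_id: str
    patient_id: str
    admit_date: dt.date
    discharge_date: dt.date
    visit_type: str  # inpatient | emergency | outpatient
    admit_source: str  # emergency | referral | transfer
    age: float
    gender: str
    marital_status: str
    family_support: str
    diagnoses: list[str]
    labs: list[tuple[str, float, str]]  # (name, value, low|normal|high)
    lab_variation: list[tuple[str, str]]  # (name, low|not-low)
    medications: list[str]
    er_visits_6mo: int
    admissions_6mo: int
    admissions_12mo: int
    isolated_room: bool
    exclusion_flags: dict[str, bool]
    outcome_R: int
    readmit_cost: float
    readmit_outside: bool
    true_p: float | None = None

    def __post_init__(self) -> None:
        if self.discharge_date < self.admit_date:
            raise ValueError("discharge before admission")
        if self.outcome_R not in (0, 1):
            raise ValueError("outcome_R must be 0 or 1")
        if self.readmit_cost < 0:
            raise ValueError("readmit_cost must be nonnegative")
        if self.readmit_cost > 0 and self.outcome_R != 1:
            raise ValueError("positive readmit_cost requires outcome_R = 1")
        for name in ("er_visits_6mo", "admissions_6mo", "admissions_12mo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def length_of_stay(self) -> int:
        return (self.discharge_date - self.admit_date).days

    def synthetic_codes(self) -> list[int]:
        """Indices of latent simulator features present on this visit."""
        pre = SYNTH_CODE_PREFIX
        return [int(c[len(pre):]) for c in self.diagnoses if c.startswith(pre)]


def synth_code(index: int) -> str:
    """Diagnosis-code spelling of latent feature ``index``."""
    return f"{SYNTH_CODE_PREFIX}{index:04d}"


def _draw_features(rng: np.random.Generator, p: CohortSimParams) -> np.ndarray:
    """Binary feature matrix; i.i.d. or equicorrelated-block Bernoulli."""
    n, m = p.n_visits, p.n_features
    if p.feature_correlation <= 0.0:
        return (rng.random((n, m)) < p.feature_density).astype(np.uint8)
    # Gaussian copula with equicorrelated blocks, thresholded at the
    # feature_density quantile.
    rho = p.feature_correlation
    z = np.empty((n, m))
    for start in range(0, m, p.block_size):
        stop = min(start + p.block_size, m)
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, stop - start))
        z[:, start:stop] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    from scipy.stats import norm

    return (z < norm.ppf(p.feature_density)).astype(np.uint8)


def _tune_intercept(eta: np.ndarray, base_rate: float, tol: float = 0.005) -> float:
    """Bisection on the intercept so mean(expit(b0 + eta)) hits base_rate."""
    lo, hi = -30.0, 30.0
    if expit(lo + eta).mean() > base_rate or expit(hi + eta).mean() < base_rate:
        raise InterceptTuningError(
            f"target prevalence {base_rate} unreachable for this coefficient draw"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta).mean() < base_rate:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    b0 = 0.5 * (lo + hi)
    if abs(expit(b0 + eta).mean() - base_rate) > tol:
        raise InterceptTuningError("bisection did not converge to base_rate")
    return b0


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched lognormal (mu, sigma): m=ln(μ²/√(μ²+σ²)), s²=ln(1+σ²/μ²)."""
    mu = np.log(mean**2 / np.sqrt(mean**2 + sd**2))
    sigma = np.sqrt(np.log(1.0 + sd**2 / mean**2))
    return float(mu), float(sigma)


def _sample_costs(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    mu, sigma = lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size=n)


def _window_date(rng: np.random.Generator, window: tuple[dt.date, dt.date]) -> dt.date:
    span = (window[1] - window[0]).days
    return window[0] + dt.timedelta(days=int(rng.integers(0, span + 1)))


def generate_cohort(params: CohortSimParams, return_truth: bool = False):
    """Generate a synthetic visit cohort; byte-identical under a fixed seed.

    The first ``round(n_visits * derivation_fraction)`` visits receive admit
    dates in the derivation window, the remainder in the validation window,
    so date-based splitting reproduces the intended cohort sizes exactly.

    With ``return_truth`` also returns the planted model as a dict with the
    coefficient vector (``beta``, indexed like the latent features), the
    active indices and the tuned intercept — for recovery tests only.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    X = _draw_features(rng, p)
    beta = np.zeros(p.n_features)
    if p.n_active_features > 0:
        active = rng.choice(p.n_features, size=p.n_active_features, replace=False)
        beta[active] = rng.normal(0.0, p.coef_scale, size=p.n_active_features)
    eta = X @ beta
    b0 = _tune_intercept(eta, p.base_rate)
    true_p = expit(b0 + eta)
    y = (rng.random(p.n_visits) < true_p).astype(int)

    costs = np.zeros(p.n_visits)
    readmitted = np.flatnonzero(y)
    costs[readmitted] = _sample_costs(rng, readmitted.size, p.cost_mean, p.cost_sd)

    # risk coupling for the LACE ingredients: standardized linear predictor
    s = (eta - eta.mean()) / (eta.std() + 1e-12)
    g = p.lace_signal * s
    los = 1 + rng.poisson(3.0 * np.exp(0.3 * g))
    er6 = rng.poisson(0.8 * np.exp(0.5 * g))
    adm6 = rng.poisson(0.5 * np.exp(0.3 * g))
    adm12 = adm6 + rng.poisson(0.4, size=p.n_visits)
    emergent = rng.random(p.n_visits) < expit(-0.2 + g)
    charlson_hits = rng.random((p.n_visits, len(_CHARLSON_CODES))) < expit(-2.0 + g)[:, None]

    n_der = int(round(p.n_visits * p.derivation_fraction))
    rates = {r: p.exclusion_rates.get(r, 0.0) for r in EXCLUSION_RULES}
    flags = {r: rng.random(p.n_visits) < rate for r, rate in rates.items()}

    out_frac = np.where(np.arange(p.n_visits) < n_der,
                        p.outside_readmit_fraction[0], p.outside_readmit_fraction[1])
    outside = (rng.random(p.n_visits) < out_frac) & (y == 1)

    ages = np.clip(rng.normal(76.0, 10.0, p.n_visits), 30.0, 100.0)
    genders = rng.choice(["F", "M"], p.n_visits)
    marital = rng.choice(_MARITAL, p.n_visits)
    support = rng.choice(_SUPPORT, p.n_visits)
    isolated = rng.random(p.n_visits) < 0.05
    meds_mask = rng.random((p.n_visits, len(_MEDICATIONS))) < 0.3

    # lab values around typical adult mid-range, mildly shifted with risk
    lab_mid = {"BUN": 14.0, "Glucose": 100.0, "Hematocrit": 42.0,
               "BNP": 60.0, "Chloride": 101.0, "Magnesium": 2.0}
    lab_sd = {"BUN": 6.0, "Glucose": 30.0, "Hematocrit": 5.0,
              "BNP": 80.0, "Chloride": 4.0, "Magnesium": 0.35}
    lab_vals = {
        name: lab_mid[name] + lab_sd[name] * (rng.standard_normal(p.n_visits) + 0.3 * g)
        for name in _LAB_PANEL
    }
    lab_vals["BNP"] = np.abs(lab_vals["BNP"])
    var_low = rng.random((p.n_visits, len(_VARIATION_PANEL))) < 0.5

    from .prep import default_encoding_spec  # local import: avoid cycle at module load

    bins = default_encoding_spec(icd9_prefixes=[]).lab_bins

    def lab_flag(name: str, value: float) -> str:
        lo, hi = bins[name]
        return "low" if value < lo else ("high" if value > hi else "normal")

    records: list[VisitRecord] = []
    for i in range(p.n_visits):
        window = DERIVATION_WINDOW if i < n_der else VALIDATION_WINDOW
        admit = _window_date(rng, window)
        codes = [synth_code(j) for j in np.flatnonzero(X[i])]
        codes += [c for j, c in enumerate(_CHARLSON_CODES) if charlson_hits[i, j]]
        y_obs, cost_obs = int(y[i]), float(costs[i])
        if p.hide_outside_labels and outside[i]:
            y_obs, cost_obs = 0, 0.0
        records.append(VisitRecord(
            visit_id=f"V{i:05d}",
            patient_id=f"P{i:05d}",
            admit_date=admit,
            discharge_date=admit + dt.timedelta(days=int(los[i])),
            visit_type="inpatient",
            admit_source="emergency" if emergent[i] else "referral",
            age=round(float(ages[i]), 1),
            gender=str(genders[i]),
            marital_status=str(marital[i]),
            family_support=str(support[i]),
            diagnoses=codes,
            labs=[(name, round(float(lab_vals[name][i]), 2),
                   lab_flag(name, float(lab_vals[name][i]))) for name in _LAB_PANEL],
            lab_variation=[(name, "low" if var_low[i, j] else "not-low")
                           for j, name in enumerate(_VARIATION_PANEL)],
            medications=[m for j, m in enumerate(_MEDICATIONS) if meds_mask[i, j]],
            er_visits_6mo=int(er6[i]),
            admissions_6mo=int(adm6[i]),
            admissions_12mo=int(adm12[i]),
            isolated_room=bool(isolated[i]),
            exclusion_flags={r: bool(flags[r][i]) for r in EXCLUSION_RULES},
            outcome_R=y_obs,
            readmit_cost=cost_obs,
            readmit_outside=bool(outside[i]),
            true_p=float(true_p[i]),
        ))
    if return_truth:
        truth = {"beta": beta, "intercept": b0,
                 "active_indices": sorted(int(j) for j in np.flatnonzero(beta))}
        return records, truth
    return records


def true_auc(cohort: list[VisitRecord]) -> float:
    """AUC of the simulator's ground-truth probabilities against outcomes.

    Mann–Whitney interpretation: the probability that a readmitted visit's
    ``true_p`` exceeds a non-readmitted one's, ties counting one half. This
    is the discrimination ceiling any fitted model can approach.
    """
    if any(v.true_p is None for v in cohort):
        raise ValueError("true_auc requires simulator ground truth on every record")
    y = np.array([v.outcome_R for v in cohort])
    if len(np.unique(y)) < 2:
        raise UndefinedAUCError("both outcome classes required for AUC")
    return float(roc_auc_score(y, [v.true_p for v in cohort]))


def visit_to_dict(v: VisitRecord) -> dict:
    """Plain-dict form of a visit (dates ISO-8601); used by the writers."""
    d = dataclasses.asdict(v)
    d["admit_date"] = v.admit_date.isoformat()
    d["discharge_date"] = v.discharge_date.isoformat()
    return d
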