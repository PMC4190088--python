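"""Cohort eligibility, outcome definition, date splitting and binary encoding.

Mirrors the CMS readmission-measure conventions: visits are dropped by five
eligibility rules (fee-for-service enrollment, in-hospital death, leaving
against medical advice, transfer to another acute facility, and the rule
that an admission cannot be both an index admission and a readmission), the
outcome is any all-cause inpatient readmission within 30 days of discharge,
and train/test cohorts are defined by admit-date windows.

Feature encoding turns each visit into a row of binary indicators: one
column per (lab, bin), per low-variation lab, per engagement rule, per
ICD-9 prefix in the diagnosis history, per medication on/off, and per
demographic category. Columns are sorted by name so the matrix layout is
deterministic; nothing derived from the outcome or its cost ever enters.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CohortDataError, ConfigurationError
from .simulate import EXCLUSION_RULES, VisitRecord, synth_code

logger = logging.getLogger(__name__)

__all__ = [
    "EncodedCohort",
    "EncodingSpec",
    "apply_cms_exclusions",
    "define_outcome",
    "split_cohorts",
    "encode_features",
    "default_encoding_spec",
    "simulation_encoding_spec",
]

#: Standard adult reference ranges (normal low, normal high) per lab.
DEFAULT_LAB_BINS: dict[str, tuple[float, float]] = {
    "BUN": (7.0, 20.0),
    "Glucose": (70.0, 140.0),
    "Hematocrit": (36.0, 50.0),
    "BNP": (0.0, 100.0),
    "Chloride": (96.0, 106.0),
    "Magnesium": (1.7, 2.2),
}

DEFAULT_VARIATION_THRESHOLDS: dict[str, float] = {
    "TSH": 0.5, "CO2": 1.0, "RDW": 0.5, "MCV": 1.0,
}

#: Named threshold rules on utilization counters: (attribute, op, threshold).
DEFAULT_ENGAGEMENT_RULES: dict[str, tuple[str, str, float]] = {
    "admitted_past_6mo": ("admissions_6mo", ">=", 1),
    "er_visits_6mo_lt2": ("er_visits_6mo", "<", 2),
    "admissions_12mo_ge2": ("admissions_12mo", ">=", 2),
    "isolated_room": ("isolated_room", "==", True),
}

DEFAULT_ICD9_PREFIXES = ["305", "496", "578", "425", "428", "250", "410", "584"]
DEFAULT_MEDICATIONS = ["digoxin", "furosemide", "lisinopril", "carvedilol", "spironolactone"]
DEFAULT_DEMOGRAPHICS: dict[str, list[str]] = {
    "gender": ["F", "M"],
    "marital_status": ["married", "single", "widowed", "divorced"],
    "family_support": ["yes", "no", "unknown"],
}

_LAB_BIN_NAMES = ("low", "normal", "high")
_FLAG_ALIASES = {"elevated": "high", "high/elevated": "high"}


@dataclass
class EncodedCohort:
    """Binary design matrix with outcome vector and deterministic column names."""

    features: np.ndarray  # (n_visits, n_features) uint8
    outcome: np.ndarray  # (n_visits,) int
    feature_names: list[str]
    visit_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.uint8)
        self.outcome = np.asarray(self.outcome, dtype=int)
        n, m = self.features.shape
        if not (len(self.outcome) == len(self.visit_ids) == n):
            raise ValueError("inconsistent cohort dimensions")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length must match matrix width")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature_names must be unique")
        if not np.isin(self.features, (0, 1)).all():
            raise ValueError("feature matrix must be binary")

    @property
    def n_visits(self) -> int:
        return self.features.shape[0]


@dataclass
class EncodingSpec:
    """Configuration of the binary visit encoding."""

    lab_bins: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LAB_BINS))
    variation_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIATION_THRESHOLDS))
    engagement_rules: dict[str, tuple[str, str, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENGAGEMENT_RULES))
    icd9_prefixes: list[str] = field(default_factory=lambda: list(DEFAULT_ICD9_PREFIXES))
    medication_list: list[str] = field(default_factory=lambda: list(DEFAULT_MEDICATIONS))
    demographics: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_DEMOGRAPHICS.items()})

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.lab_bins.items():
            if not lo < hi:
                raise ConfigurationError(f"lab {name}: bins must be ordered (lo < hi)")
        if any(not p for p in self.icd9_prefixes):
            raise ConfigurationError("ICD-9 prefixes must be nonempty strings")

    def column_names(self) -> list[str]:
        cols = []
        for lab in self.lab_bins:
            cols += [f"lab:{lab}:{b}" for b in _LAB_BIN_NAMES]
        cols += [f"labvar:{lab}:low" for lab in self.variation_thresholds]
        cols += [f"engage:{rule}" for rule in self.engagement_rules]
        cols += [f"diag:{normalize_icd9(p)}" for p in self.icd9_prefixes]
        for med in self.medication_list:
            cols += [f"med:{med}:on", f"med:{med}:off"]
        for fld, cats in self.demographics.items():
            cols += [f"demo:{fld}:{c}" for c in cats]
        return sorted(cols)


def normalize_icd9(code: str) -> str:
    """Strip dots and whitespace: '305.1 ' -> '3051'; wildcard 'x' suffixes drop."""
    code = code.strip().replace(".", "")
    while code.lower().endswith("x"):
        code = code[:-1]
    return code


def default_encoding_spec(**overrides) -> EncodingSpec:
    """The shipped default spec; keyword overrides replace whole fields."""
    return EncodingSpec(**overrides)


def simulation_encoding_spec(n_features: int, **overrides) -> EncodingSpec:
    """Encoding spec whose diagnosis prefixes cover the simulator's latent codes.

    Encoding a simulated cohort with this spec reconstructs the latent binary
    feature matrix exactly (as ``diag:SYN*`` columns) alongside the ordinary
    clinical columns, so planted signal is recoverable end-to-end.
    """
    prefixes = list(DEFAULT_ICD9_PREFIXES) + [synth_code(j) for j in range(n_features)]
    overrides.setdefault("icd9_prefixes", prefixes)
    return EncodingSpec(**overrides)


def apply_cms_exclusions(
    visits: list[VisitRecord],
) -> tuple[list[VisitRecord], dict[str, int]]:
    """Retain visits with all five exclusion flags false.

    Each excluded visit is attributed to the first rule (in the canonical
    order) whose flag is set, so the log counts are stable and
    ``len(eligible) + sum(counts) == len(visits)``.
    """
    log = {rule: 0 for rule in EXCLUSION_RULES}
    eligible = []
    for v in visits:
        for rule in EXCLUSION_RULES:
            if v.exclusion_flags.get(rule, False):
                log[rule] += 1
                break
        else:
            eligible.append(v)
    return eligible, log


def define_outcome(index_visit: VisitRecord, all_visits: list[VisitRecord]) -> int:
    """1 iff the same patient has an inpatient admission within 30 days of discharge.

    The window is half-open on the left and closed on the right: an admission
    exactly 30 days after discharge counts; an admission on the discharge day
    itself does not.
    """
    d0 = index_visit.discharge_date
    d1 = d0 + dt.timedelta(days=30)
    hit = False
    for v in all_visits:
        if v.patient_id != index_visit.patient_id or v.visit_id == index_visit.visit_id:
            continue
        if v.admit_date < index_visit.discharge_date and v.discharge_date > index_visit.admit_date:
            raise CohortDataError(
                f"overlapping stays for patient {v.patient_id}: "
                f"{index_visit.visit_id} and {v.visit_id}"
            )
        if v.visit_type == "inpatient" and d0 < v.admit_date <= d1:
            hit = True
    return int(hit)


def split_cohorts(
    visits: list[VisitRecord],
    derivation_window: tuple[dt.date, dt.date],
    validation_window: tuple[dt.date, dt.date],
) -> tuple[list[VisitRecord], list[VisitRecord]]:
    """Assign visits to derivation/validation by admit date; drop the rest."""
    (d0, d1), (v0, v1) = derivation_window, validation_window
    if d0 > d1 or v0 > v1:
        raise ConfigurationError("window start must not exceed window end")
    if d0 <= v1 and v0 <= d1:
        raise ConfigurationError("derivation and validation windows overlap")
    derivation = [v for v in visits if d0 <= v.admit_date <= d1]
    validation = [v for v in visits if v0 <= v.admit_date <= v1]
    dropped = len(visits) - len(derivation) - len(validation)
    if dropped:
        logger.info("split_cohorts: dropped %d visits outside both windows", dropped)
    return derivation, validation


def _engagement_value(visit: VisitRecord, attribute: str):
    return getattr(visit, attribute)


def _rule_fires(visit: VisitRecord, rule: tuple[str, str, float]) -> bool:
    attribute, op, threshold = rule
    value = _engagement_value(visit, attribute)
    if op == "<":
        return value < threshold
    if op == "<=":
        return value <= threshold
    if op == ">":
        return value > threshold
    if op == ">=":
        return value >= threshold
    if op == "==":
        return value == threshold
    raise ConfigurationError(f"unknown engagement operator {op!r}")


def encode_features(visits: list[VisitRecord], spec: EncodingSpec) -> EncodedCohort:
    """Encode visits into the deterministic binary design matrix.

    Labs not covered by ``spec.lab_bins`` are logged and skipped. Lab bins use
    the flag recorded on the visit (``elevated`` is an alias for ``high``), so
    for every lab present exactly one of its three bin columns is 1.
    """
    names = spec.column_names()
    col = {name: j for j, name in enumerate(names)}
    X = np.zeros((len(visits), len(names)), dtype=np.uint8)
    unknown_labs: set[str] = set()

    prefixes = [normalize_icd9(p) for p in spec.icd9_prefixes]
    for i, v in enumerate(visits):
        for lab, _value, flag in v.labs:
            if lab not in spec.lab_bins:
                unknown_labs.add(lab)
                continue
            flag = _FLAG_ALIASES.get(flag, flag)
            X[i, col[f"lab:{lab}:{flag}"]] = 1
        for lab, flag in v.lab_variation:
            if lab in spec.variation_thresholds and flag == "low":
                X[i, col[f"labvar:{lab}:low"]] = 1
        for rule_name, rule in spec.engagement_rules.items():
            if _rule_fires(v, rule):
                X[i, col[f"engage:{rule_name}"]] = 1
        # all prefixes of every normalized history code, for O(1) prefix tests
        code_prefixes = {c[:k] for c in map(normalize_icd9, v.diagnoses)
                         for k in range(1, len(c) + 1)}
        for pref in prefixes:
            if pref in code_prefixes:
                X[i, col[f"diag:{pref}"]] = 1
        meds = set(v.medications)
        for med in spec.medication_list:
            X[i, col[f"med:{med}:on" if med in meds else f"med:{med}:off"]] = 1
        for fld, cats in spec.demographics.items():
            value = getattr(v, fld)
            if value in cats:
                X[i, col[f"demo:{fld}:{value}"]] = 1
    if unknown_labs:
        logger.warning("encode_features: skipped labs not in spec: %s",
                       sorted(unknown_labs))
    return EncodedCohort(
        features=X,
        outcome=np.array([v.outcome_R for v in visits], dtype=int),
        feature_names=names,
        visit_ids=[v.visit_id for v in visits],
    )
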