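"""LACE readmission score: Length of stay, Acuity, Comorbidity, ED visits.

LACE is the manual bedside comparator for the learned classifier. Points:

* L — length of stay in days: <1→0, 1→1, 2→2, 3→3, 4–6→4, 7–13→5, ≥14→7
* A — acute/emergent admission: 3, else 0
* C — Charlson comorbidity index: 0→0, 1→1, 2→2, 3→3, ≥4→5
* E — emergency-department visits in the prior 6 months, capped at 4

Total range 0–19. The Charlson index is computed from the ICD-9 diagnosis
history with a shipped, configurable prefix→(condition, weight) map
(Deyo-style adaptation); a condition counts once however many of its codes
appear. Calibration of the integer score onto the probability scale is a
univariate logistic regression fitted on derivation data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .errors import ModelFitError
from .prep import normalize_icd9
from .simulate import VisitRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LaceComponents",
    "LaceCalibration",
    "lace_score",
    "calibrate_lace",
    "charlson_index",
    "DEFAULT_CHARLSON_MAP",
]

#: ICD-9 prefix (normalized, no dots) → (condition, Charlson weight).
#: Deyo-style adaptation; configurable, not a claim of completeness.
DEFAULT_CHARLSON_MAP: dict[str, tuple[str, int]] = {
    "410": ("myocardial_infarction", 1),
    "412": ("myocardial_infarction", 1),
    "428": ("congestive_heart_failure", 1),
    "441": ("peripheral_vascular_disease", 1),
    "4439": ("peripheral_vascular_disease", 1),
    "430": ("cerebrovascular_disease", 1),
    "431": ("cerebrovascular_disease", 1),
    "432": ("cerebrovascular_disease", 1),
    "433": ("cerebrovascular_disease", 1),
    "434": ("cerebrovascular_disease", 1),
    "435": ("cerebrovascular_disease", 1),
    "436": ("cerebrovascular_disease", 1),
    "437": ("cerebrovascular_disease", 1),
    "438": ("cerebrovascular_disease", 1),
    "290": ("dementia", 1),
    "490": ("chronic_pulmonary_disease", 1),
    "491": ("chronic_pulmonary_disease", 1),
    "492": ("chronic_pulmonary_disease", 1),
    "493": ("chronic_pulmonary_disease", 1),
    "494": ("chronic_pulmonary_disease", 1),
    "495": ("chronic_pulmonary_disease", 1),
    "496": ("chronic_pulmonary_disease", 1),
    "7100": ("rheumatic_disease", 1),
    "7101": ("rheumatic_disease", 1),
    "7104": ("rheumatic_disease", 1),
    "714": ("rheumatic_disease", 1),
    "531": ("peptic_ulcer_disease", 1),
    "532": ("peptic_ulcer_disease", 1),
    "533": ("peptic_ulcer_disease", 1),
    "534": ("peptic_ulcer_disease", 1),
    "5712": ("mild_liver_disease", 1),
    "5714": ("mild_liver_disease", 1),
    "5715": ("mild_liver_disease", 1),
    "5716": ("mild_liver_disease", 1),
    "2500": ("diabetes", 1),
    "2501": ("diabetes", 1),
    "2502": ("diabetes", 1),
    "2503": ("diabetes", 1),
    "2507": ("diabetes", 1),
    "2504": ("diabetes_with_complications", 2),
    "2505": ("diabetes_with_complications", 2),
    "2506": ("diabetes_with_complications", 2),
    "342": ("hemiplegia", 2),
    "3441": ("hemiplegia", 2),
    "582": ("renal_disease", 2),
    "583": ("renal_disease", 2),
    "585": ("renal_disease", 2),
    "586": ("renal_disease", 2),
    "588": ("renal_disease", 2),
    **{str(c): ("malignancy", 2) for c in list(range(140, 173)) +
       list(range(174, 196)) + list(range(200, 209))},
    "4560": ("severe_liver_disease", 3),
    "4561": ("severe_liver_disease", 3),
    "4562": ("severe_liver_disease", 3),
    "5722": ("severe_liver_disease", 3),
    "5723": ("severe_liver_disease", 3),
    "5724": ("severe_liver_disease", 3),
    **{str(c): ("metastatic_cancer", 6) for c in range(196, 200)},
    "042": ("hiv", 6),
    "043": ("hiv", 6),
    "044": ("hiv", 6),
}


@dataclass
class LaceComponents:
    L_points: int
    A_points: int
    C_points: int
    E_points: int

    def __post_init__(self) -> None:
        if not 0 <= self.L_points <= 7:
            raise ValueError("L points out of range")
        if self.A_points not in (0, 3):
            raise ValueError("A points must be 0 or 3")
        if not 0 <= self.C_points <= 5:
            raise ValueError("C points out of range")
        if not 0 <= self.E_points <= 4:
            raise ValueError("E points out of range")

    @property
    def total(self) -> int:
        return self.L_points + self.A_points + self.C_points + self.E_points


def charlson_index(diagnoses, code_map: dict[str, tuple[str, int]] | None = None) -> int:
    """Weighted comorbidity count; each condition contributes its weight once."""
    code_map = DEFAULT_CHARLSON_MAP if code_map is None else code_map
    codes = [normalize_icd9(c) for c in diagnoses]
    hit: dict[str, int] = {}
    for prefix, (condition, weight) in code_map.items():
        if any(c.startswith(prefix) for c in codes):
            hit[condition] = max(hit.get(condition, 0), weight)
    return sum(hit.values())


def _los_points(days: int) -> int:
    if days < 1:
        return 0
    if days <= 3:
        return days
    if days <= 6:
        return 4
    if days <= 13:
        return 5
    return 7


def _charlson_points(index: int) -> int:
    return index if index < 4 else 5


def lace_score(
    visit: VisitRecord,
    charlson_map: dict[str, tuple[str, int]] | None = None,
    on_missing: str = "impute",
) -> LaceComponents:
    """LACE points for one visit.

    ``on_missing='impute'`` scores a missing component as 0 with a warning;
    ``'error'`` raises instead.
    """
    missing = [name for name, value in [
        ("length_of_stay", visit.discharge_date),
        ("admit_source", visit.admit_source),
        ("er_visits_6mo", visit.er_visits_6mo),
    ] if value is None]
    if missing:
        if on_missing == "error":
            raise ValueError(f"missing LACE components {missing} on {visit.visit_id}")
        warnings.warn(f"imputing 0 points for missing {missing} on {visit.visit_id}")
    emergent = visit.admit_source == "emergency" or visit.visit_type == "emergency"
    return LaceComponents(
        L_points=_los_points(visit.length_of_stay),
        A_points=3 if emergent else 0,
        C_points=_charlson_points(charlson_index(visit.diagnoses, charlson_map)),
        E_points=min(int(visit.er_visits_6mo or 0), 4),
    )


@dataclass
class LaceCalibration:
    """Monotone score→probability mapping from a univariate logistic fit."""

    intercept: float
    slope: float

    def predict(self, scores) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(scores, dtype=float))


def calibrate_lace(scores, y) -> LaceCalibration:
    """Logistic regression of the outcome on the integer LACE total.

    A negative fitted slope (score anti-predictive in this cohort) keeps the
    fit but emits a warning, since the mapping is then decreasing.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if np.unique(scores).size < 2:
        raise ModelFitError("constant LACE scores cannot be calibrated")
    if len(np.unique(y)) < 2:
        raise ModelFitError("both outcome classes required to calibrate")
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    clf.fit(scores.reshape(-1, 1), y)
    slope = float(clf.coef_[0, 0])
    if slope < 0:
        warnings.warn("calibrated LACE slope is negative; mapping is decreasing")
    return LaceCalibration(intercept=float(clf.intercept_[0]), slope=slope)
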