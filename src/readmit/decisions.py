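"""Expected-utility model for allocating a post-discharge intervention.

For a patient with readmission probability p, not intervening costs p·C in
expectation (C = expected cost of one readmission); intervening costs
c + (1−α)·p·C, where c is the per-patient intervention cost and α its
efficacy (fractional reduction of the readmission probability). The two
expected costs cross at the threshold probability

    p* = c / (α·C),

and the policy that minimizes total expected cost treats exactly the
patients with p > p*. Three simplifying assumptions underlie this model:
per-patient intervention cost, readmission cost, and efficacy are each the
same for everyone a priori. Indifference at p = p* is broken toward *not*
intervening, to avoid spending when there is nothing to gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "DecisionParams",
    "AllocationPolicy",
    "expected_cost_no_intervention",
    "expected_cost_intervention",
    "intervention_threshold",
    "allocate",
    "uniform_policy",
]


@dataclass(frozen=True)
class DecisionParams:
    """Intervention cost c (USD/patient), efficacy α in (0,1], and expected
    readmission cost C (USD)."""

    intervention_cost_c: float
    efficacy_alpha: float
    readmission_cost_C: float

    def __post_init__(self) -> None:
        if self.intervention_cost_c < 0:
            raise ConfigurationError("intervention cost must be nonnegative")
        if not 0.0 < self.efficacy_alpha <= 1.0:
            raise ConfigurationError("efficacy must lie in (0, 1]")
        if self.readmission_cost_C <= 0:
            raise ConfigurationError("readmission cost must be positive")


@dataclass
class AllocationPolicy:
    """A per-visit treat/don't-treat vector with its provenance label."""

    label: str  # patient_specific | all | none | lace_specific
    intervene: np.ndarray  # bool per visit
    threshold_p_star: float | None = None

    def __post_init__(self) -> None:
        self.intervene = np.asarray(self.intervene, dtype=bool)
        if self.label not in ("patient_specific", "all", "none", "lace_specific"):
            raise ValueError(f"unknown policy label {self.label!r}")

    @property
    def n_treated(self) -> int:
        return int(self.intervene.sum())


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def expected_cost_no_intervention(p, params: DecisionParams):
    """p·C — the full readmission cost weighted by its likelihood."""
    return _check_p(p) * params.readmission_cost_C


def expected_cost_intervention(p, params: DecisionParams):
    """c + (1−α)·p·C — pay for the program, keep the residual risk."""
    return (params.intervention_cost_c
            + (1.0 - params.efficacy_alpha) * _check_p(p) * params.readmission_cost_C)


def intervention_threshold(params: DecisionParams) -> float:
    """p* = c/(α·C), where the two expected-cost lines cross.

    Returned unclipped: a value ≥ 1 means the intervention is never
    warranted; 0 (c = 0) means it is warranted for every p > 0.
    """
    denom = params.efficacy_alpha * params.readmission_cost_C
    if denom <= 0:
        raise ConfigurationError("efficacy·readmission_cost must be positive")
    return params.intervention_cost_c / denom


def allocate(p, params: DecisionParams, label: str = "patient_specific") -> AllocationPolicy:
    """Treat exactly the visits with p > p* (strict: ties go untreated)."""
    p = _check_p(p)
    p_star = intervention_threshold(params)
    return AllocationPolicy(label=label, intervene=p > p_star,
                            threshold_p_star=p_star)


def uniform_policy(n: int, treat_all: bool) -> AllocationPolicy:
    """The two uniform comparators: intervene on everyone, or on no one."""
    return AllocationPolicy(label="all" if treat_all else "none",
                            intervene=np.full(n, treat_all, dtype=bool))
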