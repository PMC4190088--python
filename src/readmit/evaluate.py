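"""Policy value: savings, readmissions prevented, and cost×efficacy sweeps.

A policy is scored either against what actually happened ("observed" mode:
realized outcomes and per-visit readmission costs) or against a probability
model ("expected" mode: p_i·C replaces y_i·cost_i). Savings are reported as
a percentage of total readmission costs, readmissions prevented as a
percentage of (expected) readmissions. For the apply-to-all policy in
observed mode the savings reduce in closed form to 100·(α − c·N/T).

The sensitivity sweep recomputes the threshold allocation cell-by-cell over
a cost × efficacy grid and reports three surfaces: patient-specific savings
vs doing nothing, vs the best uniform policy, and vs a LACE-guided
threshold policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decisions import AllocationPolicy, DecisionParams, allocate, uniform_policy
from .errors import ConfigurationError

__all__ = [
    "PolicyOutcome",
    "SensitivityGrid",
    "evaluate_policy",
    "best_uniform",
    "sensitivity_grid",
    "table4_report",
]


@dataclass
class PolicyOutcome:
    policy_label: str
    n_treated: int
    savings_percent: float
    readmissions_prevented_percent: float
    mode: str  # observed | expected


def _totals(y, costs, p, C, mode):
    """(per-visit readmission cost, per-visit readmission weight, their sums)."""
    if mode == "observed":
        if y is None or costs is None:
            raise ConfigurationError("observed mode needs outcomes and costs")
        w = np.asarray(y, dtype=float)
        v = w * np.asarray(costs, dtype=float)
    elif mode == "expected":
        if p is None:
            raise ConfigurationError("expected mode needs a probability vector")
        w = np.asarray(p, dtype=float)
        v = w * C
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    T = float(v.sum())
    if T <= 0:
        raise ConfigurationError("total readmission cost must be positive")
    return v, w, T


def evaluate_policy(
    policy: AllocationPolicy,
    params: DecisionParams,
    y=None,
    costs=None,
    p=None,
    mode: str = "observed",
) -> PolicyOutcome:
    """Savings% and prevented% of one allocation.

    observed:  savings% = 100·[α·Σ_treated y_i·cost_i − c·n_treated] / Σ y_i·cost_i
               prevented% = 100·α·Σ_treated y_i / Σ y_i
    expected:  y_i·cost_i ↦ p_i·C and y_i ↦ p_i throughout.
    """
    v, w, T = _totals(y, costs, p, params.readmission_cost_C, mode)
    treat = policy.intervene
    if len(treat) != len(v):
        raise ValueError("policy length does not match cohort size")
    alpha, c = params.efficacy_alpha, params.intervention_cost_c
    saved = alpha * float(v[treat].sum()) - c * policy.n_treated
    prevented = alpha * float(w[treat].sum()) / float(w.sum())
    return PolicyOutcome(
        policy_label=policy.label,
        n_treated=policy.n_treated,
        savings_percent=100.0 * saved / T,
        readmissions_prevented_percent=100.0 * prevented,
        mode=mode,
    )


def best_uniform(params: DecisionParams, y=None, costs=None, p=None,
                 mode: str = "observed") -> PolicyOutcome:
    """The better of apply-to-all and apply-to-none (ties go to none).

    In observed mode the apply-to-all savings equal 100·(α − c·N/T), so the
    best-uniform savings are max(0, 100·(α − c·N/T)).
    """
    n = len(y) if y is not None else len(p)
    out_all = evaluate_policy(uniform_policy(n, True), params, y, costs, p, mode)
    out_none = evaluate_policy(uniform_policy(n, False), params, y, costs, p, mode)
    return out_all if out_all.savings_percent > out_none.savings_percent else out_none


@dataclass
class SensitivityGrid:
    """Savings surfaces over the cost × efficacy grid (rows=cost, cols=efficacy)."""

    cost_axis: np.ndarray
    efficacy_axis: np.ndarray
    vs_none: np.ndarray
    vs_best_uniform: np.ndarray
    vs_lace: np.ndarray | None
    mode: str

    def to_long_dataframe(self) -> pd.DataFrame:
        frames = []
        surfaces = {"vs_none": self.vs_none, "vs_best_uniform": self.vs_best_uniform}
        if self.vs_lace is not None:
            surfaces["vs_lace"] = self.vs_lace
        for name, surf in surfaces.items():
            cc, aa = np.meshgrid(self.cost_axis, self.efficacy_axis, indexing="ij")
            frames.append(pd.DataFrame({
                "cost": cc.ravel(), "efficacy": aa.ravel(),
                "comparison": name, "savings_percent": surf.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    def plot_contours(self, path=None):
        """Render the surfaces as labelled contour maps (one panel each)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        surfaces = [("vs_none", self.vs_none),
                    ("vs_best_uniform", self.vs_best_uniform)]
        if self.vs_lace is not None:
            surfaces.append(("vs_lace", self.vs_lace))
        fig, axes = plt.subplots(1, len(surfaces), figsize=(5 * len(surfaces), 4))
        axes = np.atleast_1d(axes)
        for ax, (name, surf) in zip(axes, surfaces):
            cs = ax.contour(self.efficacy_axis, self.cost_axis, surf, levels=10)
            ax.clabel(cs, fmt="%.0f%%")
            ax.set_xlabel("efficacy α")
            ax.set_ylabel("intervention cost c ($)")
            ax.set_title(f"savings {name.replace('_', ' ')}")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


DEFAULT_COST_AXIS = tuple(np.linspace(0.0, 2500.0, 50))
DEFAULT_EFFICACY_AXIS = tuple(np.linspace(0.05, 0.60, 50))


def sensitivity_grid(
    p_classifier,
    p_lace=None,
    y=None,
    costs=None,
    cost_axis=DEFAULT_COST_AXIS,
    efficacy_axis=DEFAULT_EFFICACY_AXIS,
    C: float = 13679.0,
    mode: str = "observed",
    p_eval=None,
) -> SensitivityGrid:
    """Re-run threshold → allocate → evaluate for every (c, α) cell.

    ``p_classifier`` and ``p_lace`` drive the two patient-specific
    allocations; scoring uses observed outcomes/costs or, in expected mode,
    ``p_eval`` (defaulting to ``p_classifier``) as the probability model for
    *all* policies, so competing allocations are judged on a common scale.
    """
    cost_axis = np.asarray(cost_axis, dtype=float)
    efficacy_axis = np.asarray(efficacy_axis, dtype=float)
    if cost_axis.size == 0 or efficacy_axis.size == 0:
        raise ConfigurationError("grid axes must be nonempty")
    if mode == "expected" and p_eval is None:
        p_eval = p_classifier
    shape = (cost_axis.size, efficacy_axis.size)
    vs_none = np.empty(shape)
    vs_bu = np.empty(shape)
    vs_lace = np.empty(shape) if p_lace is not None else None
    for i, c in enumerate(cost_axis):
        for j, a in enumerate(efficacy_axis):
            params = DecisionParams(c, a, C)
            ps = evaluate_policy(allocate(p_classifier, params), params,
                                 y, costs, p_eval, mode)
            bu = best_uniform(params, y, costs, p_eval, mode)
            vs_none[i, j] = ps.savings_percent
            vs_bu[i, j] = ps.savings_percent - bu.savings_percent
            if vs_lace is not None:
                lc = evaluate_policy(
                    allocate(p_lace, params, label="lace_specific"), params,
                    y, costs, p_eval, mode)
                vs_lace[i, j] = ps.savings_percent - lc.savings_percent
    return SensitivityGrid(cost_axis, efficacy_axis, vs_none, vs_bu, vs_lace, mode)


def table4_report(
    p_classifier,
    p_lace,
    y,
    costs,
    cost_values=(300.0, 800.0, 1300.0, 1800.0),
    efficacy_values=(0.25, 0.35),
    C: float = 13679.0,
    mode: str = "observed",
) -> pd.DataFrame:
    """Policy-comparison table: savings and prevented readmissions per
    (cost, efficacy) cell for the patient-specific (classifier and LACE),
    apply-to-all and best-uniform policies."""
    rows = []
    for c in cost_values:
        for a in efficacy_values:
            params = DecisionParams(c, a, C)
            n = len(y) if mode == "observed" else len(p_classifier)
            ps = evaluate_policy(allocate(p_classifier, params), params,
                                 y, costs, p_classifier, mode)
            lc = evaluate_policy(allocate(p_lace, params, label="lace_specific"),
                                 params, y, costs, p_classifier, mode)
            al = evaluate_policy(uniform_policy(n, True), params,
                                 y, costs, p_classifier, mode)
            bu = best_uniform(params, y, costs, p_classifier, mode)
            rows.append({
                "cost": c, "efficacy": a,
                "savings_classifier_pct": ps.savings_percent,
                "savings_lace_pct": lc.savings_percent,
                "savings_all_pct": al.savings_percent,
                "savings_best_uniform_pct": bu.savings_percent,
                "prevented_classifier_pct": ps.readmissions_prevented_percent,
                "prevented_lace_pct": lc.readmissions_prevented_percent,
                "prevented_best_uniform_pct": bu.readmissions_prevented_percent,
                "n_treated_classifier": ps.n_treated,
            })
    return pd.DataFrame(rows)
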