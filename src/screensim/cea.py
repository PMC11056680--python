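"""Cost-effectiveness engine and deterministic sensitivity analyses.

Every arm is compared with the baseline arm on the cost-effectiveness
plane: the x axis is incremental effectiveness (eligible records saved from
inappropriate exclusion), the y axis incremental cost.  An arm with higher
effect and lower cost (south-east quadrant) *dominates* the baseline and no
ICER is reported; an arm with higher effect and higher cost gets
``ICER = delta_cost / delta_effect``.  South-west arms (cheaper but less
effective) carry a descriptive cost-saved-per-record-lost ratio rather than
an ICER.

Two univariate deterministic sensitivity analyses are provided: holding the
screening time-on-task rate constant at the across-arm mean, and varying
the precision of the flagship semi-automated arm between plausible bounds,
including the threshold (root-finding) analysis locating the precision at
which that arm stops dominating the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .costing import (
    HoursBreakdown,
    TimeOnTask,
    UnitCost,
    incremental_cost,
    total_cost,
    workflow_hours,
)
from .exceptions import BracketingError, ConfigurationError, ParameterError

__all__ = [
    "CEResult",
    "SAScenario",
    "CEAInputs",
    "ce_point",
    "ce_table",
    "base_case_costs",
    "run_sensitivity",
    "threshold_precision",
]

Quadrant = Literal["NE", "NW", "SE", "SW", "origin"]


@dataclass(frozen=True)
class CEResult:
    """One arm's position on the cost-effectiveness plane vs the baseline."""

    arm_id: int
    delta_cost: float
    delta_effect: float
    quadrant: Quadrant
    dominant: bool
    icer: float | None = None
    cost_saved_per_record_lost: float | None = None
    icer_undefined: bool = False


def _quadrant(delta_effect: float, delta_cost: float) -> Quadrant:
    """Sign-pattern quadrant; zeros on an axis fall to the non-favourable side
    (zero effect counts as west, zero cost as south)."""
    if delta_effect == 0 and delta_cost == 0:
        return "origin"
    east = delta_effect > 0
    north = delta_cost > 0
    return ("N" if north else "S") + ("E" if east else "W")  # type: ignore[return-value]


def ce_point(arm_id: int, delta_effect: float, delta_cost: float) -> CEResult:
    """Classify one (delta effect, delta cost) pair.

    Dominance requires strictly lower cost and strictly higher effect.  An
    ICER is emitted only in the north-east quadrant (more effect at more
    cost); south-west arms get the descriptive saved-per-lost ratio.  A
    zero effect with non-zero cost leaves the ICER undefined and flagged.
    """
    q = _quadrant(delta_effect, delta_cost)
    dominant = delta_cost < 0 and delta_effect > 0
    icer = None
    ratio = None
    undefined = delta_effect == 0 and delta_cost != 0
    if q == "NE" and delta_effect != 0:
        icer = delta_cost / delta_effect
    elif q == "SW" and delta_effect != 0:
        ratio = abs(delta_cost) / abs(delta_effect)
    return CEResult(
        arm_id=arm_id,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        quadrant=q,
        dominant=dominant,
        icer=icer,
        cost_saved_per_record_lost=ratio,
        icer_undefined=undefined,
    )


def ce_table(effects: pd.DataFrame, costs: pd.DataFrame, baseline_arm: int = 1) -> pd.DataFrame:
    """Join per-arm incremental effects and costs into a CE-plane table.

    ``effects`` needs columns ``arm_id, incremental_effectiveness``;
    ``costs`` needs ``arm_id, incremental_cost``.
    """
    merged = effects.merge(costs, on="arm_id", validate="one_to_one")
    rows = []
    for _, r in merged.iterrows():
        res = ce_point(int(r["arm_id"]), float(r["incremental_effectiveness"]), float(r["incremental_cost"]))
        rows.append(
            {
                "arm_id": res.arm_id,
                "delta_effect": res.delta_effect,
                "delta_cost": res.delta_cost,
                "quadrant": res.quadrant,
                "dominant": res.dominant,
                "icer": res.icer,
                "cost_saved_per_record_lost": res.cost_saved_per_record_lost,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CEAInputs:
    """Everything the CEA and its sensitivity analyses consume.

    ``arms`` has one row per arm: ``arm_id, screened, includes,
    search_hours_per_week, dedup_hours_per_week, screen_hours_per_100``.
    ``sa_precision`` (optional) carries the precision-analysis inputs for
    the flagship arm: ``sa_screened`` (fixed screened denominator),
    ``matched_includes`` (includes held fixed across precision values) and
    the plausible ``precision_lower`` / ``precision_upper`` bounds.
    """

    arms: pd.DataFrame
    gold_total: int
    unit_cost: UnitCost
    n_weeks: int = 4
    baseline_arm: int = 1
    sa_arm: int = 8
    sa_screened: float | None = None
    sa_matched_includes: float = 0.0
    precision_lower: float = 0.55
    precision_upper: float = 0.72

    def __post_init__(self) -> None:
        need = {
            "arm_id",
            "screened",
            "includes",
            "search_hours_per_week",
            "dedup_hours_per_week",
            "screen_hours_per_100",
        }
        missing = need - set(self.arms.columns)
        if missing:
            raise ConfigurationError(f"CEA inputs missing columns: {sorted(missing)}")
        if self.baseline_arm not in set(self.arms["arm_id"]):
            raise ConfigurationError(f"baseline arm {self.baseline_arm} missing")
        if not 0 <= self.precision_lower < self.precision_upper <= 1:
            raise ConfigurationError("precision bounds must satisfy 0 <= lower < upper <= 1")


@dataclass(frozen=True)
class SAScenario:
    """A deterministic univariate sensitivity scenario."""

    kind: Literal["constant_time", "precision_range", "precision_threshold"]
    mean_rate: float | None = None       # constant_time: override the computed mean
    precisions: tuple[float, ...] = ()   # precision_range: values to evaluate
    root_tol: float = 0.5                # precision_threshold: |delta effect| tolerance (records)


def _arm_hours(row: pd.Series, n_weeks: int, rate_override: float | None = None) -> HoursBreakdown:
    t = TimeOnTask(
        screen_hours_per_100=rate_override if rate_override is not None else float(row["screen_hours_per_100"]),
        search_hours_per_week=float(row["search_hours_per_week"]),
        dedup_hours_per_week=float(row["dedup_hours_per_week"]),
    )
    return workflow_hours(int(row["screened"]), t, n_weeks, include_search=row["search_hours_per_week"] > 0)


def base_case_costs(inputs: CEAInputs, rate_override: float | None = None) -> pd.DataFrame:
    """Per-arm hours, total and incremental cost from the count inputs."""
    df = inputs.arms.set_index("arm_id", drop=False).sort_index()
    hours = {a: _arm_hours(r, inputs.n_weeks, rate_override) for a, r in df.iterrows()}
    totals = {a: total_cost(h, inputs.unit_cost) for a, h in hours.items()}
    base = totals[inputs.baseline_arm]
    return pd.DataFrame(
        {
            "arm_id": df["arm_id"].astype(int),
            "hours_total": [hours[a].hours_total for a in df.index],
            "total_cost": [totals[a] for a in df.index],
            "incremental_cost": [incremental_cost(totals[a], base) for a in df.index],
        }
    ).reset_index(drop=True)


def _base_effects(inputs: CEAInputs) -> pd.DataFrame:
    df = inputs.arms.set_index("arm_id", drop=False).sort_index()
    base_inc = float(df.loc[inputs.baseline_arm, "includes"])
    return pd.DataFrame(
        {
            "arm_id": df["arm_id"].astype(int),
            "incremental_effectiveness": df["includes"].astype(float) - base_inc,
        }
    ).reset_index(drop=True)


def _sa_includes(inputs: CEAInputs, precision: float) -> float:
    """Flagship-arm includes as a function of its overall precision.

    ``includes(p) = matched_includes + p x sa_screened`` with the screened
    denominator held fixed at the sensitivity-analysis input value.
    """
    if inputs.sa_screened is None:
        raise ConfigurationError("sa_screened must be set for the precision analysis")
    return inputs.sa_matched_includes + precision * inputs.sa_screened


def run_sensitivity(scenario: SAScenario, inputs: CEAInputs) -> pd.DataFrame:
    """Run one deterministic univariate sensitivity analysis.

    Returns a long-format table ``(scenario, parameter_value, arm_id,
    delta_effect, delta_cost, quadrant, dominant, icer)``.

    * ``constant_time`` replaces every arm's screening rate with the
      across-arm mean and recomputes costs only.
    * ``precision_range`` re-evaluates the flagship arm's includes (hence
      its incremental effect) at each stated precision, costs unchanged.
    """
    effects = _base_effects(inputs)
    if scenario.kind == "constant_time":
        mean_rate = (
            scenario.mean_rate
            if scenario.mean_rate is not None
            else float(inputs.arms["screen_hours_per_100"].mean())
        )
        costs = base_case_costs(inputs, rate_override=mean_rate)
        table = ce_table(effects, costs[["arm_id", "incremental_cost"]], inputs.baseline_arm)
        table.insert(0, "parameter_value", mean_rate)
        table.insert(0, "scenario", "constant_time")
        return table

    if scenario.kind == "precision_range":
        precisions = scenario.precisions or (inputs.precision_lower, inputs.precision_upper)
        costs = base_case_costs(inputs)
        base_includes = float(
            inputs.arms.set_index("arm_id").loc[inputs.baseline_arm, "includes"]
        )
        frames = []
        for p in precisions:
            eff = effects.copy()
            inc = round(_sa_includes(inputs, p))
            eff.loc[eff["arm_id"] == inputs.sa_arm, "incremental_effectiveness"] = inc - base_includes
            t = ce_table(eff, costs[["arm_id", "incremental_cost"]], inputs.baseline_arm)
            t.insert(0, "parameter_value", p)
            t.insert(0, "scenario", "precision_range")
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    raise ConfigurationError(f"unknown or non-tabular scenario kind: {scenario.kind!r}")


def threshold_precision(inputs: CEAInputs, tol: float = 0.5, ndigits: int | None = 2) -> float:
    """Precision at which the flagship arm stops dominating the baseline.

    Solves ``delta_effect(p) = 0`` over the plausible precision bracket by
    Brent root finding on the same includes(p) mapping used by the
    precision range analysis; the result satisfies ``|delta_effect(p*)| <=
    tol`` records and is reported to 2 decimals.
    """
    base_includes = float(inputs.arms.set_index("arm_id").loc[inputs.baseline_arm, "includes"])

    def delta_effect(p: float) -> float:
        return _sa_includes(inputs, p) - base_includes

    lo, hi = inputs.precision_lower, inputs.precision_upper
    f_lo, f_hi = delta_effect(lo), delta_effect(hi)
    if not (f_lo < 0 < f_hi):
        raise BracketingError(
            f"delta effect does not change sign over [{lo}, {hi}]: ({f_lo:.1f}, {f_hi:.1f})"
        )
    # xtol chosen so the effect-scale tolerance holds: |dE/dp| = sa_screened
    slope = abs(inputs.sa_screened) if inputs.sa_screened else 1.0
    root = brentq(delta_effect, lo, hi, xtol=min(1e-6, tol / max(slope, 1.0)))
    assert abs(delta_effect(root)) <= max(tol, 1e-9)
    return round(float(root), ndigits) if ndigits is not None else float(root)
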