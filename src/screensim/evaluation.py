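"""Effectiveness measures and count-level replication.

Recall, precision and incremental effectiveness follow the living-map
evaluation's definitions:

* recall — eligible records identified divided by the total eligible
  records in the constructed gold standard;
* precision — records included divided by records manually screen-coded;
* incremental effectiveness — an arm's included-record count minus the
  baseline arm's count ("records saved from inappropriate exclusion").

:func:`replicate_base_case` recomputes a full per-arm effectiveness table
from count-level inputs (screened counts, include counts or the analytic
assumptions that yield them), which is how the original analysis was run in
a spreadsheet.  :func:`cumulative_precision_ci` is the monitoring statistic
used to track a deployed workflow week by week.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .exceptions import ConfigurationError, EmptyInputError, UndefinedResultError
from .workflow import ScreeningOutcome

__all__ = [
    "EffectivenessResult",
    "ReplicationInputs",
    "compute_effectiveness",
    "replicate_base_case",
    "cumulative_precision_ci",
]


@dataclass(frozen=True)
class EffectivenessResult:
    """Per-arm effectiveness versus the gold standard and the baseline arm."""

    arm_id: int
    recall: float
    precision: float
    incremental_effectiveness: int
    n_includes: int
    n_screened: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.recall <= 1.0
        assert 0.0 <= self.precision <= 1.0


def compute_effectiveness(
    outcome: ScreeningOutcome,
    gold: set,
    baseline: ScreeningOutcome,
) -> EffectivenessResult:
    """Score one arm's outcome against the gold standard and arm 1.

    ``recall = |included ∩ gold| / |gold|``;
    ``precision = includes / screened``;
    ``incremental = includes − baseline includes``.
    """
    if not gold:
        raise EmptyInputError("gold standard is empty")
    if outcome.n_screened == 0:
        raise UndefinedResultError(f"arm {outcome.arm_id}: precision undefined with zero records screened")
    recall = len(set(outcome.included_ids) & gold) / len(gold)
    precision = outcome.n_includes / outcome.n_screened
    return EffectivenessResult(
        arm_id=outcome.arm_id,
        recall=recall,
        precision=precision,
        incremental_effectiveness=outcome.n_includes - baseline.n_includes,
        n_includes=outcome.n_includes,
        n_screened=outcome.n_screened,
    )


@dataclass
class ReplicationInputs:
    """Count-level inputs for recomputing the effectiveness table.

    ``table`` has one row per arm with columns ``arm_id``, ``screened`` and
    (optionally) ``includes``.  Missing ``includes`` are derived from the
    three base-case analytic assumptions:

    i.   the fixed-target manual arm (arm 3) inherits the baseline arm's
         observed precision (``arm3_precision_equals_arm1``);
    ii.  in open-dataset arms, the conventionally indexed (matched) stratum
         is included at ``mag_matched_precision`` (default 0.5), on top of
         ``custom_includes`` — requires ``matched_screened`` and
         ``custom_includes`` columns;
    iii. hypothetical extra ineligible records split between retained and
         discarded in proportion ``extra_ineligible_split`` — an optional
         ``extra_ineligible`` column adds its retained share to ``screened``.
    """

    table: pd.DataFrame
    gold_total: int
    baseline_arm: int = 1
    arm3_precision_equals_arm1: bool = True
    mag_matched_precision: float = 0.5
    extra_ineligible_split: float | None = None

    def __post_init__(self) -> None:
        if self.gold_total <= 0:
            raise ConfigurationError("gold_total must be positive")
        if "arm_id" not in self.table.columns or "screened" not in self.table.columns:
            raise ConfigurationError("replication table needs 'arm_id' and 'screened' columns")
        if not 0.0 <= self.mag_matched_precision <= 1.0:
            raise ConfigurationError("mag_matched_precision must lie in [0, 1]")


def replicate_base_case(inputs: ReplicationInputs) -> pd.DataFrame:
    """Recompute the per-arm effectiveness table from counts.

    Returns a DataFrame with columns ``arm_id, screened, includes, recall,
    precision, incremental_effectiveness``, one row per input arm, baseline
    first in incremental terms (its incremental is 0).
    """
    df = inputs.table.copy()
    required_arms = set(df["arm_id"])
    if inputs.baseline_arm not in required_arms:
        raise ConfigurationError(f"baseline arm {inputs.baseline_arm} missing from inputs")
    df = df.set_index("arm_id", drop=False).sort_index()

    if "includes" not in df.columns:
        df["includes"] = np.nan
    df["includes"] = pd.to_numeric(df["includes"], errors="coerce")
    df["screened"] = pd.to_numeric(df["screened"], errors="raise").astype(float)

    # assumption (iii): retained share of hypothetical extra ineligibles
    if inputs.extra_ineligible_split is not None and "extra_ineligible" in df.columns:
        extra = pd.to_numeric(df["extra_ineligible"], errors="coerce").fillna(0.0)
        df["screened"] = df["screened"] + inputs.extra_ineligible_split * extra

    base = df.loc[inputs.baseline_arm]
    if np.isnan(base["includes"]):
        raise ConfigurationError("baseline arm must carry an explicit include count")
    base_precision = base["includes"] / base["screened"]

    for arm_id, row in df.iterrows():
        if not np.isnan(row["includes"]):
            continue
        if arm_id == 3 and inputs.arm3_precision_equals_arm1:
            # assumption (i)
            df.loc[arm_id, "includes"] = round(base_precision * row["screened"])
        elif {"matched_screened", "custom_includes"} <= set(df.columns) and not np.isnan(
            row.get("matched_screened", np.nan)
        ):
            # assumption (ii)
            df.loc[arm_id, "includes"] = round(
                inputs.mag_matched_precision * row["matched_screened"] + row["custom_includes"]
            )
        else:
            raise ConfigurationError(f"arm {arm_id}: includes missing and no assumption applies")

    if (df["screened"] <= 0).any():
        raise UndefinedResultError("precision undefined: an arm has zero records screened")

    out = pd.DataFrame(
        {
            "arm_id": df["arm_id"].astype(int),
            "screened": df["screened"],
            "includes": df["includes"],
            "recall": df["includes"] / inputs.gold_total,
            "precision": df["includes"] / df["screened"],
            "incremental_effectiveness": df["includes"] - df.loc[inputs.baseline_arm, "includes"],
        }
    ).reset_index(drop=True)
    return out


def cumulative_precision_ci(
    weekly: Sequence[tuple[int, int]],
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Cumulative precision with a Wilson score interval.

    ``weekly`` is a sequence of ``(includes, screened)`` pairs; the point
    estimate is total includes over total screened.  The Wilson interval is
    well-behaved near 0 and 1, which matters for the early weeks of a
    deployed workflow.
    """
    if len(weekly) == 0:
        raise EmptyInputError("no weekly counts supplied")
    inc = sum(int(i) for i, _ in weekly)
    scr = sum(int(s) for _, s in weekly)
    if scr == 0:
        raise UndefinedResultError("cumulative precision undefined with zero records screened")
    if inc > scr or any(i > s for i, s in weekly) or inc < 0:
        raise ConfigurationError("includes cannot exceed records screened")
    point = inc / scr
    lower, upper = proportion_confint(inc, scr, alpha=alpha, method="wilson")
    return point, float(lower), float(upper)
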