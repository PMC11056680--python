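"""Resource use (hours) and money per workflow arm.

The time-on-task model is linear: screening hours accrue per 100 records
screened at an arm-specific rate, and search/deduplication hours accrue per
week depending on the arm's source (conventional-search arms pay both
search and two-stage deduplication; open-dataset arms pay only
deduplication against known records).  Costs are hours times an hourly unit
cost; the four-week horizon carries no discounting.  Cost heads excluded
from the model — search-strategy development, tooling work, training — are
never represented, matching the evaluation's stated exclusions.

Money is computed at full floating precision and rounded half-up to 2
decimals only at the reporting boundary (:func:`round_money`).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .exceptions import ParameterError
from .workflow import ScreeningOutcome

__all__ = [
    "TimeOnTask",
    "UnitCost",
    "HoursBreakdown",
    "CostResult",
    "workflow_hours",
    "total_cost",
    "incremental_cost",
    "round_money",
]


@dataclass(frozen=True)
class TimeOnTask:
    """Task-level time-on-task rates for one arm.

    ``search_hours_per_week`` applies only to conventional-search arms;
    ``screen_hours_per_100`` is the hours needed to screen-code 100 records
    in this arm's workflow.
    """

    screen_hours_per_100: float
    search_hours_per_week: float = 0.0
    dedup_hours_per_week: float = 0.0

    def __post_init__(self) -> None:
        for name in ("screen_hours_per_100", "search_hours_per_week", "dedup_hours_per_week"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass(frozen=True)
class UnitCost:
    """An hourly unit cost in one currency (GBP or AUD)."""

    currency: str
    hourly_rate: float

    def __post_init__(self) -> None:
        if self.currency not in ("GBP", "AUD"):
            raise ParameterError(f"currency must be 'GBP' or 'AUD', got {self.currency!r}")
        if self.hourly_rate <= 0:
            raise ParameterError("hourly_rate must be positive")


@dataclass(frozen=True)
class HoursBreakdown:
    hours_search: float
    hours_dedup: float
    hours_screen: float

    @property
    def hours_total(self) -> float:
        return self.hours_search + self.hours_dedup + self.hours_screen


@dataclass(frozen=True)
class CostResult:
    """Per-arm resource use and money, incremental versus the baseline arm."""

    arm_id: int
    hours: HoursBreakdown
    total_cost: float
    incremental_cost: float
    currency: str

    def to_row(self) -> dict:
        return {
            "arm_id": self.arm_id,
            "hours_search": self.hours.hours_search,
            "hours_dedup": self.hours.hours_dedup,
            "hours_screen": self.hours.hours_screen,
            "hours_total": self.hours.hours_total,
            "total_cost": round_money(self.total_cost),
            "incremental_cost": round_money(self.incremental_cost),
            "currency": self.currency,
        }


def workflow_hours(
    outcome: ScreeningOutcome | int,
    t: TimeOnTask,
    n_weeks: int,
    include_search: bool = True,
) -> HoursBreakdown:
    """Hours spent on the manual tasks of one arm.

    ``hours_screen = n_screened x screen_hours_per_100 / 100``; search and
    dedup hours accrue per week.  ``include_search`` is False for
    open-dataset arms, whose search step is fully automated.
    """
    n_screened = outcome.n_screened if isinstance(outcome, ScreeningOutcome) else int(outcome)
    if n_screened < 0 or n_weeks <= 0:
        raise ParameterError("n_screened must be non-negative and n_weeks positive")
    return HoursBreakdown(
        hours_search=(t.search_hours_per_week * n_weeks) if include_search else 0.0,
        hours_dedup=t.dedup_hours_per_week * n_weeks,
        hours_screen=n_screened * t.screen_hours_per_100 / 100.0,
    )


def total_cost(hours: HoursBreakdown | float, unit: UnitCost) -> float:
    """Total money: hours times the hourly unit cost (full precision)."""
    h = hours.hours_total if isinstance(hours, HoursBreakdown) else float(hours)
    if h < 0:
        raise ParameterError("hours must be non-negative")
    return h * unit.hourly_rate


def incremental_cost(arm_total: float, baseline_total: float) -> float:
    """Signed cost difference versus the baseline arm (same currency)."""
    return arm_total - baseline_total


def round_money(x: float) -> float:
    """Half-up rounding to 2 decimals at the reporting boundary."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
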