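"""Screening-workflow simulator.

Simulates the eight study-identification workflows of the living-map
evaluation as a pipeline of: source-stream selection, deduplication, an
optional classifier gate, (optionally prioritised) week-by-week manual
screening with an optional fixed weekly target, and a target-recall stop
rule.  Each arm yields a :class:`ScreeningOutcome` with the tallies the
effectiveness and costing calculators consume.

Arm semantics
-------------
* ``source`` selects the conventional stream (``"ME"``) or the open-dataset
  stream (``"MAG"``: conventionally indexed records matched into the open
  dataset plus the custom Boolean search stratum).
* The classifier gate retains records with ``score0 >= threshold``; the
  threshold is calibrated so that at least ``target_recall`` of a set of
  known-eligible calibration scores are retained.
* Priority screening orders pending records by an effective score
  ``s_eff = lam * [eligible] + (1 - lam) * score0`` with
  ``lam = n_labelled / (n_labelled + halfsat)`` — a stylised active-learning
  curve that starts at the raw classifier ranking and converges to a perfect
  oracle as screening decisions accumulate.  The ranking is refreshed every
  ``rerank_every`` screened records.
* With ``target_recall = 1.0`` screening continues until the stream is
  exhausted; with a relaxed target it stops as soon as the target fraction
  of the arm's retained eligible records has been included.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus import Corpus, resolve_roots
from .exceptions import ConfigurationError, EmptyInputError, ParameterError

__all__ = [
    "ArmConfig",
    "ClassifierGate",
    "EngineParams",
    "ScreeningOutcome",
    "calibrate_threshold",
    "apply_gate",
    "deduplicate",
    "priority_rank",
    "run_arm",
    "build_gold_standard",
    "select_mag_custom_top",
    "default_arms",
    "load_arm_configs",
    "validate_canonical_arms",
]


@dataclass(frozen=True)
class ArmConfig:
    """One study arm: a point on the five workflow decision axes."""

    arm_id: int
    label: str
    source: str  # "ME" or "MAG"
    dedup_between_sources: bool
    dedup_against_known: bool
    classifier_gate: bool
    priority_screening: bool
    fixed_target_per_week: int | None
    target_recall: float

    def __post_init__(self) -> None:
        if not 1 <= self.arm_id <= 8:
            raise ConfigurationError(f"arm_id must be in 1..8, got {self.arm_id}")
        if self.source not in ("ME", "MAG"):
            raise ConfigurationError(f"source must be 'ME' or 'MAG', got {self.source!r}")
        if not 0.0 < self.target_recall <= 1.0:
            raise ConfigurationError(f"target_recall must be in (0, 1], got {self.target_recall}")
        if self.fixed_target_per_week is not None and self.fixed_target_per_week <= 0:
            raise ConfigurationError("fixed_target_per_week must be positive when set")


#: The canonical dot-pattern of the eight arms across the five decision axes.
_CANONICAL = {
    1: ("ME", True, True, False, False, None, 1.0),
    2: ("ME", True, True, False, False, None, 0.95),
    3: ("ME", True, True, False, False, 1500, 0.95),
    4: ("ME", True, True, True, False, None, 0.95),
    5: ("ME", True, True, True, True, 1500, 0.95),
    6: ("MAG", False, True, False, False, None, 1.0),
    7: ("MAG", False, True, True, False, None, 0.95),
    8: ("MAG", False, True, True, True, 1500, 0.95),
}


def validate_canonical_arms(arms: Sequence[ArmConfig]) -> None:
    """Check that arms 1-8 reproduce the canonical decision-axis pattern."""
    by_id = {a.arm_id: a for a in arms}
    if sorted(by_id) != list(range(1, 9)):
        raise ConfigurationError(f"expected arms 1..8, got {sorted(by_id)}")
    for arm_id, pattern in _CANONICAL.items():
        a = by_id[arm_id]
        got = (
            a.source,
            a.dedup_between_sources,
            a.dedup_against_known,
            a.classifier_gate,
            a.priority_screening,
            a.fixed_target_per_week,
            a.target_recall,
        )
        if got != pattern:
            raise ConfigurationError(
                f"arm {arm_id} does not match the canonical pattern: "
                f"expected {pattern}, got {got}"
            )


def load_arm_configs(path: str | Path) -> list[ArmConfig]:
    """Read arm definitions from a YAML or JSON config file."""
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    arms = [
        ArmConfig(
            arm_id=int(d["arm_id"]),
            label=str(d["label"]),
            source=str(d["source"]),
            dedup_between_sources=bool(d["dedup_between_sources"]),
            dedup_against_known=bool(d["dedup_against_known"]),
            classifier_gate=bool(d["classifier_gate"]),
            priority_screening=bool(d["priority_screening"]),
            fixed_target_per_week=(None if d.get("fixed_target_per_week") in (None, "")
                                   else int(d["fixed_target_per_week"])),
            target_recall=float(d["target_recall"]),
        )
        for d in data["arms"]
    ]
    return arms


def default_arms() -> list[ArmConfig]:
    """The eight canonical study arms, loaded from the packaged config."""
    with resources.as_file(resources.files("screensim.data") / "arms.yaml") as p:
        arms = load_arm_configs(p)
    validate_canonical_arms(arms)
    return arms


@dataclass(frozen=True)
class ClassifierGate:
    """A score threshold retaining records for manual screening."""

    threshold: float
    calibration_target_recall: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ParameterError(f"threshold must lie in [0, 1], got {self.threshold}")


def calibrate_threshold(scores_eligible: Sequence[float], target_recall: float) -> ClassifierGate:
    """Largest threshold retaining at least ``target_recall`` of the scores.

    Retention uses ``score >= threshold``, so the returned threshold is the
    k-th largest calibration score with ``k = ceil(target_recall * n)``.
    """
    scores = np.asarray(scores_eligible, dtype=float)
    if scores.size == 0:
        raise EmptyInputError("cannot calibrate a gate on an empty score list")
    if not 0.0 < target_recall <= 1.0:
        raise ParameterError(f"target_recall must be in (0, 1], got {target_recall}")
    desc = np.sort(scores)[::-1]
    k = math.ceil(target_recall * desc.size)
    return ClassifierGate(threshold=float(desc[k - 1]), calibration_target_recall=target_recall)


def apply_gate(records: pd.DataFrame, gate: ClassifierGate) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into (retained, discarded) by ``score0 >= threshold``."""
    keep = records["score0"].to_numpy() >= gate.threshold
    return records[keep], records[~keep]


def deduplicate(
    records: pd.DataFrame,
    known_ids: frozenset | set = frozenset(),
    dup_map: pd.Series | None = None,
) -> tuple[pd.DataFrame, int]:
    """Remove duplicates within a batch and against already-known records.

    Each record is resolved to the root of its ``dup_of`` chain (using
    ``dup_map`` — the full corpus mapping — when the chain leaves the batch).
    One record per root is kept (the earliest by record_id); records whose
    root is in ``known_ids`` are dropped.  Idempotent.

    Returns ``(unique, n_removed)``.
    """
    if len(records) == 0:
        return records, 0
    if dup_map is None:
        dup_map = records.set_index("record_id")["dup_of"]
    roots = resolve_roots(dup_map, records["record_id"].tolist())
    df = records.copy()
    df["root_id"] = roots.loc[df["record_id"]].to_numpy()
    df = df[~df["root_id"].isin(known_ids)]
    df = df.sort_values("record_id").drop_duplicates(subset="root_id", keep="first")
    n_removed = len(records) - len(df)
    return df.reset_index(drop=True), n_removed


def priority_rank(
    pending: pd.DataFrame,
    n_labelled: int,
    learning_halfsat: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Order pending records by the active-learning effective score.

    ``s_eff = lam * [eligible] + (1 - lam) * score0`` with
    ``lam = n_labelled / (n_labelled + learning_halfsat)``; ties broken by
    ascending record_id (stable).  ``seed`` is accepted for interface
    symmetry with the stochastic operations but the ranking is
    deterministic.
    """
    if learning_halfsat <= 0:
        raise ParameterError("learning_halfsat must be positive")
    lam = n_labelled / (n_labelled + learning_halfsat)
    s_eff = lam * pending["eligible"].to_numpy(dtype=float) + (1.0 - lam) * pending["score0"].to_numpy()
    order = np.lexsort((pending["record_id"].to_numpy(), -s_eff))
    return pending.iloc[order]


@dataclass(frozen=True)
class EngineParams:
    """Tunables of the screening simulator (not arm-defining)."""

    rerank_every: int = 100
    learning_halfsat: int = 2000
    known_ids: frozenset = frozenset()
    mag_release_lag: bool = False  # shift custom-stratum availability by one week
    seed: int = 0


@dataclass
class ScreeningOutcome:
    """Per-arm screening tallies and identity sets.

    ``screened_ids`` / ``included_ids`` hold duplicate-chain *root* ids so
    that outcomes from different source streams are comparable.
    """

    arm_id: int
    n_unique_after_dedup: int
    n_duplicates_removed: int
    n_discarded_by_gate: int
    n_screened: int
    n_includes: int
    n_excludes: int
    per_week: list[tuple[int, int, int]]  # (week, screened, includes)
    screened_ids: set
    included_ids: set

    def validate(self) -> None:
        assert self.n_screened == self.n_includes + self.n_excludes
        assert self.n_screened <= self.n_unique_after_dedup - self.n_discarded_by_gate
        assert sum(s for _, s, _ in self.per_week) == self.n_screened
        assert all(v >= 0 for v in (
            self.n_unique_after_dedup, self.n_discarded_by_gate,
            self.n_screened, self.n_includes, self.n_excludes,
        ))

    def to_row(self) -> dict:
        return {
            "arm_id": self.arm_id,
            "n_unique_after_dedup": self.n_unique_after_dedup,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_discarded_by_gate": self.n_discarded_by_gate,
            "n_screened": self.n_screened,
            "n_includes": self.n_includes,
            "n_excludes": self.n_excludes,
        }


def _select_stream(corpus: Corpus, arm: ArmConfig) -> pd.DataFrame:
    if arm.source == "ME":
        return corpus.me_stream
    return corpus.mag_stream


def run_arm(
    corpus: Corpus,
    arm: ArmConfig,
    gate: ClassifierGate | None = None,
    engine: EngineParams | None = None,
) -> ScreeningOutcome:
    """Simulate one study arm end to end.

    Pipeline order: select source stream -> deduplicate -> gate (if on) ->
    order records (priority if on, else ascending record_id as a
    label-independent stand-in for alphabetical order) -> screen week by
    week, capped at the fixed weekly target if set -> stop when the target
    recall is reached among the arm's retained eligible records (omniscient
    stop, mirroring a retrospective simulation), or when records are
    exhausted.
    """
    engine = engine or EngineParams()
    if arm.classifier_gate and gate is None:
        raise ConfigurationError(f"arm {arm.arm_id} requires a classifier gate but none was supplied")
    if not arm.classifier_gate and gate is not None:
        raise ConfigurationError(f"arm {arm.arm_id} has no classifier gate but one was supplied")

    stream = _select_stream(corpus, arm)
    known = engine.known_ids if arm.dedup_against_known else frozenset()
    unique, n_removed = deduplicate(stream, known_ids=known, dup_map=corpus.dup_map())
    n_unique = len(unique)

    if arm.classifier_gate:
        retained, discarded = apply_gate(unique, gate)
        n_discarded = len(discarded)
    else:
        retained, n_discarded = unique, 0

    # availability week (optional one-week release lag of the custom stratum)
    avail_week = retained["week"].to_numpy().copy()
    if engine.mag_release_lag and arm.source == "MAG":
        avail_week = np.where(retained["in_mag_custom_stratum"].to_numpy(), avail_week + 1, avail_week)

    rec_ids = retained["record_id"].to_numpy()
    root_ids = retained["root_id"].to_numpy() if "root_id" in retained.columns else rec_ids
    eligible = retained["eligible"].to_numpy()
    score0 = retained["score0"].to_numpy()

    n_eligible_retained = int(eligible.sum())
    screen_all = arm.target_recall >= 1.0
    stop_target = math.ceil(arm.target_recall * n_eligible_retained)

    screened = np.zeros(rec_ids.size, dtype=bool)
    n_screened = n_includes = 0
    per_week: list[tuple[int, int, int]] = []
    # a relaxed target over zero retained eligibles is met before screening
    stopped = (not screen_all) and stop_target == 0

    for week in range(1, corpus.params.n_weeks + 1):
        cap = arm.fixed_target_per_week if arm.fixed_target_per_week is not None else np.inf
        wk_screened = wk_includes = 0
        while not stopped and wk_screened < cap:
            avail = ~screened & (avail_week <= week)
            idx = np.flatnonzero(avail)
            if idx.size == 0:
                break
            if arm.priority_screening:
                lam = n_screened / (n_screened + engine.learning_halfsat)
                s_eff = lam * eligible[idx].astype(float) + (1.0 - lam) * score0[idx]
                order = idx[np.lexsort((rec_ids[idx], -s_eff))]
                chunk = order[: int(min(cap - wk_screened, engine.rerank_every))]
            else:
                order = idx[np.argsort(rec_ids[idx])]
                chunk = order[: int(min(cap - wk_screened, order.size))]
            if not screen_all:
                # stop mid-chunk the moment the include target is reached
                cum = np.cumsum(eligible[chunk])
                hit = np.flatnonzero(cum + n_includes >= stop_target)
                if hit.size:
                    chunk = chunk[: hit[0] + 1]
                    stopped = True
            screened[chunk] = True
            c_inc = int(eligible[chunk].sum())
            wk_screened += chunk.size
            wk_includes += c_inc
            n_screened += chunk.size
            n_includes += c_inc
            if not arm.priority_screening and not stopped:
                # non-priority order never changes; one pass per week suffices
                break
        per_week.append((week, wk_screened, wk_includes))
        if stopped:
            break

    outcome = ScreeningOutcome(
        arm_id=arm.arm_id,
        n_unique_after_dedup=n_unique,
        n_duplicates_removed=n_removed,
        n_discarded_by_gate=n_discarded,
        n_screened=n_screened,
        n_includes=n_includes,
        n_excludes=n_screened - n_includes,
        per_week=per_week,
        screened_ids=set(root_ids[screened].tolist()),
        included_ids=set(root_ids[screened & eligible].tolist()),
    )
    outcome.validate()
    return outcome


def select_mag_custom_top(corpus: Corpus, cap: int = 1500) -> pd.DataFrame:
    """Top-``cap`` custom-search records over the period, by classifier score.

    Emulates screening only the highest-priority slice of the custom search
    for gold-standard construction; ties broken by record_id.
    """
    custom = corpus.mag_custom_stream
    order = np.lexsort((custom["record_id"].to_numpy(), -custom["score0"].to_numpy()))
    return custom.iloc[order[:cap]]


def build_gold_standard(outcome_arm1: ScreeningOutcome, mag_custom_top: pd.DataFrame,
                        dup_map: pd.Series | None = None) -> set:
    """Gold standard: full-screen ME includes + eligible custom-top records.

    Custom-stratum records are resolved to duplicate-chain roots before the
    union, so overlap with the conventional stream is counted once.
    """
    elig = mag_custom_top[mag_custom_top["eligible"]]
    if dup_map is not None and len(elig):
        roots = resolve_roots(dup_map, elig["record_id"].tolist())
        elig_ids = set(roots.to_numpy().tolist())
    else:
        ids = elig["record_id"].to_numpy()
        dup = elig["dup_of"].to_numpy()
        # record ids are opaque keys: substitute the one-hop parent when linked
        elig_ids = {d if not pd.isna(d) else i for i, d in zip(ids, dup)}
    return set(outcome_arm1.included_ids) | elig_ids
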