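"""Reusable simulation experiments.

Small, seeded experiment recipes built from the package's own pieces, used
by the test-suite and the reproduction script so that headline quantities
are always recomputed the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import GeneratorParams, generate_corpus
from .workflow import calibrate_threshold

__all__ = ["GateCalibrationResult", "gate_calibration_experiment"]


@dataclass(frozen=True)
class GateCalibrationResult:
    """Held-out performance of a recall-calibrated classifier gate."""

    threshold: float
    heldout_recall: float          # recall among held-out eligible records
    heldout_discard_fraction: float  # share of the held-out stream discarded
    n_calibration: int
    n_heldout: int


def gate_calibration_experiment(
    n_records: int = 20_000,
    prevalence: float = 0.40,
    seed: int = 42,
    target_recall: float = 0.95,
    calibration_split: float = 0.5,
    n_weeks: int = 4,
) -> GateCalibrationResult:
    """Calibrate a gate on half the stream, evaluate it on the other half.

    Generates a default synthetic conventional-search stream of
    ``n_records`` unique records at the given eligibility prevalence,
    splits it at random into calibration and held-out halves, calibrates
    the score threshold to ``target_recall`` on the calibration eligible
    scores, and measures the gate's held-out eligible recall and the
    fraction of the held-out stream it discards (the workload reduction
    relative to screening everything).
    """
    weekly = max(1, n_records // n_weeks)
    params = GeneratorParams(
        weekly_me_results=weekly,
        n_weeks=n_weeks,
        prevalence_me=prevalence,
        dup_rate=0.0,
        seed=seed,
    )
    corpus = generate_corpus(params)
    me = corpus.records[corpus.records["in_me"] & ~corpus.records["in_mag_custom_stratum"]]

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    n = len(me)
    idx = rng.permutation(n)
    n_cal = int(round(calibration_split * n))
    cal, held = me.iloc[idx[:n_cal]], me.iloc[idx[n_cal:]]

    gate = calibrate_threshold(cal.loc[cal["eligible"], "score0"].to_numpy(), target_recall)

    held_scores = held["score0"].to_numpy()
    held_elig = held["eligible"].to_numpy()
    retained = held_scores >= gate.threshold
    recall = float(retained[held_elig].mean())
    discard = float((~retained).mean())
    return GateCalibrationResult(
        threshold=gate.threshold,
        heldout_recall=recall,
        heldout_discard_fraction=discard,
        n_calibration=n_cal,
        n_heldout=n - n_cal,
    )
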