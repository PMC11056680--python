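"""End-to-end pipeline: simulate / replicate / sensitivity report bundles.

``run_pipeline`` glues the modules together and writes a bundle of
schema-stable CSVs plus a run manifest:

* ``effectiveness.csv`` — per-arm recall / precision / incremental effect;
* ``costs.csv`` — per-arm hours, total and incremental cost;
* ``ce_plane.csv`` — cost-effectiveness plane coordinates and dominance;
* ``sensitivity.csv`` — long-format deterministic sensitivity results;
* ``manifest.json`` — seed, config hash, package and library versions,
  and the analytic assumptions toggled for the run.

The same config and seed always produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import CEAInputs, SAScenario, base_case_costs, ce_table, run_sensitivity, threshold_precision
from .corpus import Corpus, GeneratorParams, generate_corpus
from .costing import round_money
from .evaluation import ReplicationInputs, compute_effectiveness, replicate_base_case
from .exceptions import BracketingError, ConfigurationError, ScreensimError
from .io import (
    RunConfig,
    find_osf_file,
    load_synthetic_inputs,
    load_unit_cost,
    read_osf_csv,
)
from .workflow import (
    ArmConfig,
    EngineParams,
    build_gold_standard,
    calibrate_threshold,
    default_arms,
    run_arm,
    select_mag_custom_top,
)

__all__ = ["run_pipeline", "simulate_arms"]

CALIBRATION_TARGET_RECALL = 0.95
GOLD_CUSTOM_CAP = 1500


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in asdict(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ScreensimError):
                raise type(exc)(f"[stage: {name}] {exc}") from exc
            return False

    return _Ctx()


def simulate_arms(
    params: GeneratorParams,
    arms: list[ArmConfig] | None = None,
    calibration_seed: int | None = None,
    engine: EngineParams | None = None,
):
    """Generate a corpus, calibrate the gate, and run every arm.

    The gate is calibrated on a *separate* synthetic stream (the weeks
    preceding the evaluation period), never on the evaluation corpus.

    Returns ``(corpus, gate, outcomes, gold)`` with ``outcomes`` keyed by
    arm_id.
    """
    arms = arms if arms is not None else default_arms()
    if calibration_seed is None:
        calibration_seed = int(np.random.SeedSequence(params.seed).generate_state(2)[1] % (2**31))
    corpus = generate_corpus(params)
    cal_params = GeneratorParams(
        **{**{f: getattr(params, f) for f in params.__dataclass_fields__}, "seed": calibration_seed}
    )
    cal_corpus = generate_corpus(cal_params)
    cal_scores = cal_corpus.me_stream.loc[cal_corpus.me_stream["eligible"], "score0"]
    gate = calibrate_threshold(cal_scores.to_numpy(), CALIBRATION_TARGET_RECALL)

    engine = engine or EngineParams(seed=params.seed)
    outcomes = {}
    for arm in sorted(arms, key=lambda a: a.arm_id):
        outcomes[arm.arm_id] = run_arm(corpus, arm, gate if arm.classifier_gate else None, engine)
    if 1 not in outcomes:
        raise ConfigurationError("arm 1 (baseline) must be simulated to build the gold standard")
    gold = build_gold_standard(
        outcomes[1], select_mag_custom_top(corpus, GOLD_CUSTOM_CAP), dup_map=corpus.dup_map()
    )
    return corpus, gate, outcomes, gold


def _simulate_bundle(config: RunConfig) -> dict[str, pd.DataFrame]:
    params = GeneratorParams(**{**config.generator, "seed": config.seed})
    arms = default_arms()
    if config.arm_subset:
        wanted = set(config.arm_subset) | {1}
        arms = [a for a in arms if a.arm_id in wanted]
    with _stage("simulate"):
        corpus, gate, outcomes, gold = simulate_arms(params, arms)
    with _stage("effectiveness"):
        eff_rows = []
        for arm_id, out in outcomes.items():
            r = compute_effectiveness(out, gold, outcomes[1])
            eff_rows.append(
                {
                    "arm_id": arm_id,
                    "screened": r.n_screened,
                    "includes": r.n_includes,
                    "recall": round(r.recall, 4),
                    "precision": round(r.precision, 4),
                    "incremental_effectiveness": r.incremental_effectiveness,
                }
            )
        effectiveness = pd.DataFrame(eff_rows).sort_values("arm_id").reset_index(drop=True)
    with _stage("costing"):
        rates = load_synthetic_inputs("timeontask").set_index("arm_id")
        arm_rows = []
        for arm in arms:
            t = rates.loc[arm.arm_id]
            out = outcomes[arm.arm_id]
            arm_rows.append(
                {
                    "arm_id": arm.arm_id,
                    "screened": out.n_screened,
                    "includes": out.n_includes,
                    "search_hours_per_week": float(t["search_hours_per_week"]) if arm.source == "ME" else 0.0,
                    "dedup_hours_per_week": float(t["dedup_hours_per_week"]),
                    "screen_hours_per_100": float(t["screen_hours_per_100"]),
                }
            )
        inputs = CEAInputs(
            arms=pd.DataFrame(arm_rows),
            gold_total=len(gold),
            unit_cost=load_unit_cost(config.currency),
            n_weeks=params.n_weeks,
            sa_screened=float(outcomes[8].n_screened) if 8 in outcomes else None,
        )
        costs = base_case_costs(inputs)
    with _stage("cea"):
        plane = ce_table(
            effectiveness[["arm_id", "incremental_effectiveness"]],
            costs[["arm_id", "incremental_cost"]],
        )
        sa_frames = [run_sensitivity(SAScenario(kind="constant_time"), inputs)]
        if inputs.sa_screened:
            try:
                sa_frames.append(run_sensitivity(SAScenario(kind="precision_range"), inputs))
            except BracketingError:
                pass
        sensitivity = pd.concat(sa_frames, ignore_index=True)
    return {
        "effectiveness": effectiveness,
        "costs": _round_cost_table(costs),
        "ce_plane": plane,
        "sensitivity": sensitivity,
        "_extra": {"gate_threshold": gate.threshold, "gold_total": len(gold)},
    }


def _load_inputs_table(config: RunConfig, role: str) -> pd.DataFrame:
    cmap = config.column_maps.get(role)
    if config.input_dir is not None:
        return read_osf_csv(find_osf_file(config.input_dir, role), role, cmap)
    return load_synthetic_inputs(role, cmap)


def _replicate_bundle(config: RunConfig) -> dict[str, pd.DataFrame]:
    with _stage("read inputs"):
        base = _load_inputs_table(config, "basecase")
        sa_prec = _load_inputs_table(config, "sa_precision").set_index("quantity")["value"]
    with _stage("replicate effectiveness"):
        rep = ReplicationInputs(
            table=base[["arm_id", "screened", "includes"]],
            gold_total=int(base["gold_total"].iloc[0]),
        )
        effectiveness = replicate_base_case(rep)
        effectiveness["recall"] = effectiveness["recall"].round(4)
        effectiveness["precision"] = effectiveness["precision"].round(4)
    with _stage("costing"):
        inputs = CEAInputs(
            arms=base[
                ["arm_id", "screened", "includes",
                 "search_hours_per_week", "dedup_hours_per_week", "screen_hours_per_100"]
            ],
            gold_total=int(base["gold_total"].iloc[0]),
            unit_cost=load_unit_cost(config.currency),
            sa_screened=float(sa_prec["sa_screened"]),
            sa_matched_includes=float(sa_prec.get("matched_includes", 0.0)),
            precision_lower=float(sa_prec.get("precision_lower", 0.55)),
            precision_upper=float(sa_prec.get("precision_upper", 0.72)),
        )
        costs = base_case_costs(inputs)
    with _stage("cea"):
        plane = ce_table(
            effectiveness[["arm_id", "incremental_effectiveness"]],
            costs[["arm_id", "incremental_cost"]],
        )
        sensitivity = pd.concat(
            [
                run_sensitivity(SAScenario(kind="constant_time"), inputs),
                run_sensitivity(SAScenario(kind="precision_range"), inputs),
            ],
            ignore_index=True,
        )
        try:
            p_star = threshold_precision(inputs)
        except BracketingError:
            p_star = None
    return {
        "effectiveness": effectiveness,
        "costs": _round_cost_table(costs),
        "ce_plane": plane,
        "sensitivity": sensitivity,
        "_extra": {"threshold_precision": p_star, "gold_total": int(base["gold_total"].iloc[0])},
    }


def _round_cost_table(costs: pd.DataFrame) -> pd.DataFrame:
    out = costs.copy()
    out["hours_total"] = out["hours_total"].round(2)
    for c in ("total_cost", "incremental_cost"):
        out[c] = out[c].map(round_money)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run one configured pipeline and write the report bundle.

    Returns the manifest dict; CSVs and ``manifest.json`` land in
    ``config.out_dir``.
    """
    if config.mode == "simulate":
        bundle = _simulate_bundle(config)
    elif config.mode in ("replicate", "sensitivity"):
        bundle = _replicate_bundle(config)
        if config.mode == "sensitivity":
            bundle = {"sensitivity": bundle["sensitivity"], "_extra": bundle["_extra"]}
    else:  # pragma: no cover - guarded by RunConfig
        raise ConfigurationError(f"unknown mode {config.mode!r}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    extra = bundle.pop("_extra", {})
    written = []
    for name, df in bundle.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, encoding="utf-8")
        written.append(path.name)

    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "currency": config.currency,
        "config_hash": _config_hash(config),
        "outputs": written,
        "versions": {
            "screensim": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "analytic_assumptions": {
            "arm3_precision_equals_arm1": True,
            "mag_matched_precision": 0.5,
            "no_discounting": True,
        },
        **extra,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest
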