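"""CSV readers/writers and run configuration.

The replication inputs are the CSV files of the public study deposit, read
by their published names ("Time on task data.csv", "Base case analysis
data.csv", "Sensitivity analysis – Precision.csv", "Sensitivity analysis –
Time on task") with both exact and normalised-name lookup (the deposit uses
an en-dash).  Because the deposit's exact column headers cannot be
hard-coded sight unseen, every reader validates against a per-role column
map that callers can override with their own mapping.

Packaged synthetic stand-ins for the deposit (``synthetic_base_case.csv``
etc.) use the same schemas, so the replicate pipeline runs out of the box.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import yaml

from .costing import UnitCost
from .exceptions import ConfigurationError, SchemaError

__all__ = [
    "OSF_FILENAMES",
    "ROLE_COLUMNS",
    "RunConfig",
    "read_osf_csv",
    "find_osf_file",
    "load_unit_cost",
    "packaged_data_path",
]

Role = Literal["timeontask", "basecase", "sa_precision", "sa_time"]

#: Published deposit filenames per role (note the en-dash in the SA names).
OSF_FILENAMES: dict[str, str] = {
    "timeontask": "Time on task data.csv",
    "basecase": "Base case analysis data.csv",
    "sa_precision": "Sensitivity analysis – Precision.csv",
    "sa_time": "Sensitivity analysis – Time on task.csv",
}

#: Packaged synthetic stand-ins with the same schemas.
_SYNTHETIC_FILENAMES: dict[str, str] = {
    "timeontask": "synthetic_time_on_task.csv",
    "basecase": "synthetic_base_case.csv",
    "sa_precision": "synthetic_sa_precision.csv",
    "sa_time": "synthetic_time_on_task.csv",
}

#: Expected columns per role: (required, numeric).
ROLE_COLUMNS: dict[str, tuple[list[str], list[str]]] = {
    "timeontask": (
        ["arm_id", "screen_hours_per_100"],
        ["arm_id", "screen_hours_per_100", "search_hours_per_week", "dedup_hours_per_week"],
    ),
    "basecase": (
        ["arm_id", "screened", "includes", "gold_total"],
        ["arm_id", "screened", "includes", "gold_total",
         "search_hours_per_week", "dedup_hours_per_week", "screen_hours_per_100"],
    ),
    "sa_precision": (["quantity", "value"], ["value"]),
    "sa_time": (["arm_id", "screen_hours_per_100"], ["arm_id", "screen_hours_per_100"]),
}


def _normalise_name(name: str) -> str:
    s = unicodedata.normalize("NFKC", name)
    s = s.replace("–", "-").replace("—", "-")
    return " ".join(s.casefold().split())


def find_osf_file(directory: str | Path, role: str) -> Path:
    """Locate the deposit CSV for a role by exact or normalised name."""
    directory = Path(directory)
    if role not in OSF_FILENAMES:
        raise ConfigurationError(f"unknown role {role!r}; expected one of {sorted(OSF_FILENAMES)}")
    exact = directory / OSF_FILENAMES[role]
    if exact.exists():
        return exact
    wanted = _normalise_name(OSF_FILENAMES[role])
    wanted_stem = _normalise_name(Path(OSF_FILENAMES[role]).stem)
    for p in sorted(directory.glob("*.csv")):
        if _normalise_name(p.name) == wanted or _normalise_name(p.stem) == wanted_stem:
            return p
    raise FileNotFoundError(f"no file matching {OSF_FILENAMES[role]!r} in {directory}")


def read_osf_csv(
    path: str | Path,
    expected_role: str,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate one replication-input CSV.

    ``column_map`` renames file columns to canonical names
    (``{file_column: canonical_column}``) before validation, so deposits
    with different headers can be read without code changes.  Raises
    :class:`SchemaError` naming expected vs found columns, or the offending
    cell on a parse failure.
    """
    if expected_role not in ROLE_COLUMNS:
        raise ConfigurationError(f"unknown role {expected_role!r}")
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    if column_map:
        df = df.rename(columns=dict(column_map))
    required, numeric = ROLE_COLUMNS[expected_role]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {missing}; expected {required}, found {list(df.columns)}"
        )
    if len(df) == 0:
        raise SchemaError(f"{path.name}: no data rows")
    for c in numeric:
        if c not in df.columns:
            continue
        parsed = pd.to_numeric(df[c], errors="coerce")
        bad = parsed.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"{path.name}: non-numeric value {df.loc[row, c]!r} at row {row}, column {c!r}")
        df[c] = parsed
    return df


def packaged_data_path(name: str) -> Path:
    """Path of a packaged data file (arms.yaml, synthetic stand-ins, ...)."""
    with resources.as_file(resources.files("screensim.data") / name) as p:
        return Path(p)


def load_synthetic_inputs(role: str, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read the packaged synthetic stand-in for a deposit role."""
    return read_osf_csv(packaged_data_path(_SYNTHETIC_FILENAMES[role]), role, column_map)


def load_unit_cost(currency: str = "GBP", path: str | Path | None = None) -> UnitCost:
    """Hourly unit cost for a currency from a YAML config (packaged default)."""
    p = Path(path) if path is not None else packaged_data_path("unit_costs.yaml")
    data = yaml.safe_load(p.read_text(encoding="utf-8"))
    try:
        rate = float(data["currencies"][currency])
    except KeyError as exc:
        raise ConfigurationError(f"no rate for currency {currency!r} in {p}") from exc
    return UnitCost(currency=currency, hourly_rate=rate)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: Literal["simulate", "replicate", "sensitivity"]
    out_dir: Path
    seed: int | None = None
    currency: str = "GBP"
    generator: dict = field(default_factory=dict)  # simulate: GeneratorParams kwargs
    input_dir: Path | None = None                  # replicate/sensitivity: deposit dir
    arm_subset: list[int] | None = None
    column_maps: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.mode not in ("simulate", "replicate", "sensitivity"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate":
            if self.seed is None:
                raise ConfigurationError("simulate mode requires a seed")
            if "weekly_me_results" not in self.generator:
                raise ConfigurationError(
                    "simulate mode requires generator.weekly_me_results (no canonical default)"
                )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "input_dir" in data and data["input_dir"] is not None:
            data["input_dir"] = Path(data["input_dir"])
        return cls(**data)
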