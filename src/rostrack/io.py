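"""Shared CSV/JSON/YAML readers, writers, and run configuration.

CSV inputs use a header row, period decimal separator, UTF-8.  Reports are
written as JSON (machine-readable, stable field order, full-precision floats
plus display-rounded twins) or CSV.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .exceptions import SchemaError

# column -> kind; "float?" marks a nullable numeric column
TITRATION_SCHEMA = {"dmpo_mM": "float", "dmpoh_uM": "float"}
DECAY_SCHEMA = {"time_min": "float", "intensity": "float"}
STANDARDS_SCHEMA = {"conc_uM": "float", "signal": "float"}
SAMPLES_SCHEMA = {"sample_id": "str", "signal": "float"}
BUDGET_SCHEMA = {
    "condition": "str", "let_keV_um": "float?", "total_oh": "float",
    "sparse_oh": "float", "sparse_density": "float", "sparse_conc": "float",
    "h2o2": "float", "o2_consumption": "float", "total_oxidation": "float",
}
HYPOXIC_SCHEMA = {"let_keV_um": "float", "total_oxidation": "float"}
DEPTH_SCHEMA = {"depth_mm": "float", "let_keV_um": "float",
                "dose_rate_Gy_min": "float"}

_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+$")


def read_table(path: str | Path, schema: Mapping[str, str]) -> pd.DataFrame:
    """Read and validate a CSV table against a column schema.

    Raises :class:`SchemaError` naming the offending column and 1-based data
    row for missing columns, non-numeric cells, decimal commas, or an empty
    file.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file does not exist")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")

    out: dict[str, Any] = {}
    for col, kind in schema.items():
        raw = df[col]
        if kind == "str":
            out[col] = raw.astype(str)
            continue
        values = []
        for i, cell in enumerate(raw, start=1):
            cell = cell.strip()
            if cell == "":
                if kind == "float?":
                    values.append(float("nan"))
                    continue
                raise SchemaError(f"{path}: row {i}, column {col!r}: empty cell")
            if _DECIMAL_COMMA.match(cell):
                raise SchemaError(
                    f"{path}: row {i}, column {col!r}: {cell!r} uses a decimal "
                    "comma; use a period decimal separator")
            try:
                values.append(float(cell))
            except ValueError:
                raise SchemaError(
                    f"{path}: row {i}, column {col!r}: {cell!r} is not numeric"
                ) from None
        out[col] = values
    return pd.DataFrame(out)


def _display_twins(obj: Any) -> Any:
    """Recursively add 2-decimal display twins next to float leaves."""
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    if isinstance(obj, Mapping):
        out: dict[str, Any] = {}
        for key, value in obj.items():
            out[key] = _display_twins(value)
            if isinstance(value, float):
                out[f"{key}_display"] = round(value, 2)
        return out
    if isinstance(obj, (list, tuple)):
        return [_display_twins(v) for v in obj]
    return obj


def write_report(results: Mapping[str, Any], path: str | Path,
                 fmt: str = "json") -> Path:
    """Write an analysis report with stable field order.

    JSON keeps full-precision floats and adds ``*_display`` twins rounded to
    the 2-decimal reporting convention; CSV writes one flat row per top-level
    record.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = _display_twins(results)
        path.write_text(json.dumps(payload, indent=2, sort_keys=False,
                                   allow_nan=True) + "\n", encoding="utf-8")
    elif fmt == "csv":
        flat = results
        if is_dataclass(flat) and not isinstance(flat, type):
            flat = asdict(flat)
        pd.json_normalize(dict(flat)).to_csv(path, index=False)
    else:
        raise SchemaError(f"unknown report format {fmt!r}")
    return path


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text(encoding="utf-8"))


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (YAML sidecar or CLI flags).

    Unknown keys are rejected so typos fail loudly.
    """

    dose_Gy: float | None = None
    modality: str | None = None
    let_keV_um: float | None = None
    exposure_s: float = 60.0
    seed: int | None = None
    reference_density_per_um: float = 1000.0
    plateau_level: float = 0.35
    plateau_onset_keV_um: float = 70.0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.modality is not None and self.modality not in {"xray", "carbon"}:
            raise SchemaError(f"modality must be 'xray' or 'carbon', got {self.modality!r}")
        if self.dose_Gy is not None and self.dose_Gy <= 0:
            raise SchemaError("dose_Gy must be > 0")
        if self.exposure_s <= 0:
            raise SchemaError("exposure_s must be > 0")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config file into a :class:`RunConfig` (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    allowed = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {', '.join(sorted(unknown))}")
    return RunConfig(**raw)
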