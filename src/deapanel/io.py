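"""Schema-validated CSV I/O and YAML run configuration.

The on-disk panel dialect is UTF-8 CSV with a header row, '.' decimal
separator, and one row per jurisdiction-year.  Floats are written with
Python's shortest-roundtrip representation, so write -> read is the
identity and repeated runs are byte-comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from deapanel.synthetic import CONTEXT_COLS, INPUT_COLS, OUTPUT_COLS


@dataclass(frozen=True)
class PanelSchema:
    """Ordered column contract for the jurisdiction-year panel table."""

    id_cols: tuple[str, ...] = ("jurisdiction_id", "year", "region")
    input_cols: tuple[str, ...] = tuple(INPUT_COLS)
    output_cols: tuple[str, ...] = tuple(OUTPUT_COLS)
    context_cols: tuple[str, ...] = tuple(CONTEXT_COLS)

    @property
    def columns(self) -> list[str]:
        return (
            list(self.id_cols)
            + list(self.input_cols)
            + list(self.output_cols)
            + list(self.context_cols)
        )


SCHEMA = PanelSchema()


class SchemaError(ValueError):
    """Raised when a panel violates the schema; message lists every failure."""


def validate_panel(panel: pd.DataFrame, schema: PanelSchema = SCHEMA) -> pd.DataFrame:
    """Validate (and type-coerce) a panel table in place; raise on violations.

    Every failing cell is reported with its row index, so a bad export is
    diagnosable in one pass.
    """
    problems: list[str] = []
    expected = set(schema.columns)
    got = set(panel.columns)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise SchemaError(
            f"column set mismatch: missing={missing} unexpected={extra}"
        )
    panel = panel[schema.columns].copy()
    numeric_cols = [c for c in schema.columns if c != "jurisdiction_id"]
    for col in numeric_cols:
        coerced = pd.to_numeric(panel[col], errors="coerce")
        bad = panel.index[coerced.isna() & panel[col].notna()]
        for i in bad:
            problems.append(f"row {i}: {col}={panel.at[i, col]!r} not numeric")
        panel[col] = coerced
    for col in ("year", "region"):
        try:
            panel[col] = panel[col].astype("int64")
        except (ValueError, TypeError):
            pass  # non-integral values are reported below as violations

    dup = panel.duplicated(subset=["jurisdiction_id", "year"])
    for i in panel.index[dup]:
        problems.append(
            f"row {i}: duplicate (jurisdiction_id, year) = "
            f"({panel.at[i, 'jurisdiction_id']}, {panel.at[i, 'year']})"
        )
    for col in list(schema.input_cols) + list(schema.output_cols):
        neg = panel.index[panel[col] < 0]
        for i in neg:
            problems.append(f"row {i}: {col}={panel.at[i, col]} is negative")
    over = panel.index[panel["controlled_patients"] > panel["treated_patients"] + 1e-9]
    for i in over:
        problems.append(
            f"row {i}: controlled_patients={panel.at[i, 'controlled_patients']} "
            f"exceeds treated_patients={panel.at[i, 'treated_patients']}"
        )
    bad_gini = panel.index[(panel["gini"] < 0) | (panel["gini"] > 1)]
    for i in bad_gini:
        problems.append(f"row {i}: gini={panel.at[i, 'gini']} outside [0, 1]")
    for col in ("phc_coverage", "indigenous_pct", "gov_support", "employment"):
        bad = panel.index[(panel[col] < 0) | (panel[col] > 100)]
        for i in bad:
            problems.append(f"row {i}: {col}={panel.at[i, col]} outside [0, 100]")
    nan_rows = panel.index[panel[numeric_cols].isna().any(axis=1)]
    for i in nan_rows:
        cols = [c for c in numeric_cols if pd.isna(panel.at[i, c])]
        problems.append(f"row {i}: missing values in {cols}")
    if problems:
        raise SchemaError(
            f"{len(problems)} schema violation(s):\n" + "\n".join(problems)
        )
    return panel


def load_panel(path: str | Path, schema: PanelSchema = SCHEMA) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    panel = pd.read_csv(path, float_precision="round_trip")
    if panel.empty:
        raise SchemaError(f"{path} is empty")
    return validate_panel(panel, schema)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    write_csv(panel, path)


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    # %.17g round-trips float64 exactly (pandas default is 16 digits)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Nested pipeline configuration with one master seed.

    Per-stage seeds are derived from the master seed by fixed offsets so
    each stage is independently reproducible.
    """

    seed: int = 0
    outdir: str = "deapanel_output"
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "describe", "dea", "bootstrap",
                                 "rf", "regional", "report"]
    )
    synthetic: dict = field(default_factory=dict)
    dea: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)
    determinants: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    panel_path: str | None = None  # load instead of simulate

    # fixed per-stage seed offsets
    SEED_OFFSETS = {"simulate": 0, "bootstrap": 10_000, "rf": 20_000}

    def stage_seed(self, stage: str) -> int:
        return self.seed + self.SEED_OFFSETS.get(stage, 0)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
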