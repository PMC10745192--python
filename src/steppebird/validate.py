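"""CSV schemas and dataset validation.

All pipeline artifacts are plain CSV (field-ecology convention): columns
typed below, dates as integer Julian days, decimals with '.' separator.
``validate_dataset`` checks schema (columns, types, ranges), enumerated
values, and referential integrity (every detection/visit/count row must
reference a surveyed plot-year), reporting every violation with its row
number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("steppebird")

__all__ = ["SCHEMAS", "validate_dataset", "ValidationReport",
           "read_csv", "write_csv"]

# column -> (dtype kind, allowed range or enum); None = free
SCHEMAS: dict[str, dict] = {
    "plots": {
        "required": ["plot_id", "year", "enrollment", "shrub_cover",
                     "gpp_mean", "lai_mean", "precip_mean", "tmax", "tmin"],
        "enums": {"enrollment": {"SGI", "non-SGI"}},
        "ranges": {"shrub_cover": (0.0, 1.0)},
        "unique": ["plot_id", "year"],
    },
    "nest_detections": {
        "required": ["plot_id", "year", "species", "transect_id",
                     "distance_m", "opportunistic"],
        "ranges": {"distance_m": (0.0, None)},
    },
    "effort": {
        "required": ["plot_id", "year", "transect_id", "length_m",
                     "rounds"],
        "ranges": {"length_m": (0.0, None), "rounds": (1, None)},
    },
    "nest_visits": {
        "required": ["nest_id", "plot_id", "year", "species", "visit_day",
                     "stage", "status"],
        "enums": {"stage": {"egg", "nestling"},
                  "status": {"active", "fledged", "failed"}},
    },
    "ddo_counts": {
        "required": ["plot_id", "year", "visit", "species",
                     "observer_primary", "observer_secondary", "x1", "x2"],
        "ranges": {"x1": (0, None), "x2": (0, None)},
    },
}


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    def add(self, table: str, row: int | None, kind: str, message: str):
        self.violations.append(
            {"table": table, "row": row, "kind": kind, "message": message})
        log.warning("validation [%s] %s row %s: %s", kind, table, row,
                    message)

    @property
    def ok(self) -> bool:
        return not self.violations

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.violations,
            columns=["table", "row", "kind", "message"])

    def __repr__(self):
        return (f"ValidationReport(ok={self.ok}, "
                f"violations={len(self.violations)})")


def _check_table(name: str, df: pd.DataFrame,
                 report: ValidationReport) -> None:
    schema = SCHEMAS[name]
    for col in schema["required"]:
        if col not in df.columns:
            report.add(name, None, "schema", f"missing column {col!r}")
    for col, allowed in schema.get("enums", {}).items():
        if col not in df.columns:
            continue
        bad = ~df[col].astype(str).isin(allowed)
        for idx in df.index[bad]:
            report.add(name, int(idx), "enum",
                       f"{col}={df.loc[idx, col]!r} not in {sorted(allowed)}")
    for col, (lo, hi) in schema.get("ranges", {}).items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if lo is not None:
            bad |= vals < lo
        if hi is not None:
            bad |= vals > hi
        for idx in df.index[bad]:
            report.add(name, int(idx), "range",
                       f"{col}={df.loc[idx, col]!r} outside "
                       f"[{lo}, {hi if hi is not None else 'inf'}]")
    unique = schema.get("unique")
    if unique and all(c in df.columns for c in unique):
        dup = df.duplicated(subset=unique)
        for idx in df.index[dup]:
            report.add(name, int(idx), "unique",
                       f"duplicate key {tuple(df.loc[idx, unique])}")


def validate_dataset(tables: dict[str, pd.DataFrame],
                     strict: bool = False) -> ValidationReport:
    """Validate a set of pipeline tables against their schemas.

    ``tables`` maps schema name (see :data:`SCHEMAS`) to a DataFrame;
    unknown names are ignored.  Referential integrity requires a
    ``plots`` table.  In strict mode any violation raises.
    """
    report = ValidationReport()
    for name, df in tables.items():
        if name in SCHEMAS:
            _check_table(name, df, report)

    plots = tables.get("plots")
    if plots is not None and {"plot_id", "year"} <= set(plots.columns):
        plot_keys = set(zip(plots["plot_id"], plots["year"]))
        for name in ("nest_detections", "nest_visits", "ddo_counts",
                     "effort"):
            df = tables.get(name)
            if df is None or not {"plot_id", "year"} <= set(df.columns):
                continue
            for idx, (pid, yr) in enumerate(zip(df["plot_id"], df["year"])):
                if (pid, yr) not in plot_keys:
                    report.add(name, idx, "integrity",
                               f"({pid!r}, {yr!r}) has no plot row")
    if strict and not report.ok:
        raise ValueError(
            f"dataset failed validation with {len(report.violations)} "
            "violation(s); first: "
            f"{report.violations[0]}")
    return report


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps write/read lossless for IEEE doubles
    return pd.read_csv(path, float_precision="round_trip")
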