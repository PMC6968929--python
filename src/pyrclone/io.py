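"""Readers and writers for lineage tables, run configs and result reports.

The canonical lineage table is a UTF-8 CSV/TSV with a header row and the
required columns ``lineage_id, method, area, age, l23, l4, l5, l6``.
Optional columns: ``a_l23..a_l6`` and ``b_l23..b_l6`` (the two MADM reporter
sub-clones) and ``n_ccpn, n_scpn, n_cthpn, n_hpn`` (projection-subtype
counts).  Counts must be literal non-negative integers; a blank cell is an
error, never silently a zero, because zero counts are semantically loaded
(they drive the censoring mask of the occupancy model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .lineage import LayerCounts, Lineage

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_lineage_table",
    "write_lineage_table",
    "lineages_to_frame",
    "write_report",
    "read_report",
    "read_config",
]

REQUIRED_COLUMNS = ("lineage_id", "method", "area", "age", "l23", "l4", "l5", "l6")
SUBCLONE_A = ("a_l23", "a_l4", "a_l5", "a_l6")
SUBCLONE_B = ("b_l23", "b_l4", "b_l5", "b_l6")
SUBTYPE_COLUMNS = {"n_ccpn": "CCPN", "n_scpn": "SCPN", "n_cthpn": "CThPN", "n_hpn": "HPN"}


class SchemaError(ValueError):
    """A table does not match the expected column schema."""


_KNOWN_CONFIG_KEYS = frozenset(
    {
        "seed",
        "input",
        "output",
        "stages",
        "min_size",
        "max_size",
        "n_repeats",
        "n_draws",
        "burn_in",
        "thinning",
        "n_max",
        "alpha",
        "beta_a",
        "beta_b",
        "simulator_spec",
        "area",
    }
)


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    seed: int
    input: Optional[str] = None
    output: Optional[str] = None
    stages: Sequence[str] = field(default_factory=list)
    options: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        unknown = set(raw) - _KNOWN_CONFIG_KEYS
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise SchemaError("config must declare a seed")
        options = {
            k: v for k, v in raw.items()
            if k not in ("seed", "input", "output", "stages")
        }
        return cls(
            seed=int(raw["seed"]),
            input=raw.get("input"),
            output=raw.get("output"),
            stages=list(raw.get("stages", [])),
            options=options,
        )


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration, rejecting unknown keys."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"config file {path} does not hold a key/value mapping")
    return RunConfig.from_mapping(raw)


def _parse_count(value: Any, row: int, column: str) -> int:
    if pd.isna(value) or (isinstance(value, str) and value.strip() == ""):
        raise ValueError(
            f"row {row}: column {column!r} is blank; counts must be explicit integers"
        )
    try:
        as_float = float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row}: column {column!r} is not a number: {value!r}") from exc
    if as_float != int(as_float):
        raise ValueError(f"row {row}: column {column!r} is not an integer: {value!r}")
    n = int(as_float)
    if n < 0:
        raise ValueError(f"row {row}: column {column!r} is negative: {n}")
    return n


def read_lineage_table(
    path: str | Path,
    dialect: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[Lineage]:
    """Read a lineage table into a list of :class:`Lineage`.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    dialect
        "csv" or "tsv"; inferred from the file suffix when omitted.
    column_map
        Optional mapping from the file's column names to canonical ones, for
        tables exported with non-canonical headers.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=True)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    has_subclones = all(c in frame.columns for c in SUBCLONE_A + SUBCLONE_B)
    subtype_cols = [c for c in SUBTYPE_COLUMNS if c in frame.columns]

    lineages: list[Lineage] = []
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2  # header is line 1
        counts = LayerCounts(
            l23=_parse_count(row["l23"], rownum, "l23"),
            l4=_parse_count(row["l4"], rownum, "l4"),
            l5=_parse_count(row["l5"], rownum, "l5"),
            l6=_parse_count(row["l6"], rownum, "l6"),
        )
        sub_a = sub_b = None
        if has_subclones and not all(pd.isna(row[c]) for c in SUBCLONE_A + SUBCLONE_B):
            sub_a = LayerCounts(
                *[_parse_count(row[c], rownum, c) for c in SUBCLONE_A]
            )
            sub_b = LayerCounts(
                *[_parse_count(row[c], rownum, c) for c in SUBCLONE_B]
            )
        subtypes = None
        if subtype_cols and not all(pd.isna(row[c]) for c in subtype_cols):
            subtypes = {
                SUBTYPE_COLUMNS[c]: _parse_count(row[c], rownum, c)
                for c in subtype_cols
            }
        lineages.append(
            Lineage(
                id=str(row["lineage_id"]),
                method=str(row["method"]),
                area=str(row["area"]),
                age=str(row["age"]),
                counts=counts,
                subclone_a=sub_a,
                subclone_b=sub_b,
                subtype_counts=subtypes,
            )
        )
    return lineages


def lineages_to_frame(dataset: Sequence[Lineage]) -> pd.DataFrame:
    """Render lineages as a canonical-schema DataFrame."""
    records = []
    any_sub = any(lin.subclone_a is not None for lin in dataset)
    any_subtype = any(lin.subtype_counts is not None for lin in dataset)
    for lin in dataset:
        rec: dict[str, Any] = {
            "lineage_id": lin.id,
            "method": lin.method,
            "area": lin.area,
            "age": lin.age,
            "l23": lin.counts.l23,
            "l4": lin.counts.l4,
            "l5": lin.counts.l5,
            "l6": lin.counts.l6,
        }
        if any_sub:
            for cols, sub in ((SUBCLONE_A, lin.subclone_a), (SUBCLONE_B, lin.subclone_b)):
                for col in cols:
                    rec[col] = getattr(sub, col.split("_", 1)[1]) if sub else None
        if any_subtype:
            for col, name in SUBTYPE_COLUMNS.items():
                rec[col] = (
                    lin.subtype_counts.get(name, 0) if lin.subtype_counts else None
                )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_lineage_table(
    dataset: Sequence[Lineage], path: str | Path, dialect: Optional[str] = None
) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if dialect == "tsv" else ","
    lineages_to_frame(dataset).to_csv(path, sep=sep, index=False)


def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    """Serialize structured results as pretty-printed JSON.

    Reports are plain text for diffability; numpy scalars/arrays are coerced
    to native types.
    """

    def _coerce(obj: Any) -> Any:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot serialize {type(obj).__name__}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_coerce)
        fh.write("\n")


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
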