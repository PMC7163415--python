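"""Reading and writing the five-sheet bundle.

Sheets travel as CSV (default) or Parquet with the column contracts in
:mod:`wardflow.schemas`.  Reading is defensive: a missing required
column is a hard error naming the column, while malformed *rows* are
collected into a reject report (sheet, row, column, reason) instead of
being silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schemas import SHEET_SCHEMAS, SHEETS

__all__ = ["SchemaError", "RawBundle", "write_sheets", "read_sources", "REJECT_COLUMNS"]

REJECT_COLUMNS = ["sheet", "row", "column", "reason"]

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}")
_TIME_RE = re.compile(r"^\d{2}:\d{2}:\d{2}$")


class SchemaError(ValueError):
    """Input does not satisfy the sheet schema (e.g. missing column)."""


@dataclass
class RawBundle:
    """Typed five-sheet bundle plus the reject report."""

    activity: pd.DataFrame
    nurses: pd.DataFrame
    working_hours: pd.DataFrame
    movements: pd.DataFrame
    discharge: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=REJECT_COLUMNS)
    )

    def sheet(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def write_sheets(sheets: dict[str, pd.DataFrame], outdir, fmt: str = "csv") -> dict[str, Path]:
    """Write the five sheets to ``outdir`` as ``<sheet>.<fmt>``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in SHEETS:
        df = sheets[name]
        path = outdir / f"{name}.{ 'parquet' if fmt == 'parquet' else 'csv'}"
        if fmt == "parquet":
            df.to_parquet(path, index=False)
        elif fmt == "csv":
            df.to_csv(path, index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'parquet'")
        paths[name] = path
    return paths


def _load_raw(path: Path) -> pd.DataFrame:
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
        return df.astype(object).where(df.notna(), np.nan)
    return pd.read_csv(path, dtype=str)


def _coerce_sheet(df: pd.DataFrame, sheet: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate/convert one sheet; returns (typed frame, rejects)."""
    schema = SHEET_SCHEMAS[sheet]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"sheet {sheet!r}: missing required column(s): {', '.join(missing)}")
    df = df[list(schema)].reset_index(drop=True)
    bad_reason: dict[int, tuple[str, str]] = {}

    def flag(mask: pd.Series, col: str, reason: str) -> None:
        for i in df.index[mask]:
            bad_reason.setdefault(int(i), (col, reason))

    out = {}
    for col, kind in schema.items():
        nullable = kind.endswith("?")
        k = kind.rstrip("?")
        s = df[col]
        isna = s.isna() | (s.astype(str).str.strip() == "")
        if not nullable and k == "str":
            flag(isna, col, "missing value")
        if k == "str":
            out[col] = s.where(~isna, np.nan).astype(object)
        elif k == "date":
            parsed = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
            flag(parsed.isna(), col, "unparseable date (expected YYYY-MM-DD)")
            out[col] = parsed
        elif k == "time":
            ok = s.astype(str).str.match(_TIME_RE).fillna(False)
            td = pd.to_timedelta(s.where(ok), errors="coerce")
            valid = ok & td.notna() & (td < pd.Timedelta(days=1))
            flag(~valid, col, "unparseable time (expected HH:MM:SS)")
            out[col] = td
        elif k == "int":
            parsed = pd.to_numeric(s, errors="coerce")
            flag(parsed.isna() | (parsed % 1 != 0), col, "not an integer")
            out[col] = parsed
        elif k == "float":
            parsed = pd.to_numeric(s, errors="coerce")
            flag(parsed.isna() | (parsed < 0), col, "not a nonnegative number")
            out[col] = parsed
        elif k == "bool":
            mapped = s.map(
                {
                    "True": True, "False": False, "true": True, "false": False,
                    "1": True, "0": False, True: True, False: False,
                }
            )
            flag(mapped.isna(), col, "not a boolean")
            out[col] = mapped
        elif k == "icd10":
            ok = s.astype(str).str.match(_ICD_RE).fillna(False)
            flag(~ok, col, "not an ICD-10 code")
            out[col] = s.astype(object)
        elif k.startswith("enum:"):
            allowed = set(k.split(":", 1)[1].split("|"))
            ok = s.isin(allowed)
            flag(~ok, col, f"value outside {{{', '.join(sorted(allowed))}}}")
            out[col] = s.astype(object)
        else:  # pragma: no cover - schema author error
            raise SchemaError(f"unknown schema kind {kind!r}")

    typed = pd.DataFrame(out)
    if bad_reason:
        bad_idx = sorted(bad_reason)
        rejects = pd.DataFrame(
            [(sheet, i, bad_reason[i][0], bad_reason[i][1]) for i in bad_idx],
            columns=REJECT_COLUMNS,
        )
        typed = typed.drop(index=bad_idx).reset_index(drop=True)
    else:
        rejects = pd.DataFrame(columns=REJECT_COLUMNS)

    # sheet-specific integer domains
    if sheet == "nurses" and not typed.empty:
        outside = ~typed["group"].isin([1, 2, 3, 4, 5])
        if outside.any():
            extra = pd.DataFrame(
                [("nurses", int(i), "group", "group outside 1..5") for i in typed.index[outside]],
                columns=REJECT_COLUMNS,
            )
            rejects = pd.concat([rejects, extra], ignore_index=True)
            typed = typed[~outside].reset_index(drop=True)
        typed["group"] = typed["group"].astype(int)
    return typed, rejects


def read_sources(indir, fmt: str | None = None) -> RawBundle:
    """Read and type-check the five sheets from a directory.

    ``fmt`` is inferred from the files present when not given.  Raises
    :class:`SchemaError` for missing files/columns; malformed rows land
    in ``bundle.rejects``.
    """
    indir = Path(indir)
    typed = {}
    all_rejects = []
    for name in SHEETS:
        candidates = (
            [indir / f"{name}.{fmt}"]
            if fmt
            else [indir / f"{name}.csv", indir / f"{name}.parquet"]
        )
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise SchemaError(f"input sheet not found: {candidates[0]}")
        frame, rejects = _coerce_sheet(_load_raw(path), name)
        typed[name] = frame
        all_rejects.append(rejects)
    rejects = pd.concat(all_rejects, ignore_index=True)
    return RawBundle(rejects=rejects, **typed)
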