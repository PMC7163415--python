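"""Patient turnover: per-slot ADT event counts and census-normalised
ratios.

Admission is any entry to the hospital and discharge any exit; transfers
(movement of an admitted patient between units) split into transfers-in
and transfers-out of each unit, so one transfer contributes exactly two
events hospital-wide.  An event at clock time tau belongs to the slot
whose half-open window [t, t + interval) contains tau.  Because units
differ in size, counts are divided by the number of patients present at
the data point, giving turnover ratios on a common scale; ratios at
zero-census points are missing (the counts are kept) and may exceed one
by design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["count_events", "normalize", "aggregate_profiles", "EVENT_COUNT_COLUMNS"]

EVENT_COUNT_COLUMNS = ["n_admissions", "n_discharges", "n_transfers_in", "n_transfers_out"]
RATIO_COLUMNS = ["r_admissions", "r_discharges", "r_transfers_in", "r_transfers_out"]

_KIND_TO_COLUMN = {
    ("entry", "admission"): "n_admissions",
    ("entry", "transfer_in"): "n_transfers_in",
    ("exit", "discharge"): "n_discharges",
    ("exit", "transfer_out"): "n_transfers_out",
}


def count_events(stays: pd.DataFrame, grid) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-slot counts of admissions, discharges and transfers in/out.

    Returns ``(counts, excluded)`` where ``excluded`` logs events whose
    timestamp falls outside the grid span (they are not counted).
    """
    ts = grid.timestamps()
    t = ts.to_numpy()
    span_end = t[-1] + np.timedelta64(grid.interval_minutes * 60, "s")
    unit_index = {u: i for i, u in enumerate(grid.units)}
    unknown = sorted(set(stays["unit_id"]) - set(grid.units)) if not stays.empty else []
    if unknown:
        raise ValueError(f"stays reference units absent from the grid: {', '.join(unknown)}")

    counts = np.zeros((len(grid.units), len(t), 4), dtype=np.int64)
    col_index = {c: j for j, c in enumerate(EVENT_COUNT_COLUMNS)}
    excluded_rows = []

    def _tally(when: np.ndarray, units: np.ndarray, cols: np.ndarray, kinds: np.ndarray):
        slot = np.searchsorted(t, when, side="right") - 1
        ok = (slot >= 0) & (when < span_end)
        for w, u, c, k in zip(when[~ok], units[~ok], cols[~ok], kinds[~ok]):
            excluded_rows.append((u, pd.Timestamp(w), k, "outside grid span"))
        ui = np.array([unit_index[u] for u in units[ok]], dtype=np.int64)
        ci = np.array([col_index[c] for c in cols[ok]], dtype=np.int64)
        np.add.at(counts, (ui, slot[ok], ci), 1)

    if not stays.empty:
        entry_cols = stays["entry_kind"].map(
            {"admission": "n_admissions", "transfer_in": "n_transfers_in"}
        ).to_numpy()
        exit_cols = stays["exit_kind"].map(
            {"discharge": "n_discharges", "transfer_out": "n_transfers_out"}
        ).to_numpy()
        units = stays["unit_id"].to_numpy()
        _tally(stays["entry_ts"].to_numpy(), units, entry_cols, stays["entry_kind"].to_numpy())
        _tally(stays["exit_ts"].to_numpy(), units, exit_cols, stays["exit_kind"].to_numpy())

    frames = []
    for u, i in unit_index.items():
        frame = pd.DataFrame({"unit_id": u, "timestamp": ts})
        for c, j in col_index.items():
            frame[c] = counts[i, :, j]
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    excluded = pd.DataFrame(
        excluded_rows, columns=["unit_id", "timestamp", "kind", "reason"]
    )
    return out, excluded


def normalize(events: pd.DataFrame, census: pd.DataFrame) -> pd.DataFrame:
    """Divide each event count by the patient census at the same point.

    ``events`` and ``census`` must share the same (unit, timestamp)
    lattice; a mismatch is an error.  Zero-census points yield missing
    ratios while the counts are preserved.
    """
    merged = events.merge(
        census[["unit_id", "timestamp", "n_patients"]],
        on=["unit_id", "timestamp"],
        how="left",
        validate="one_to_one",
    )
    if merged["n_patients"].isna().any() or len(merged) != len(census):
        raise ValueError("event and census tables are on different grids")
    denom = merged["n_patients"].where(merged["n_patients"] > 0)
    for n_col, r_col in zip(EVENT_COUNT_COLUMNS, RATIO_COLUMNS):
        merged[r_col] = merged[n_col] / denom
    return merged


def aggregate_profiles(
    points: pd.DataFrame, unit_department: dict[str, str]
) -> pd.DataFrame:
    """Department turnover profiles by daytype and slot-of-day.

    Each unit first contributes its own mean ratio per (daytype, slot);
    the department profile is the mean across its units (missing ratios
    excluded).  Output is long over event types, with exits
    (discharges, transfers out) additionally given a negative
    ``signed_ratio`` for the leaving side of bar charts; mean counts
    stay unsigned.
    """
    p = points.assign(
        department=points["unit_id"].map(unit_department),
        daytype=np.where(points["timestamp"].dt.dayofweek >= 5, "weekend", "weekday"),
        tod=points["timestamp"].dt.strftime("%H:%M"),
    )
    unit_level = (
        p.groupby(["department", "daytype", "tod", "unit_id"], sort=True)[
            RATIO_COLUMNS + EVENT_COUNT_COLUMNS
        ]
        .mean()
        .reset_index()
    )
    dept_level = (
        unit_level.groupby(["department", "daytype", "tod"], sort=True)[
            RATIO_COLUMNS + EVENT_COUNT_COLUMNS
        ]
        .mean()
        .reset_index()
    )
    long = dept_level.melt(
        id_vars=["department", "daytype", "tod"],
        value_vars=RATIO_COLUMNS,
        var_name="event",
        value_name="mean_ratio",
    )
    long["event"] = long["event"].str.removeprefix("r_")
    count_long = dept_level.melt(
        id_vars=["department", "daytype", "tod"],
        value_vars=EVENT_COUNT_COLUMNS,
        var_name="event",
        value_name="mean_count",
    )
    count_long["event"] = count_long["event"].str.removeprefix("n_")
    long = long.merge(count_long, on=["department", "daytype", "tod", "event"])
    exits = long["event"].isin(["discharges", "transfers_out"])
    long["side"] = np.where(exits, "leaving", "incoming")
    long["signed_ratio"] = np.where(exits, -long["mean_ratio"], long["mean_ratio"])
    return long
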