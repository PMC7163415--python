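"""Interval census: patients and nurses on the unit x day x slot lattice.

Demand and supply are sampled on a fixed lattice of clock slots (default
30 minutes, i.e. 48 data points per day).  Counting is point-in-time at
the slot start with half-open membership — a patient or nurse present at
slot time *t* iff ``start <= t < end`` — so an instantaneous transfer
never double-counts a patient in two units, and a nurse on break at *t*
is not counted.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import HOURLY_GROUPS

__all__ = [
    "SlotGrid",
    "build_slot_grid",
    "count_patients",
    "count_nurses",
    "build_census",
    "daily_presence_summary",
]

#: census column per hourly nurse group
GROUP_COLUMNS = {1: "n_rn", 2: "n_lpn", 3: "n_other"}


@dataclass(frozen=True)
class SlotGrid:
    """The unit x calendar-day x slot lattice."""

    units: tuple[str, ...]
    start_date: dt.date
    end_date: dt.date
    interval_minutes: int = 30

    def __post_init__(self):
        if self.interval_minutes <= 0 or 1440 % self.interval_minutes != 0:
            raise ValueError(
                f"interval_minutes must divide 1440, got {self.interval_minutes}"
            )
        if self.end_date < self.start_date:
            raise ValueError("grid horizon empty: end_date precedes start_date")
        if not self.units:
            raise ValueError("grid needs at least one unit")

    @property
    def slots_per_day(self) -> int:
        return 1440 // self.interval_minutes

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def n_points(self) -> int:
        return len(self.units) * self.n_days * self.slots_per_day

    def timestamps(self) -> pd.DatetimeIndex:
        """All slot instants of the horizon (shared by every unit)."""
        return pd.date_range(
            self.start_date,
            pd.Timestamp(self.end_date) + pd.Timedelta(days=1),
            freq=f"{self.interval_minutes}min",
            inclusive="left",
        )

    def frame(self) -> pd.DataFrame:
        """Materialised lattice: one row per (unit, slot instant)."""
        ts = self.timestamps()
        return pd.DataFrame(
            {
                "unit_id": np.repeat(np.array(self.units, dtype=object), len(ts)),
                "timestamp": np.tile(ts.to_numpy(), len(self.units)),
            }
        )


def build_slot_grid(
    units,
    start_date: dt.date,
    end_date: dt.date,
    interval_minutes: int = 30,
) -> SlotGrid:
    """Construct the complete lattice (default 48 slots per day)."""
    return SlotGrid(
        units=tuple(units),
        start_date=pd.Timestamp(start_date).date(),
        end_date=pd.Timestamp(end_date).date(),
        interval_minutes=interval_minutes,
    )


def _check_units(df: pd.DataFrame, grid: SlotGrid, what: str) -> None:
    unknown = sorted(set(df["unit_id"]) - set(grid.units))
    if unknown:
        raise ValueError(f"{what} reference units absent from the grid: {', '.join(unknown)}")


def _interval_counts(
    starts: np.ndarray, ends: np.ndarray, ts: pd.DatetimeIndex
) -> np.ndarray:
    """Number of intervals with start <= t < end at every slot instant t."""
    t = ts.to_numpy()
    lo = np.searchsorted(t, starts, side="left")
    hi = np.searchsorted(t, ends, side="left")
    diff = np.zeros(len(t) + 1, dtype=np.int64)
    np.add.at(diff, lo, 1)
    np.add.at(diff, hi, -1)
    return np.cumsum(diff[:-1])


def _interval_coverage(
    starts: np.ndarray, ends: np.ndarray, ts: pd.DatetimeIndex, interval_minutes: int
) -> np.ndarray:
    """Average occupancy over each slot window [t, t + interval)."""
    t = ts.to_numpy()
    width = np.timedelta64(interval_minutes * 60, "s")
    out = np.zeros(len(t), dtype=float)
    w = float(interval_minutes * 60)
    for s, e in zip(starts, ends):
        lo = int(np.searchsorted(t, s, side="right")) - 1
        hi = int(np.searchsorted(t, e, side="left"))
        for i in range(max(lo, 0), min(hi, len(t))):
            ov = min(e, t[i] + width) - max(s, t[i])
            sec = ov / np.timedelta64(1, "s")
            if sec > 0:
                out[i] += sec / w
    return out


def count_patients(
    stays: pd.DataFrame, grid: SlotGrid, method: str = "point"
) -> pd.DataFrame:
    """Patient census per (unit, slot instant).

    ``method='point'`` (default) samples presence at the slot start;
    ``method='interval_mean'`` reports the mean occupancy over the slot
    window instead (an alternative offered for sensitivity checks).
    """
    if method not in ("point", "interval_mean"):
        raise ValueError(f"unknown method {method!r}")
    if not stays.empty:
        _check_units(stays, grid, "stays")
    ts = grid.timestamps()
    parts = []
    for unit in grid.units:
        sub = stays[stays["unit_id"] == unit] if not stays.empty else stays
        if sub.empty:
            counts = np.zeros(len(ts), dtype=np.int64 if method == "point" else float)
        elif method == "point":
            counts = _interval_counts(
                sub["entry_ts"].to_numpy(), sub["exit_ts"].to_numpy(), ts
            )
        else:
            counts = _interval_coverage(
                sub["entry_ts"].to_numpy(), sub["exit_ts"].to_numpy(), ts, grid.interval_minutes
            )
        parts.append(
            pd.DataFrame({"unit_id": unit, "timestamp": ts, "n_patients": counts})
        )
    return pd.concat(parts, ignore_index=True)


def count_nurses(segments: pd.DataFrame, grid: SlotGrid) -> pd.DataFrame:
    """Per-group nurse census per (unit, slot instant).

    A nurse is counted at slot *t* iff some working segment covers it
    (``start <= t < end``); a nurse on break at *t* is therefore absent.
    """
    if not segments.empty:
        _check_units(segments, grid, "segments")
    ts = grid.timestamps()
    parts = []
    for unit in grid.units:
        cols = {"unit_id": unit, "timestamp": ts}
        for g, col in GROUP_COLUMNS.items():
            sub = (
                segments[(segments["unit_id"] == unit) & (segments["group"] == g)]
                if not segments.empty
                else segments
            )
            if sub.empty:
                cols[col] = np.zeros(len(ts), dtype=np.int64)
            else:
                cols[col] = _interval_counts(
                    sub["start_ts"].to_numpy(), sub["end_ts"].to_numpy(), ts
                )
        parts.append(pd.DataFrame(cols))
    return pd.concat(parts, ignore_index=True)


def build_census(
    stays: pd.DataFrame, segments: pd.DataFrame, grid: SlotGrid
) -> pd.DataFrame:
    """Long census table: unit, timestamp, n_patients, n_rn, n_lpn, n_other."""
    pat = count_patients(stays, grid)
    nur = count_nurses(segments, grid)
    return pat.merge(nur, on=["unit_id", "timestamp"], validate="one_to_one")


def daily_presence_summary(
    daily_presence: pd.DataFrame,
    start_date: dt.date | None = None,
    end_date: dt.date | None = None,
) -> pd.DataFrame:
    """Summaries for the daily-only groups (students, external nurses).

    Per unit and group: total over the period, daily mean, daily median
    and daily maximum.  Days without a presence row count as zero, which
    is why the period bounds matter (they default to the observed date
    range).
    """
    cols = ["unit_id", "group", "total", "daily_mean", "daily_median", "daily_max"]
    if daily_presence.empty:
        return pd.DataFrame(columns=cols)
    dp = daily_presence.copy()
    dp["date"] = pd.DatetimeIndex(dp["date"]).normalize()
    start = pd.Timestamp(start_date) if start_date else dp["date"].min()
    end = pd.Timestamp(end_date) if end_date else dp["date"].max()
    days = pd.date_range(start, end, freq="D")
    rows = []
    for (unit, group), grp in dp.groupby(["unit_id", "group"]):
        series = (
            grp.set_index("date")["count"].reindex(days, fill_value=0).astype(float)
        )
        rows.append(
            {
                "unit_id": unit,
                "group": int(group),
                "total": float(series.sum()),
                "daily_mean": float(series.mean()),
                "daily_median": float(series.median()),
                "daily_max": float(series.max()),
            }
        )
    return pd.DataFrame(rows, columns=cols)
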