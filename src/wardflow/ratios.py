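"""Patient-to-nurse ratios, extreme-mismatch thresholds, and stratified
summaries.

The ratio at a data point is patients present divided by nurses of one
qualification group present at the same instant on the same unit; points
with zero nurses have a missing ratio (they are excluded from medians
and percentage denominators, but their count is reported so the
information is not lost).

"Extreme" staffing is flagged relative to each stratum's median ratio m:
extreme lower threshold ELT = m - m/2 = m/2 and extreme higher threshold
EHT = m + m/2 = 1.5 m, i.e. at least 50% less/more work per nurse than
typical.  A point is extreme when it falls strictly beyond a threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .census import GROUP_COLUMNS

__all__ = [
    "compute_ratios",
    "compute_thresholds",
    "key_timepoint_summary",
    "department_mean_ci",
    "KEY_TIMEPOINTS",
]

KEY_TIMEPOINTS = ("02:00", "10:00", "18:00")

#: sample-quantile convention used for all medians/IQRs in this module
QUANTILE_METHOD = "linear"


def compute_ratios(census: pd.DataFrame) -> pd.DataFrame:
    """One ratio point per census point per hourly nurse group.

    Returns a long table: unit_id, timestamp, group, n_patients,
    n_nurses, ratio (NaN where the group's nurse count is zero).
    """
    parts = []
    for g, col in GROUP_COLUMNS.items():
        part = census[["unit_id", "timestamp", "n_patients", col]].rename(
            columns={col: "n_nurses"}
        )
        part = part.assign(group=g)
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["n_patients"] / out["n_nurses"]
    out["ratio"] = ratio.where(out["n_nurses"] > 0)
    return out[["unit_id", "timestamp", "group", "n_patients", "n_nurses", "ratio"]]


def compute_thresholds(
    ratios: pd.DataFrame, by: tuple[str, ...] = ("unit_id", "group")
) -> pd.DataFrame:
    """Median/IQR, ELT/EHT and extreme percentages per stratum.

    Percentages are over the stratum's non-missing points; strata whose
    median is zero are flagged ``degenerate`` (thresholds collapse to
    zero), and all-missing strata are marked unavailable.
    """
    rows = []
    for key, grp in ratios.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        r = grp["ratio"].dropna().to_numpy(dtype=float)
        n_missing = int(grp["ratio"].isna().sum())
        base = dict(zip(by, key))
        base["n_points"] = len(grp)
        base["n_zero_nurse"] = n_missing
        if r.size == 0:
            rows.append(
                base
                | {
                    "available": False,
                    "median": np.nan, "q1": np.nan, "q3": np.nan,
                    "elt": np.nan, "eht": np.nan,
                    "pct_below_elt": np.nan, "pct_above_eht": np.nan,
                    "pct_normal": np.nan, "degenerate": False,
                }
            )
            continue
        med = float(np.quantile(r, 0.5, method=QUANTILE_METHOD))
        q1 = float(np.quantile(r, 0.25, method=QUANTILE_METHOD))
        q3 = float(np.quantile(r, 0.75, method=QUANTILE_METHOD))
        elt = med - med / 2.0
        eht = med + med / 2.0
        below = float(np.count_nonzero(r < elt)) * 100.0 / r.size
        above = float(np.count_nonzero(r > eht)) * 100.0 / r.size
        rows.append(
            base
            | {
                "available": True,
                "median": med, "q1": q1, "q3": q3,
                "elt": elt, "eht": eht,
                "pct_below_elt": below,
                "pct_above_eht": above,
                "pct_normal": 100.0 - below - above,
                "degenerate": med == 0.0,
            }
        )
    return pd.DataFrame(rows)


def _daytype(ts: pd.Series) -> pd.Series:
    return np.where(ts.dt.dayofweek >= 5, "weekend", "weekday")


def key_timepoint_summary(
    ratios: pd.DataFrame,
    unit_department: dict[str, str],
    timepoints: tuple[str, ...] = KEY_TIMEPOINTS,
) -> pd.DataFrame:
    """Median (IQR) of the ratio at fixed clock times, split weekday vs
    weekend (Saturday/Sunday) and stratified by department and group."""
    r = ratios.copy()
    tod = r["timestamp"].dt.strftime("%H:%M")
    r = r[tod.isin(timepoints)]
    r = r.assign(
        timepoint=tod[tod.isin(timepoints)],
        daytype=_daytype(r["timestamp"]),
        department=r["unit_id"].map(unit_department),
    )
    rows = []
    for (dept, group, tp, dtp), grp in r.groupby(
        ["department", "group", "timepoint", "daytype"], sort=True
    ):
        v = grp["ratio"].dropna().to_numpy(dtype=float)
        rows.append(
            {
                "department": dept,
                "group": int(group),
                "timepoint": tp,
                "daytype": dtp,
                "n_points": len(grp),
                "median": float(np.quantile(v, 0.5, method=QUANTILE_METHOD)) if v.size else np.nan,
                "q1": float(np.quantile(v, 0.25, method=QUANTILE_METHOD)) if v.size else np.nan,
                "q3": float(np.quantile(v, 0.75, method=QUANTILE_METHOD)) if v.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def department_mean_ci(
    series: pd.DataFrame,
    unit_department: dict[str, str],
    level: float = 0.95,
    value_col: str = "ratio",
) -> pd.DataFrame:
    """Department mean profiles over the slot-of-week with CIs.

    For every (department, group, weekday, slot time): each unit first
    contributes its own mean over the study weeks, then the department
    mean is taken across those unit values with a t-interval at the
    requested level.  Departments with a single unit report the mean
    with a missing CI.
    """
    s = series.copy()
    s = s.assign(
        department=s["unit_id"].map(unit_department),
        dow=s["timestamp"].dt.dayofweek,
        tod=s["timestamp"].dt.strftime("%H:%M"),
    )
    group_keys = ["department", "dow", "tod"]
    if "group" in s.columns:
        group_keys.insert(1, "group")
    unit_means = (
        s.groupby(group_keys + ["unit_id"], sort=True)[value_col].mean().reset_index()
    )
    rows = []
    for key, grp in unit_means.groupby(group_keys, sort=True):
        v = grp[value_col].dropna().to_numpy(dtype=float)
        n = v.size
        mean = float(v.mean()) if n else np.nan
        if n >= 2:
            se = float(v.std(ddof=1)) / np.sqrt(n)
            tcrit = float(stats.t.ppf(0.5 + level / 2.0, df=n - 1))
            lo, hi = mean - tcrit * se, mean + tcrit * se
        else:
            lo = hi = np.nan
        rows.append(dict(zip(group_keys, key)) | {
            "n_units": n, "mean": mean, "ci_low": lo, "ci_high": hi,
        })
    return pd.DataFrame(rows)
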