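"""Department-level descriptive overview.

Per department: case volume and unit count, patient age (mean/SD and
median/IQR), length of stay (median/IQR), patients per day per unit
(median/IQR, taken from the census at a daily reference slot), and the
two most common main diagnoses at ICD-10 chapter level with incidence
n/N (%).
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from ._rounding import pct
from .icd10 import CHAPTERS, icd10_chapter

#: tie-break rank: chapters in code order, unknown last
_CHAPTER_RANK = {label: i for i, (_, _, _, label) in enumerate(CHAPTERS)}

__all__ = ["compute_los", "icd10_chapter", "department_overview"]


def compute_los(admission_date: dt.date, discharge_date: dt.date) -> int:
    """Length of stay in whole days: discharge date minus admission date.

    Clock times are ignored; a same-day admission and discharge has LOS 0.
    Raises ``ValueError`` when the discharge precedes the admission.
    """
    if isinstance(admission_date, (pd.Timestamp, dt.datetime)):
        admission_date = admission_date.date()
    if isinstance(discharge_date, (pd.Timestamp, dt.datetime)):
        discharge_date = discharge_date.date()
    delta = (discharge_date - admission_date).days
    if delta < 0:
        raise ValueError(
            f"discharge {discharge_date} precedes admission {admission_date}"
        )
    return delta


def _median_iqr(values: pd.Series) -> tuple[float, float, float]:
    v = pd.Series(values).dropna().to_numpy(dtype=float)
    if v.size == 0:
        return (np.nan, np.nan, np.nan)
    return (
        float(np.median(v)),
        float(np.quantile(v, 0.25)),
        float(np.quantile(v, 0.75)),
    )


def department_overview(
    cases: pd.DataFrame,
    census: pd.DataFrame | None = None,
    unit_department: dict[str, str] | None = None,
    reference_time: str = "12:00",
) -> pd.DataFrame:
    """Build the department overview table.

    Parameters
    ----------
    cases
        Linked case table with columns case_id, department, age_years,
        los_days, main_dx.
    census
        Optional long census table (unit_id, timestamp, n_patients); when
        given together with ``unit_department`` the "patients per day per
        unit" statistic is computed from the census value at
        ``reference_time`` of each day.
    unit_department
        Mapping unit -> department for the census units.
    reference_time
        Clock time of the daily reference slot (default noon).  The
        collapse of 48 intraday points to one daily count is a reporting
        convention, configurable on purpose.
    """
    if cases.empty:
        return pd.DataFrame()

    ppdu: dict[str, tuple[float, float, float]] = {}
    n_units: dict[str, int] = {}
    if census is not None and unit_department is not None and not census.empty:
        ref = pd.to_timedelta(reference_time + ":00")
        daily = census[census["timestamp"] - census["timestamp"].dt.normalize() == ref]
        daily = daily.assign(department=daily["unit_id"].map(unit_department))
        for dept, grp in daily.groupby("department"):
            ppdu[dept] = _median_iqr(grp["n_patients"])
            n_units[dept] = grp["unit_id"].nunique()

    chapters = cases["main_dx"].map(icd10_chapter)
    rows = []
    for dept, grp in cases.groupby("department", sort=False):
        n = len(grp)
        age = grp["age_years"].astype(float)
        age_med, age_q1, age_q3 = _median_iqr(age)
        los_med, los_q1, los_q3 = _median_iqr(grp["los_days"])
        # top-2 chapters by incidence; ties broken by chapter code order
        counts = (
            chapters.loc[grp.index]
            .value_counts()
            .rename_axis("chapter")
            .reset_index(name="n")
        )
        counts["rank"] = counts["chapter"].map(_CHAPTER_RANK).fillna(len(CHAPTERS))
        counts = counts.sort_values(["n", "rank"], ascending=[False, True], kind="stable")
        top = list(counts.itertuples(index=False))[:2]
        while len(top) < 2:
            top.append(None)
        row = {
            "department": dept,
            "n_patients": n,
            "n_units": n_units.get(dept, np.nan),
            "age_mean": float(age.mean()) if n else np.nan,
            "age_sd": float(age.std(ddof=1)) if n > 1 else 0.0,
            "age_median": age_med,
            "age_q1": age_q1,
            "age_q3": age_q3,
            "los_median": los_med,
            "los_q1": los_q1,
            "los_q3": los_q3,
        }
        med_iqr = ppdu.get(dept, (np.nan, np.nan, np.nan))
        row["patients_day_unit_median"], row["patients_day_unit_q1"], row["patients_day_unit_q3"] = med_iqr
        for rank, item in enumerate(top, start=1):
            if item is None:
                row[f"dx{rank}_chapter"] = None
                row[f"dx{rank}_n"] = np.nan
                row[f"dx{rank}_pct"] = np.nan
            else:
                row[f"dx{rank}_chapter"] = item.chapter
                row[f"dx{rank}_n"] = int(item.n)
                row[f"dx{rank}_pct"] = pct(int(item.n), n)
        rows.append(row)

    out = pd.DataFrame(rows).sort_values("n_patients", ascending=False, kind="stable")
    return out.reset_index(drop=True)
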