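"""Synthetic hospital event generator.

Produces the five staffing/discharge sheets the ingest stage reads,
together with the generating ground truth (stay intervals, shift
segments, daily presence) so downstream modules can be validated against
what was actually simulated:

* patient flow — admissions from a time-inhomogeneous Poisson process
  (hour-of-day x day-of-week intensity per unit), right-skewed length of
  stay, and inter-unit transfers that split a hospital stay into
  per-unit stay intervals;
* roster — shift-template staffing per unit/day with break rules that
  split shifts into working segments; students and external nurses
  (groups 4-5) are emitted with daily presence only, mirroring source
  systems that record no time breakdown for them;
* activity — care rows linking on-duty nurses to patients present on
  their unit, plus administrative/teaching/education/absence rows;
* data-quality defects — nurses without working-hours records,
  outpatient cases, healthy newborns in the maternity department.

Determinism: every public function derives its generator from
``config.seed`` and a fixed stream key, so identical configurations give
byte-identical outputs.

A deliberate timing convention: patient-movement timestamps always carry
a seconds component in 1..59, i.e. an ADT event never falls exactly on a
minute boundary (and hence never on a census-slot boundary).  Point
sampling of the census and half-open event windows then satisfy the flow
conservation identity exactly.  Nurse shift times stay at whole minutes,
matching real rosters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import schemas
from .config import DAILY_GROUPS, HOURLY_GROUPS, SimConfig
from .descriptives import compute_los
from .icd10 import chapter_codes

__all__ = [
    "Truth",
    "SyntheticBundle",
    "simulate_patient_flow",
    "simulate_roster",
    "simulate_activity",
    "make_bundle",
]

# fixed sub-stream keys, one per stochastic stage
_STREAM_FLOW, _STREAM_ROSTER, _STREAM_ACTIVITY, _STREAM_DEFECTS = 11, 22, 33, 44

STAY_COLUMNS = ["case_id", "unit_id", "department", "entry_ts", "exit_ts", "entry_kind", "exit_kind"]
SEGMENT_COLUMNS = ["nurse_id", "unit_id", "group", "start_ts", "end_ts"]


@dataclass
class Truth:
    """Generating ground truth for oracle comparisons."""

    stays: pd.DataFrame            # STAY_COLUMNS, all cases incl. flagged ones
    segments: pd.DataFrame         # SEGMENT_COLUMNS, groups 1-3
    daily_presence: pd.DataFrame   # date, unit_id, group, count (groups 4-5)
    cases: pd.DataFrame            # per-case table incl. outpatient/newborn flags


@dataclass
class SyntheticBundle:
    """The five sheets plus the truth that generated them."""

    activity: pd.DataFrame
    nurses: pd.DataFrame
    working_hours: pd.DataFrame
    movements: pd.DataFrame
    discharge: pd.DataFrame
    truth: Truth
    defects: dict

    def sheets(self) -> dict[str, pd.DataFrame]:
        return {
            schemas.ACTIVITY: self.activity,
            schemas.NURSES: self.nurses,
            schemas.WORKING_HOURS: self.working_hours,
            schemas.MOVEMENTS: self.movements,
            schemas.DISCHARGE: self.discharge,
        }


def _off_minute(ts: pd.Series | pd.DatetimeIndex):
    """Floor to whole seconds and push second-00 marks to second 01 so no
    event sits exactly on a minute (hence slot) boundary."""
    ts = pd.DatetimeIndex(ts).floor("s")
    return ts + pd.to_timedelta((ts.second == 0).astype(int), unit="s")


# ---------------------------------------------------------------------------
# Patient flow
# ---------------------------------------------------------------------------

def simulate_patient_flow(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate admissions, stays and transfers.

    Returns
    -------
    cases : DataFrame
        One row per case: case_id, department, admit_unit, age_years,
        admission_ts, discharge_ts, main_dx, chapter.
    stays : DataFrame
        One row per contiguous unit presence (``STAY_COLUMNS``); a case
        with *k* transfers contributes *k + 1* stays whose transfer
        boundaries share one timestamp (instantaneous relocation).
    """
    rng = np.random.default_rng([config.seed, _STREAM_FLOW])
    hours = pd.date_range(
        config.start_date,
        pd.Timestamp(config.end_date) + pd.Timedelta(days=1),
        freq="h",
        inclusive="left",
    )
    hod = hours.hour.to_numpy()
    dow = hours.dayofweek.to_numpy()
    unit_dept = config.unit_department

    adm_ts_parts, adm_unit_parts = [], []
    for unit in config.units:
        lam = config.admission_rate.rate(hod, dow, unit)
        n = rng.poisson(lam)
        total = int(n.sum())
        if total == 0:
            continue
        base = np.repeat(hours.to_numpy(), n)
        minute = rng.integers(0, 60, total)
        second = rng.integers(1, 60, total)  # 1..59: never on a minute boundary
        ts = pd.DatetimeIndex(base) + pd.to_timedelta(minute * 60 + second, unit="s")
        adm_ts_parts.append(ts)
        adm_unit_parts.append(np.full(total, unit, dtype=object))

    if not adm_ts_parts:
        return (
            pd.DataFrame(
                columns=["case_id", "department", "admit_unit", "age_years",
                         "admission_ts", "discharge_ts", "main_dx", "chapter"]
            ),
            pd.DataFrame(columns=STAY_COLUMNS),
        )

    adm_ts = pd.DatetimeIndex(np.concatenate([p.to_numpy() for p in adm_ts_parts]))
    adm_unit = np.concatenate(adm_unit_parts)
    order = np.argsort(adm_ts.to_numpy(), kind="stable")
    adm_ts, adm_unit = adm_ts[order], adm_unit[order]
    n_cases = len(adm_ts)

    cases = pd.DataFrame(
        {
            "case_id": [f"P{i + 1:06d}" for i in range(n_cases)],
            "admit_unit": adm_unit,
            "admission_ts": adm_ts,
        }
    )
    cases["department"] = cases["admit_unit"].map(unit_dept)

    # per-department draws: LOS, age, diagnosis
    cases["los_raw_days"] = np.nan
    cases["age_years"] = np.nan
    cases["main_dx"] = ""
    cases["chapter"] = ""
    for dept, idx in cases.groupby("department", sort=True).groups.items():
        k = len(idx)
        cases.loc[idx, "los_raw_days"] = config.los_for(dept).sample(rng, k)
        mean, sd = config.age_for(dept)
        a, b = (0.0 - mean) / sd, (110.0 - mean) / sd
        cases.loc[idx, "age_years"] = np.round(
            stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=k, random_state=rng), 1
        )
        weights = config.chapter_weights_for(dept)
        numerals = list(weights)
        p = np.array([weights[c] for c in numerals], dtype=float)
        p /= p.sum()
        chap_idx = rng.choice(len(numerals), size=k, p=p)
        codes = []
        pool = {c: chapter_codes(c) for c in numerals}
        for ci in chap_idx:
            numeral = numerals[ci]
            prefix = pool[numeral][rng.integers(len(pool[numeral]))]
            codes.append(f"{prefix}.{rng.integers(10)}")
        cases.loc[idx, "main_dx"] = codes
        cases.loc[idx, "chapter"] = [numerals[ci] for ci in chap_idx]

    dis_ts = _off_minute(
        cases["admission_ts"] + pd.to_timedelta(cases["los_raw_days"], unit="D")
    )
    # guarantee a strictly positive stay even after flooring
    too_short = dis_ts <= pd.DatetimeIndex(cases["admission_ts"])
    dis_ts = dis_ts + pd.to_timedelta(too_short.astype(int) * 120, unit="s")
    cases["discharge_ts"] = dis_ts
    cases = cases.drop(columns="los_raw_days")

    # transfers: Poisson(transfer_prob * LOS_days) relocation events per case
    los_days = (
        (cases["discharge_ts"] - cases["admission_ts"]).dt.total_seconds() / 86400.0
    ).to_numpy()
    n_transfers = rng.poisson(config.transfer_prob * los_days)
    all_units = config.units
    tw = config.transfer_weights or {}

    stay_rows: list[tuple] = []
    for i in range(n_cases):
        cid = cases["case_id"].iat[i]
        t0 = cases["admission_ts"].iat[i]
        t1 = cases["discharge_ts"].iat[i]
        unit = cases["admit_unit"].iat[i]
        kt = int(n_transfers[i])
        times: list[pd.Timestamp] = []
        if kt > 0 and len(all_units) > 1:
            u = np.sort(rng.random(kt))
            cand = _off_minute(pd.DatetimeIndex(t0 + (t1 - t0) * u))
            times = [t for t in cand.unique() if t0 < t < t1]
        boundaries = [t0, *times, t1]
        seq = [unit]
        for _ in times:
            choices = [v for v in all_units if v != seq[-1]]
            w = np.array([tw.get(v, 1.0) for v in choices], dtype=float)
            seq.append(choices[rng.choice(len(choices), p=w / w.sum())])
        for j, u_j in enumerate(seq):
            stay_rows.append(
                (
                    cid,
                    u_j,
                    unit_dept[u_j],
                    boundaries[j],
                    boundaries[j + 1],
                    "admission" if j == 0 else "transfer_in",
                    "discharge" if j == len(seq) - 1 else "transfer_out",
                )
            )

    stays = pd.DataFrame(stay_rows, columns=STAY_COLUMNS)
    return cases, stays


# ---------------------------------------------------------------------------
# Roster
# ---------------------------------------------------------------------------

def _pool_sizes(config: SimConfig) -> dict[int, int]:
    """Per-group nurse pool size per unit: twice the daily requirement for
    the hourly groups (so consecutive night shifts never force an
    overlapping assignment), and group-mix-proportional pools for the
    daily-only groups."""
    need = {g: 0 for g in HOURLY_GROUPS}
    for shift in config.shift_template:
        for g in HOURLY_GROUPS:
            need[g] += max(shift.weekday_staff.get(g, 0), shift.weekend_staff.get(g, 0))
    sizes = {g: (2 * n + 1 if n > 0 else 0) for g, n in need.items()}
    ref = sum(sizes.values())
    mix = config.group_mix
    mix_hourly = sum(mix[g - 1] for g in HOURLY_GROUPS) or 1.0
    for g in DAILY_GROUPS:
        wants_presence = config.daily_presence_rate.get(g, 0.0) > 0
        sizes[g] = int(round(ref * mix[g - 1] / mix_hourly))
        if wants_presence:
            sizes[g] = max(sizes[g], 3)
    return sizes


def simulate_roster(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Roster nurses onto shifts and emit working segments.

    Returns
    -------
    nurses : DataFrame
        nurse_id, contract_id, group for every pool member.
    segments : DataFrame
        ``SEGMENT_COLUMNS`` for groups 1-3; breaks split each shift into
        two segments.
    presence : DataFrame
        nurse_id, contract_id, unit_id, group, date for groups 4-5
        (daily presence, no clock times).
    """
    rng = np.random.default_rng([config.seed, _STREAM_ROSTER])
    dates = config.dates
    nurse_rows, seg_rows, presence_rows = [], [], []
    counter = 0
    sizes = _pool_sizes(config)

    for unit in config.units:
        pools: dict[int, list[str]] = {}
        for g in sorted(sizes):
            ids = []
            for _ in range(sizes[g]):
                counter += 1
                ids.append(f"N{counter:05d}")
            pools[g] = ids
            nurse_rows.extend((nid, f"K{nid[1:]}", g) for nid in ids)

        last_end: dict[str, pd.Timestamp] = {}
        for day in dates:
            weekend = day.dayofweek >= 5
            for shift in config.shift_template:
                staff = shift.weekend_staff if weekend else shift.weekday_staff
                start_ts = day + pd.Timedelta(hours=shift.start.hour, minutes=shift.start.minute)
                end_ts = day + pd.Timedelta(hours=shift.end.hour, minutes=shift.end.minute)
                if end_ts <= start_ts:
                    end_ts += pd.Timedelta(days=1)
                for g in sorted(staff):
                    k = staff[g]
                    if k == 0:
                        continue
                    avail = [
                        n
                        for n in pools[g]
                        if last_end.get(n, pd.Timestamp.min) <= start_ts
                    ]
                    if len(avail) < k:
                        raise RuntimeError(
                            f"nurse pool exhausted on {day.date()} {shift.label} "
                            f"unit {unit} group {g}"
                        )
                    chosen = rng.choice(np.array(avail, dtype=object), size=k, replace=False)
                    for nid in chosen:
                        last_end[nid] = end_ts
                        seg_rows.extend(
                            (nid, unit, g, s, e)
                            for s, e in _split_by_break(rng, shift, day, start_ts, end_ts)
                        )
            for g in DAILY_GROUPS:
                lam = config.daily_presence_rate.get(g, 0.0)
                if lam <= 0 or not pools.get(g):
                    continue
                c = min(int(rng.poisson(lam)), len(pools[g]))
                if c == 0:
                    continue
                chosen = rng.choice(np.array(pools[g], dtype=object), size=c, replace=False)
                presence_rows.extend((nid, f"K{nid[1:]}", unit, g, day) for nid in chosen)

    nurses = pd.DataFrame(nurse_rows, columns=["nurse_id", "contract_id", "group"])
    segments = pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS)
    presence = pd.DataFrame(
        presence_rows, columns=["nurse_id", "contract_id", "unit_id", "group", "date"]
    )
    return nurses, segments, presence


def _split_by_break(rng, shift, day, start_ts, end_ts):
    """Split one rostered shift into working segments around the break."""
    if shift.break_window is None or shift.break_minutes == 0:
        return [(start_ts, end_ts)]
    w0, w1 = shift.break_window
    b0 = day + pd.Timedelta(hours=w0.hour, minutes=w0.minute)
    b1 = day + pd.Timedelta(hours=w1.hour, minutes=w1.minute)
    if b0 < start_ts:  # clock window belongs to the post-midnight part
        b0 += pd.Timedelta(days=1)
        b1 += pd.Timedelta(days=1)
    b0 = max(b0, start_ts)
    b1 = min(b1, end_ts)
    dur = pd.Timedelta(minutes=shift.break_minutes)
    latest = b1 - dur
    if latest < b0:  # window too tight: no break
        return [(start_ts, end_ts)]
    slack_min = int((latest - b0).total_seconds() // 60)
    bstart = b0 + pd.Timedelta(minutes=int(rng.integers(0, slack_min + 1)))
    return [(start_ts, bstart), (bstart + dur, end_ts)]


# ---------------------------------------------------------------------------
# Activity
# ---------------------------------------------------------------------------

def simulate_activity(
    cases: pd.DataFrame,
    stays: pd.DataFrame,
    segments: pd.DataFrame,
    presence: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Emit the activity sheet: care rows linking each on-duty nurse to
    patients present on her unit that calendar day, plus non-care rows at
    the configured per-nurse-day probabilities."""
    rng = np.random.default_rng([config.seed, _STREAM_ACTIVITY])
    if stays.empty and segments.empty and presence.empty:
        return pd.DataFrame(columns=list(schemas.SHEET_SCHEMAS[schemas.ACTIVITY]))

    nurse_days = []
    if not segments.empty:
        nd = segments.assign(date=segments["start_ts"].dt.normalize())
        nd = nd.drop_duplicates(["nurse_id", "unit_id", "date"])
        nurse_days.append(
            pd.DataFrame(
                {
                    "nurse_id": nd["nurse_id"].to_numpy(),
                    "contract_id": ["K" + n[1:] for n in nd["nurse_id"]],
                    "unit_id": nd["unit_id"].to_numpy(),
                    "date": nd["date"].to_numpy(),
                }
            )
        )
    if not presence.empty:
        nurse_days.append(
            presence[["nurse_id", "contract_id", "unit_id", "date"]].assign(
                date=pd.DatetimeIndex(presence["date"]).normalize()
            )
        )
    nurse_days_df = (
        pd.concat(nurse_days, ignore_index=True)
        if nurse_days
        else pd.DataFrame(columns=["nurse_id", "contract_id", "unit_id", "date"])
    )
    nurse_days_df = nurse_days_df.sort_values(
        ["unit_id", "date", "nurse_id"], kind="stable"
    ).reset_index(drop=True)

    # patients present per (unit, calendar day)
    present: dict[tuple, list[str]] = {}
    for row in stays.itertuples(index=False):
        d0 = row.entry_ts.normalize()
        d1 = row.exit_ts.normalize()
        for day in pd.date_range(d0, d1, freq="D"):
            present.setdefault((row.unit_id, day), []).append(row.case_id)

    rows = []
    for nd in nurse_days_df.itertuples(index=False):
        pool = present.get((nd.unit_id, pd.Timestamp(nd.date)), [])
        if pool:
            k = min(len(pool), int(rng.integers(1, 7)))
            picked = rng.choice(np.array(pool, dtype=object), size=k, replace=False)
            for cid in picked:
                rows.append(
                    (nd.nurse_id, nd.contract_id, cid, nd.unit_id, nd.date, "care", "inpatient")
                )
        for act, p in config.activity_mix.items():
            if rng.random() < p:
                rows.append(
                    (nd.nurse_id, nd.contract_id, None, nd.unit_id, nd.date, act, "inpatient")
                )

    activity = pd.DataFrame(
        rows,
        columns=["nurse_id", "contract_id", "case_id", "unit_id", "date", "activity_type", "setting"],
    )
    if config.activity_outpatient_frac > 0 and not activity.empty:
        mask = rng.random(len(activity)) < config.activity_outpatient_frac
        activity.loc[mask, "setting"] = "outpatient"
    return activity


# ---------------------------------------------------------------------------
# Bundle assembly (defects applied here)
# ---------------------------------------------------------------------------

def make_bundle(config: SimConfig) -> SyntheticBundle:
    """Run the full generator and assemble the five linked sheets.

    Defect application: a fraction of hourly-group nurses lose all their
    working-hours rows; a fraction of cases is flagged outpatient (their
    movement rows carry the outpatient setting); a fraction of maternity
    cases becomes healthy newborns (age 0, flag set in the discharge
    sheet).
    """
    cases, stays = simulate_patient_flow(config)
    nurses, segments, presence = simulate_roster(config)
    activity = simulate_activity(cases, stays, segments, presence, config)
    rng = np.random.default_rng([config.seed, _STREAM_DEFECTS])
    dr = config.defect_rates

    outpatient_cases: set = set()
    newborn_cases: set = set()
    if not cases.empty:
        mask_out = rng.random(len(cases)) < dr.outpatient
        outpatient_cases = set(cases.loc[mask_out, "case_id"])
        if dr.newborn > 0 and config.maternity_department is not None:
            mat = cases["department"] == config.maternity_department
            mask_nb = mat & (rng.random(len(cases)) < dr.newborn) & ~mask_out
            newborn_cases = set(cases.loc[mask_nb, "case_id"])
            cases = cases.copy()
            cases.loc[mask_nb, "age_years"] = 0.0

    hourly_nurses = nurses.loc[nurses["group"].isin(HOURLY_GROUPS), "nurse_id"]
    active = hourly_nurses[hourly_nurses.isin(segments["nurse_id"])].unique()
    missing_wh = set(active[rng.random(len(active)) < dr.missing_working_hours])

    # --- sheets ---
    wh = segments.copy()
    wh = wh[~wh["nurse_id"].isin(missing_wh)]
    working_hours = pd.DataFrame(
        {
            "nurse_id": wh["nurse_id"].to_numpy(),
            "contract_id": ["K" + n[1:] for n in wh["nurse_id"]],
            "date": wh["start_ts"].dt.strftime("%Y-%m-%d").to_numpy(),
            "start_time": wh["start_ts"].dt.strftime("%H:%M:%S").to_numpy(),
            "end_time": wh["end_ts"].dt.strftime("%H:%M:%S").to_numpy(),
        }
    ).reset_index(drop=True)

    mv_rows = []
    for st in stays.itertuples(index=False):
        setting = "outpatient" if st.case_id in outpatient_cases else "inpatient"
        if st.entry_kind == "admission":
            mv_rows.append((st.case_id, st.unit_id, "admission", st.entry_ts, setting))
        else:
            mv_rows.append((st.case_id, st.unit_id, "transfer", st.entry_ts, setting))
        if st.exit_kind == "discharge":
            mv_rows.append((st.case_id, st.unit_id, "discharge", st.exit_ts, setting))
    mv = pd.DataFrame(mv_rows, columns=["case_id", "unit_id", "event", "ts", "setting"])
    mv = mv.sort_values(["case_id", "ts", "event"], kind="stable").reset_index(drop=True)
    movements = pd.DataFrame(
        {
            "case_id": mv["case_id"],
            "unit_id": mv["unit_id"],
            "event": mv["event"],
            "date": mv["ts"].dt.strftime("%Y-%m-%d"),
            "time": mv["ts"].dt.strftime("%H:%M:%S"),
            "setting": mv["setting"],
        }
    )

    discharge = pd.DataFrame(
        {
            "case_id": cases["case_id"],
            "age_years": cases["age_years"],
            "admission_date": cases["admission_ts"].dt.strftime("%Y-%m-%d"),
            "discharge_date": cases["discharge_ts"].dt.strftime("%Y-%m-%d"),
            "main_dx": cases["main_dx"],
            "department": cases["department"],
            "healthy_newborn": cases["case_id"].isin(newborn_cases),
        }
    )

    activity_sheet = activity.copy()
    activity_sheet["date"] = pd.DatetimeIndex(activity_sheet["date"]).strftime("%Y-%m-%d")

    nurses_sheet = nurses.sort_values("nurse_id", kind="stable").reset_index(drop=True)

    daily_presence = (
        presence.groupby(["date", "unit_id", "group"], as_index=False)
        .agg(count=("nurse_id", "nunique"))
        if not presence.empty
        else pd.DataFrame(columns=["date", "unit_id", "group", "count"])
    )

    truth_cases = cases.copy()
    truth_cases["outpatient"] = truth_cases["case_id"].isin(outpatient_cases)
    truth_cases["healthy_newborn"] = truth_cases["case_id"].isin(newborn_cases)
    truth_cases["los_days"] = [
        compute_los(a.date(), d.date())
        for a, d in zip(truth_cases["admission_ts"], truth_cases["discharge_ts"])
    ]

    return SyntheticBundle(
        activity=activity_sheet,
        nurses=nurses_sheet,
        working_hours=working_hours,
        movements=movements,
        discharge=discharge,
        truth=Truth(
            stays=stays.reset_index(drop=True),
            segments=segments.reset_index(drop=True),
            daily_presence=daily_presence,
            cases=truth_cases.reset_index(drop=True),
        ),
        defects={
            "missing_working_hours_nurses": sorted(missing_wh),
            "outpatient_cases": sorted(outpatient_cases),
            "newborn_cases": sorted(newborn_cases),
        },
    )
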