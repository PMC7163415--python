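"""Linkage of the staffing sheets with the medical discharge data.

The stages mirror how such event sources are merged in practice:

1. restrict the activity sheet to inpatient, direct/indirect-care rows
   (duplicates removed first);
2. nurse side — join activity with the nurse register and the
   working-hours sheet on (nurse, contract, date); nurse-days that have
   care activity but no recorded working time are excluded and counted;
   students and external nurses (groups 4-5), who carry no time
   breakdown, are routed into a daily-presence table; contract
   identifiers are dropped after the join;
3. patient side — order each case's movement events in time, pair them
   into per-unit stay intervals (admission/transfer-in opens,
   transfer-out/discharge closes), join with the discharge record, and
   exclude outpatient cases and healthy newborns;
4. deidentify — stable Patient1…/Nurse1…/Unit1… pseudonyms, mapping
   discarded unless explicitly kept.

Every inclusion/exclusion stage is recorded in a :class:`Funnel` whose
report carries numerators, denominators and half-up percentages to one
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from ._rounding import pct
from .config import DAILY_GROUPS, HOURLY_GROUPS
from .descriptives import compute_los
from .io import REJECT_COLUMNS, RawBundle, _coerce_sheet

__all__ = [
    "Funnel",
    "FunnelStage",
    "funnel_report",
    "LinkedDataset",
    "typed_from_sheets",
    "filter_care_activity",
    "link_nurse_side",
    "link_patient_side",
    "deidentify",
    "link",
]

SHIFT_COLUMNS = ["nurse_id", "unit_id", "group", "start_ts", "end_ts"]
STAY_COLUMNS = ["case_id", "unit_id", "department", "entry_ts", "exit_ts", "entry_kind", "exit_kind"]
CASE_COLUMNS = ["case_id", "department", "age_years", "admission_date", "discharge_date", "los_days", "main_dx"]

_EVENT_ORDER = {"admission": 0, "transfer": 1, "discharge": 2}


# ---------------------------------------------------------------------------
# Funnel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunnelStage:
    stage: str
    metric: str  # e.g. cases / nurses / units / person_days
    numerator: int
    denominator: int | None = None
    kind: str = "retained"  # retained count vs excluded count


@dataclass
class Funnel:
    """Ordered record of inclusion/exclusion stages.

    ``kind='retained'`` stages carry how much survives the stage (these
    are non-increasing along the funnel for a given metric);
    ``kind='excluded'`` stages carry how much one exclusion removed.
    """

    stages: list[FunnelStage] = field(default_factory=list)

    def add(
        self,
        stage: str,
        metric: str,
        numerator: int,
        denominator: int | None = None,
        kind: str = "retained",
    ):
        self.stages.append(FunnelStage(stage, metric, int(numerator), denominator, kind))

    def to_frame(self) -> pd.DataFrame:
        return funnel_report(self)


def funnel_report(funnel: Funnel) -> pd.DataFrame:
    """Stage table with numerators, denominators and percentages to one
    decimal (half-up); a zero/absent denominator leaves the percent
    missing."""
    rows = [
        {
            "stage": s.stage,
            "metric": s.metric,
            "kind": s.kind,
            "numerator": s.numerator,
            "denominator": s.denominator,
            "percent": pct(s.numerator, s.denominator),
        }
        for s in funnel.stages
    ]
    return pd.DataFrame(
        rows, columns=["stage", "metric", "kind", "numerator", "denominator", "percent"]
    )


# ---------------------------------------------------------------------------
# Linked dataset container
# ---------------------------------------------------------------------------

@dataclass
class LinkedDataset:
    """Deidentified analysis dataset produced by :func:`link`."""

    stays: pd.DataFrame           # STAY_COLUMNS
    shifts: pd.DataFrame          # SHIFT_COLUMNS (groups 1-3)
    cases: pd.DataFrame           # CASE_COLUMNS
    daily_presence: pd.DataFrame  # date, unit_id, group (4/5), count
    funnel: Funnel
    rejects: pd.DataFrame
    info: dict = field(default_factory=dict)
    id_map: dict | None = None

    @property
    def units(self) -> list[str]:
        units = set(self.stays["unit_id"]) | set(self.shifts["unit_id"])
        if not self.daily_presence.empty:
            units |= set(self.daily_presence["unit_id"])
        return sorted(units)

    @property
    def unit_department(self) -> dict[str, str]:
        """unit -> department, via the stays table (majority vote)."""
        if self.stays.empty:
            return {}
        top = (
            self.stays.groupby("unit_id")["department"]
            .agg(lambda s: s.value_counts().index[0])
        )
        return top.to_dict()


def typed_from_sheets(sheets: dict[str, pd.DataFrame]) -> RawBundle:
    """Type-check in-memory sheets (same validation as reading from disk)."""
    typed, rejects = {}, []
    for name, df in sheets.items():
        frame, rej = _coerce_sheet(df, name)
        typed[name] = frame
        rejects.append(rej)
    return RawBundle(rejects=pd.concat(rejects, ignore_index=True), **typed)


# ---------------------------------------------------------------------------
# Stage 1: activity subset
# ---------------------------------------------------------------------------

def filter_care_activity(raw: RawBundle, funnel: Funnel | None = None) -> tuple[RawBundle, Funnel]:
    """Keep inpatient direct/indirect-care activity rows only.

    Duplicate activity records are removed first; source and retained
    cases/nurses/units are recorded in the funnel.
    """
    funnel = funnel or Funnel()
    act = raw.activity.drop_duplicates(ignore_index=True)
    n_dup = len(raw.activity) - len(act)

    def _counts(df):
        return (
            df["case_id"].nunique(dropna=True),
            df["nurse_id"].nunique(),
            df["unit_id"].nunique(),
        )

    c0, n0, u0 = _counts(act)
    kept = act[(act["setting"] == "inpatient") & (act["activity_type"] == "care")].reset_index(drop=True)
    c1, n1, u1 = _counts(kept)
    funnel.add("source activity", "cases", c0)
    funnel.add("source activity", "nurses", n0)
    funnel.add("source activity", "units", u0)
    funnel.add("inpatient care activity", "cases", c1, c0)
    funnel.add("inpatient care activity", "nurses", n1, n0)
    funnel.add("inpatient care activity", "units", u1, u0)
    out = replace(raw, activity=kept)
    out.rejects = raw.rejects
    out.rejects.attrs["duplicate_activity_rows"] = n_dup
    return out, funnel


# ---------------------------------------------------------------------------
# Stage 2: nurse side
# ---------------------------------------------------------------------------

def link_nurse_side(
    raw: RawBundle, funnel: Funnel
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Join care activity with nurse records and working hours.

    Returns (shifts, daily_presence, info).  ``info`` carries counts of
    deduplicated working-hours rows, unknown-nurse activity and
    multi-unit nurse-days.
    """
    nd = (
        raw.activity[["nurse_id", "contract_id", "unit_id", "date"]]
        .drop_duplicates()
        .sort_values(["nurse_id", "date", "unit_id"], kind="stable")
    )
    n_ambiguous = nd.duplicated(["nurse_id", "contract_id", "date"]).sum()
    nd = nd.drop_duplicates(["nurse_id", "contract_id", "date"], keep="first")

    merged = nd.merge(raw.nurses, on=["nurse_id", "contract_id"], how="left")
    unknown = merged["group"].isna()
    merged = merged[~unknown]

    daily = merged[merged["group"].isin(DAILY_GROUPS)]
    daily_presence = (
        daily.groupby(["date", "unit_id", "group"], as_index=False)
        .agg(count=("nurse_id", "nunique"))
        .astype({"group": int})
    )

    hourly = merged[merged["group"].isin(HOURLY_GROUPS)]
    n_nurse_days = len(hourly)

    wh = raw.working_hours
    n_wh = len(wh)
    wh = wh.drop_duplicates(["nurse_id", "contract_id", "date", "start_time"])
    n_wh_dup = n_wh - len(wh)

    joined = hourly.merge(wh, on=["nurse_id", "contract_id", "date"], how="left")
    no_time = joined["start_time"].isna()
    excluded_days = (
        joined.loc[no_time, ["nurse_id", "date"]].drop_duplicates().shape[0]
    )
    funnel.add(
        "nurse-days excluded (no working time recorded)",
        "person_days",
        excluded_days,
        n_nurse_days,
        kind="excluded",
    )

    seg = joined[~no_time].copy()
    seg["start_ts"] = seg["date"] + seg["start_time"]
    crosses = seg["end_time"] <= seg["start_time"]
    seg["end_ts"] = seg["date"] + seg["end_time"] + pd.to_timedelta(crosses.astype(int), unit="D")
    shifts = (
        seg[SHIFT_COLUMNS]
        .astype({"group": int})
        .sort_values(["nurse_id", "start_ts"], kind="stable")
        .reset_index(drop=True)
    )
    retained_nurses = raw.activity["nurse_id"].nunique()
    funnel.add("nurses with usable working time", "nurses", shifts["nurse_id"].nunique(), retained_nurses)

    info = {
        "working_hours_duplicates_removed": int(n_wh_dup),
        "activity_without_nurse_record": int(unknown.sum()),
        "multi_unit_nurse_days_collapsed": int(n_ambiguous),
        "excluded_person_days": int(excluded_days),
    }
    return shifts, daily_presence, info


# ---------------------------------------------------------------------------
# Stage 3: patient side
# ---------------------------------------------------------------------------

def _pair_case_events(case_id: str, ev: pd.DataFrame, department) -> tuple[list, str | None]:
    """State machine turning one case's ordered movement events into stay
    intervals; returns (stay rows, error reason or None)."""
    stays = []
    open_stay = None  # (unit, ts, entry_kind)
    closed = False
    for row in ev.itertuples(index=False):
        if closed:
            return [], "event after discharge"
        if row.event == "admission":
            if open_stay is not None:
                return [], "second admission while stay open"
            open_stay = (row.unit_id, row.ts, "admission")
        elif row.event == "transfer":
            if open_stay is None:
                return [], "transfer before admission"
            u, t, kind = open_stay
            if row.ts < t:
                return [], "events out of order"
            stays.append((case_id, u, department, t, row.ts, kind, "transfer_out"))
            open_stay = (row.unit_id, row.ts, "transfer_in")
        else:  # discharge
            if open_stay is None:
                return [], "discharge before admission"
            u, t, kind = open_stay
            if row.ts <= t:
                return [], "discharge not after entry"
            stays.append((case_id, u, department, t, row.ts, kind, "discharge"))
            open_stay = None
            closed = True
    if open_stay is not None or not closed:
        return [], "no discharge event"
    return stays, None


def link_patient_side(
    raw: RawBundle,
    funnel: Funnel,
    maternity_department: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pair movement events into stays and join the discharge record.

    Exclusions recorded in the funnel: outpatient cases, healthy
    newborns (in the maternity department when one is named, otherwise
    wherever flagged).  Cases whose event sequence cannot be paired land
    in the reject report.
    """
    case_ids = pd.Index(raw.activity["case_id"].dropna().unique())
    n_retained = len(case_ids)

    mv = raw.movements[raw.movements["case_id"].isin(case_ids)].copy()
    outpatient = pd.Index(mv.loc[mv["setting"] == "outpatient", "case_id"].unique())
    funnel.add("outpatient cases excluded", "cases", len(outpatient), n_retained, kind="excluded")

    disc = raw.discharge[raw.discharge["case_id"].isin(case_ids)]
    nb = disc["healthy_newborn"].astype(bool)
    if maternity_department is not None:
        nb = nb & (disc["department"] == maternity_department)
    newborn = pd.Index(disc.loc[nb, "case_id"].unique()).difference(outpatient)
    funnel.add("healthy newborn cases excluded", "cases", len(newborn), n_retained, kind="excluded")

    used = case_ids.difference(outpatient).difference(newborn)
    no_discharge_record = used.difference(disc["case_id"])
    used = used.difference(no_discharge_record)
    funnel.add("cases used", "cases", len(used), n_retained)

    disc = disc.set_index("case_id")
    mv = mv[mv["case_id"].isin(used)]
    mv["ts"] = mv["date"] + mv["time"]
    mv["_order"] = mv["event"].map(_EVENT_ORDER)
    mv = mv.sort_values(["case_id", "ts", "_order"], kind="stable")

    stay_rows: list[tuple] = []
    reject_rows: list[tuple] = []
    paired_cases: list[str] = []
    for cid, ev in mv.groupby("case_id", sort=False):
        dept = disc.at[cid, "department"]
        rows, err = _pair_case_events(cid, ev, dept)
        if err is not None:
            reject_rows.append(("movements", cid, "event", err))
            continue
        stay_rows.extend(rows)
        paired_cases.append(cid)

    cases = disc.loc[paired_cases].reset_index()
    bad_dates = cases["discharge_date"] < cases["admission_date"]
    for cid in cases.loc[bad_dates, "case_id"]:
        reject_rows.append(("discharge", cid, "discharge_date", "discharge before admission"))
    dropped = set(cases.loc[bad_dates, "case_id"])
    cases = cases[~bad_dates].copy()
    if dropped:
        stay_rows = [r for r in stay_rows if r[0] not in dropped]

    cases["los_days"] = [
        compute_los(a, d) for a, d in zip(cases["admission_date"], cases["discharge_date"])
    ]
    cases = cases[CASE_COLUMNS]
    stays = pd.DataFrame(stay_rows, columns=STAY_COLUMNS)
    rejects = pd.DataFrame(reject_rows, columns=REJECT_COLUMNS)
    for cid in no_discharge_record:
        rejects.loc[len(rejects)] = ("discharge", cid, "case_id", "no discharge record")
    return stays, cases, rejects


# ---------------------------------------------------------------------------
# Stage 4: deidentification
# ---------------------------------------------------------------------------

def deidentify(linked: LinkedDataset, keep_map: bool = False) -> LinkedDataset:
    """Replace raw identifiers by stable pseudonyms.

    Pseudonyms are assigned in sorted raw-id order, so the same input
    always yields the same mapping.  The mapping is discarded unless
    ``keep_map`` is set.
    """
    patients = sorted(set(linked.cases["case_id"]) | set(linked.stays["case_id"]))
    nurses = sorted(set(linked.shifts["nurse_id"]))
    units = sorted(
        set(linked.stays["unit_id"])
        | set(linked.shifts["unit_id"])
        | (set(linked.daily_presence["unit_id"]) if not linked.daily_presence.empty else set())
    )
    pmap = {raw: f"Patient{i + 1}" for i, raw in enumerate(patients)}
    nmap = {raw: f"Nurse{i + 1}" for i, raw in enumerate(nurses)}
    umap = {raw: f"Unit{i + 1}" for i, raw in enumerate(units)}

    stays = linked.stays.assign(
        case_id=linked.stays["case_id"].map(pmap), unit_id=linked.stays["unit_id"].map(umap)
    )
    shifts = linked.shifts.assign(
        nurse_id=linked.shifts["nurse_id"].map(nmap), unit_id=linked.shifts["unit_id"].map(umap)
    )
    cases = linked.cases.assign(case_id=linked.cases["case_id"].map(pmap))
    presence = linked.daily_presence
    if not presence.empty:
        presence = presence.assign(unit_id=presence["unit_id"].map(umap))

    return LinkedDataset(
        stays=stays,
        shifts=shifts,
        cases=cases,
        daily_presence=presence,
        funnel=linked.funnel,
        rejects=linked.rejects,
        info=linked.info,
        id_map={"patients": pmap, "nurses": nmap, "units": umap} if keep_map else None,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def link(
    raw: RawBundle,
    maternity_department: str | None = None,
    keep_map: bool = False,
) -> LinkedDataset:
    """Run the full linkage: filter -> nurse side -> patient side ->
    deidentify; returns the :class:`LinkedDataset` with its funnel."""
    filtered, funnel = filter_care_activity(raw)
    shifts, daily_presence, info = link_nurse_side(filtered, funnel)
    stays, cases, rejects = link_patient_side(filtered, funnel, maternity_department)
    rejects = pd.concat([raw.rejects[REJECT_COLUMNS], rejects], ignore_index=True)
    linked = LinkedDataset(
        stays=stays,
        shifts=shifts,
        cases=cases,
        daily_presence=daily_presence,
        funnel=funnel,
        rejects=rejects,
        info=info,
    )
    return deidentify(linked, keep_map=keep_map)
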