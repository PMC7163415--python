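"""Linkage stage: reading/writing, the care-activity filter, nurse- and
patient-side joins, event pairing, deidentification and the funnel."""

import numpy as np
import pandas as pd
import pytest

import wardflow as wf
from wardflow.ingest import (
    Funnel,
    filter_care_activity,
    funnel_report,
    link,
    link_patient_side,
    typed_from_sheets,
)
from wardflow.io import SchemaError, read_sources, write_sheets


# ---------------------------------------------------------------------------
# io round trips and validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt", ["csv", "parquet"])
def test_write_read_round_trip_preserves_records(bundle, tmp_path, fmt):
    write_sheets(bundle.sheets(), tmp_path, fmt=fmt)
    raw = read_sources(tmp_path, fmt=fmt)
    assert raw.rejects.empty
    assert len(raw.activity) == len(bundle.activity)
    assert len(raw.movements) == len(bundle.movements)
    # timestamps survive the round trip to the second
    ts = (raw.movements["date"] + raw.movements["time"]).sort_values().reset_index(drop=True)
    orig = pd.to_datetime(
        bundle.movements["date"] + " " + bundle.movements["time"]
    ).sort_values().reset_index(drop=True)
    pd.testing.assert_series_equal(ts, orig, check_names=False)


def test_empty_sheets_give_empty_bundle(bundle, tmp_path):
    empty = {name: df.iloc[0:0] for name, df in bundle.sheets().items()}
    write_sheets(empty, tmp_path)
    raw = read_sources(tmp_path)
    assert raw.rejects.empty and raw.activity.empty and raw.discharge.empty


def test_missing_column_is_a_hard_error_naming_it(bundle, tmp_path):
    sheets = bundle.sheets().copy()
    sheets["movements"] = sheets["movements"].drop(columns=["time"])
    write_sheets(sheets, tmp_path)
    with pytest.raises(SchemaError, match="time"):
        read_sources(tmp_path)


def test_malformed_rows_land_in_reject_report(bundle, tmp_path):
    sheets = bundle.sheets().copy()
    mv = sheets["movements"].copy()
    mv.loc[0, "time"] = "25:99"
    mv.loc[1, "event"] = "teleport"
    sheets["movements"] = mv
    write_sheets(sheets, tmp_path)
    raw = read_sources(tmp_path)
    assert len(raw.movements) == len(mv) - 2
    reasons = raw.rejects.set_index("row")["reason"]
    assert "time" in raw.rejects["column"].tolist()
    assert reasons.loc[0].startswith("unparseable time")


# ---------------------------------------------------------------------------
# activity filter
# ---------------------------------------------------------------------------

def test_care_filter_keeps_only_inpatient_care_rows(defect_bundle):
    raw = typed_from_sheets(defect_bundle.sheets())
    filtered, funnel = filter_care_activity(raw)
    assert (filtered.activity["activity_type"] == "care").all()
    assert (filtered.activity["setting"] == "inpatient").all()
    frame = funnel.to_frame()
    src = frame[(frame["stage"] == "source activity") & (frame["metric"] == "cases")]
    kept = frame[(frame["stage"] == "inpatient care activity") & (frame["metric"] == "cases")]
    assert kept["numerator"].iat[0] <= src["numerator"].iat[0]


def test_all_outpatient_activity_retains_nothing(bundle):
    sheets = bundle.sheets().copy()
    sheets["activity"] = sheets["activity"].assign(setting="outpatient")
    filtered, funnel = filter_care_activity(typed_from_sheets(sheets))
    assert filtered.activity.empty
    frame = funnel.to_frame()
    kept = frame[(frame["stage"] == "inpatient care activity") & (frame["metric"] == "cases")]
    assert kept["numerator"].iat[0] == 0 and kept["percent"].iat[0] == 0.0


# ---------------------------------------------------------------------------
# nurse side
# ---------------------------------------------------------------------------

def test_nurse_days_without_hours_are_excluded_per_day(defect_cfg, defect_bundle):
    raw = typed_from_sheets(defect_bundle.sheets())
    ld = link(raw, maternity_department=defect_cfg.maternity_department)
    missing = set(defect_bundle.defects["missing_working_hours_nurses"])
    assert missing, "defect config should remove some nurses' hours"
    # affected nurse-days are excluded; no other nurse-day can be
    seg = defect_bundle.truth.segments
    expected_lost = (
        seg[seg["nurse_id"].isin(missing)]
        .assign(date=lambda d: d["start_ts"].dt.normalize())
        .drop_duplicates(["nurse_id", "date"])
    )
    assert 0 < ld.info["excluded_person_days"] <= len(expected_lost)
    # nurses losing their hours still keep activity but emit no shifts
    assert not set(ld.shifts["nurse_id"]) & missing
    frame = ld.funnel.to_frame()
    row = frame[frame["metric"] == "person_days"].iloc[0]
    assert row["numerator"] == ld.info["excluded_person_days"]


def test_daily_groups_routed_to_daily_presence_not_shifts(linked, bundle):
    assert set(linked.daily_presence["group"]).issubset({4, 5})
    assert set(linked.shifts["group"]).issubset({1, 2, 3})
    expected = bundle.truth.daily_presence["count"].sum()
    assert linked.daily_presence["count"].sum() == expected


def test_contract_identifiers_do_not_survive_linkage(linked):
    for df in (linked.stays, linked.shifts, linked.cases, linked.daily_presence):
        assert "contract_id" not in df.columns


# ---------------------------------------------------------------------------
# patient side: pairing
# ---------------------------------------------------------------------------

def _movement_sheets(movement_rows, cases):
    """Minimal five-sheet dict around hand-written movement rows."""
    case_ids = sorted({r[0] for r in movement_rows})
    activity = pd.DataFrame(
        [("N1", "K1", c, "U01", "2015-01-01", "care", "inpatient") for c in case_ids],
        columns=["nurse_id", "contract_id", "case_id", "unit_id", "date", "activity_type", "setting"],
    )
    nurses = pd.DataFrame([("N1", "K1", 1)], columns=["nurse_id", "contract_id", "group"])
    wh = pd.DataFrame(
        [("N1", "K1", "2015-01-01", "07:00:00", "15:00:00")],
        columns=["nurse_id", "contract_id", "date", "start_time", "end_time"],
    )
    movements = pd.DataFrame(
        movement_rows, columns=["case_id", "unit_id", "event", "date", "time", "setting"]
    )
    discharge = pd.DataFrame(cases, columns=[
        "case_id", "age_years", "admission_date", "discharge_date", "main_dx", "department", "healthy_newborn",
    ])
    return {
        "activity": activity, "nurses": nurses, "working_hours": wh,
        "movements": movements, "discharge": discharge,
    }


def test_case_without_transfer_yields_exactly_one_stay():
    sheets = _movement_sheets(
        [
            ("C1", "U01", "admission", "2015-01-01", "10:00:01", "inpatient"),
            ("C1", "U01", "discharge", "2015-01-03", "14:30:01", "inpatient"),
        ],
        [("C1", 50, "2015-01-01", "2015-01-03", "I21.0", "Internal Medicine", False)],
    )
    raw = typed_from_sheets(sheets)
    stays, cases, rejects = link_patient_side(*filter_care_activity(raw))
    assert rejects.empty and len(stays) == 1
    st = stays.iloc[0]
    assert (st["entry_kind"], st["exit_kind"]) == ("admission", "discharge")
    assert cases["los_days"].iat[0] == 2


def test_single_transfer_splits_into_two_stays_sharing_the_timestamp():
    sheets = _movement_sheets(
        [
            ("C1", "U01", "admission", "2015-01-01", "10:00:01", "inpatient"),
            ("C1", "U02", "transfer", "2015-01-02", "09:15:01", "inpatient"),
            ("C1", "U02", "discharge", "2015-01-03", "14:30:01", "inpatient"),
        ],
        [("C1", 50, "2015-01-01", "2015-01-03", "I21.0", "Internal Medicine", False)],
    )
    stays, _, rejects = link_patient_side(*filter_care_activity(typed_from_sheets(sheets)))
    assert rejects.empty and len(stays) == 2
    first, second = stays.sort_values("entry_ts").itertuples(index=False)
    assert first.exit_kind == "transfer_out" and second.entry_kind == "transfer_in"
    assert first.exit_ts == second.entry_ts
    assert (first.unit_id, second.unit_id) == ("U01", "U02")


@pytest.mark.parametrize(
    "rows, reason",
    [
        (
            [
                ("C1", "U01", "admission", "2015-01-01", "10:00:01", "inpatient"),
                ("C1", "U02", "admission", "2015-01-02", "10:00:01", "inpatient"),
                ("C1", "U02", "discharge", "2015-01-03", "10:00:01", "inpatient"),
            ],
            "second admission",
        ),
        (
            [("C1", "U01", "discharge", "2015-01-01", "10:00:01", "inpatient")],
            "discharge before admission",
        ),
        (
            [("C1", "U01", "admission", "2015-01-01", "10:00:01", "inpatient")],
            "no discharge",
        ),
    ],
)
def test_unpairable_event_sequences_are_rejected_with_reason(rows, reason):
    sheets = _movement_sheets(
        rows, [("C1", 50, "2015-01-01", "2015-01-03", "I21.0", "Internal Medicine", False)]
    )
    stays, cases, rejects = link_patient_side(*filter_care_activity(typed_from_sheets(sheets)))
    assert stays.empty and cases.empty
    assert len(rejects) == 1 and reason in rejects["reason"].iat[0]


def test_outpatient_and_newborn_cases_are_excluded_with_funnel_counts(defect_cfg, defect_bundle):
    raw = typed_from_sheets(defect_bundle.sheets())
    ld = link(raw, maternity_department=defect_cfg.maternity_department)
    frame = ld.funnel.to_frame().set_index("stage")
    truth = defect_bundle.truth.cases
    linked_case_count = frame.loc["cases used", "numerator"]
    assert linked_case_count == len(ld.cases)
    # outpatient + newborn + used account for every retained case
    retained = frame.loc["cases used", "denominator"]
    assert (
        frame.loc["outpatient cases excluded", "numerator"]
        + frame.loc["healthy newborn cases excluded", "numerator"]
        + linked_case_count
        == retained
    )
    assert frame.loc["outpatient cases excluded", "numerator"] > 0
    assert frame.loc["healthy newborn cases excluded", "numerator"] > 0
    assert truth["outpatient"].sum() >= frame.loc["outpatient cases excluded", "numerator"]


# ---------------------------------------------------------------------------
# truth recovery and deidentification
# ---------------------------------------------------------------------------

def test_defect_free_linkage_recovers_generator_truth(bundle, linked):
    inv_u = {v: k for k, v in linked.id_map["units"].items()}
    inv_p = {v: k for k, v in linked.id_map["patients"].items()}
    inv_n = {v: k for k, v in linked.id_map["nurses"].items()}
    cols = ["case_id", "unit_id", "entry_ts", "exit_ts", "entry_kind", "exit_kind"]
    got = (
        linked.stays.assign(
            case_id=linked.stays["case_id"].map(inv_p),
            unit_id=linked.stays["unit_id"].map(inv_u),
        )[cols]
        .sort_values(cols)
        .reset_index(drop=True)
    )
    want = bundle.truth.stays[cols].sort_values(cols).reset_index(drop=True)
    pd.testing.assert_frame_equal(got, want)

    cols = ["nurse_id", "unit_id", "group", "start_ts", "end_ts"]
    got = (
        linked.shifts.assign(
            nurse_id=linked.shifts["nurse_id"].map(inv_n),
            unit_id=linked.shifts["unit_id"].map(inv_u),
        )[cols]
        .sort_values(cols)
        .reset_index(drop=True)
    )
    want = (
        bundle.truth.segments[cols]
        .astype({"group": int})
        .sort_values(cols)
        .reset_index(drop=True)
    )
    pd.testing.assert_frame_equal(got, want)


def test_deidentified_output_contains_no_raw_identifier(bundle, linked):
    raw_ids = (
        set(bundle.nurses["nurse_id"])
        | set(bundle.nurses["contract_id"])
        | set(bundle.discharge["case_id"])
        | set(bundle.movements["unit_id"])
    )
    for df in (linked.stays, linked.shifts, linked.cases, linked.daily_presence):
        for col in df.columns:
            assert not set(df[col].astype(str)) & raw_ids, f"raw id leaked in {col}"


def test_pseudonyms_are_stable_and_cover_distinct_ids(bundle, demo_cfg, linked):
    again = link(
        typed_from_sheets(bundle.sheets()),
        maternity_department=demo_cfg.maternity_department,
        keep_map=True,
    )
    assert again.id_map == linked.id_map
    assert len(set(linked.id_map["patients"].values())) == len(linked.id_map["patients"])
    assert set(linked.stays["unit_id"]).issubset(set(linked.id_map["units"].values()))


# ---------------------------------------------------------------------------
# funnel report
# ---------------------------------------------------------------------------

def test_funnel_percent_arithmetic_known_pairs():
    funnel = Funnel()
    funnel.add("units retained", "units", 70, 152)
    funnel.add("nurses usable", "nurses", 4633, 5736)
    funnel.add("degenerate", "cases", 0, 0)
    report = funnel_report(funnel)
    assert report["percent"].tolist()[:2] == [46.1, 80.8]
    assert np.isnan(report["percent"].iat[2])


def test_funnel_retained_counts_never_increase_along_stages(linked):
    frame = linked.funnel.to_frame()
    retained = frame[frame["kind"] == "retained"]
    for _, series in retained.groupby("metric")["numerator"]:
        assert (series.diff().dropna() <= 0).all()
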