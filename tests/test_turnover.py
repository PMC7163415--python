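"""Turnover: slot assignment of ADT events, transfer conservation,
census normalisation and department profiles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wardflow.census import build_census, build_slot_grid, count_patients
from wardflow.turnover import EVENT_COUNT_COLUMNS, aggregate_profiles, count_events, normalize

from _oracles import brute_force_event_tally, random_stays

STAY_COLS = ["case_id", "unit_id", "department", "entry_ts", "exit_ts", "entry_kind", "exit_kind"]


def _stays(rows):
    return pd.DataFrame(
        [
            (f"C{i}", u, "D", pd.Timestamp(e), pd.Timestamp(x), ek, xk)
            for i, (u, e, x, ek, xk) in enumerate(rows)
        ],
        columns=STAY_COLS,
    )


def test_event_assigned_to_enclosing_half_open_window():
    grid = build_slot_grid(["U1"], dt.date(2015, 1, 1), dt.date(2015, 1, 1), 30)
    stays = _stays([("U1", "2015-01-01 09:15:01", "2015-01-01 12:00:01", "admission", "discharge")])
    events, excluded = count_events(stays, grid)
    assert excluded.empty
    at = events.set_index(events["timestamp"].dt.strftime("%H:%M"))
    assert at.loc["09:00", "n_admissions"] == 1
    assert at.loc["09:30", "n_admissions"] == 0
    assert at.loc["12:00", "n_discharges"] == 1


def test_one_transfer_contributes_one_out_and_one_in():
    grid = build_slot_grid(["U1", "U2"], dt.date(2015, 1, 1), dt.date(2015, 1, 1), 30)
    t = "2015-01-01 10:20:01"
    stays = _stays(
        [
            ("U1", "2015-01-01 08:00:01", t, "admission", "transfer_out"),
            ("U2", t, "2015-01-01 20:00:01", "transfer_in", "discharge"),
        ]
    )
    events, _ = count_events(stays, grid)
    assert events["n_transfers_out"].sum() == 1
    assert events["n_transfers_in"].sum() == 1
    out_slot = events.loc[events["n_transfers_out"] == 1].iloc[0]
    in_slot = events.loc[events["n_transfers_in"] == 1].iloc[0]
    assert out_slot["unit_id"] == "U1" and in_slot["unit_id"] == "U2"
    assert out_slot["timestamp"] == in_slot["timestamp"]


def test_events_outside_grid_span_are_excluded_and_logged():
    grid = build_slot_grid(["U1"], dt.date(2015, 1, 2), dt.date(2015, 1, 2), 30)
    stays = _stays([("U1", "2015-01-01 09:00:01", "2015-01-03 10:00:01", "admission", "discharge")])
    events, excluded = count_events(stays, grid)
    assert events[EVENT_COUNT_COLUMNS].to_numpy().sum() == 0
    assert len(excluded) == 2
    assert set(excluded["reason"]) == {"outside grid span"}


def test_event_counts_match_brute_force_tally():
    rng = np.random.default_rng(7)
    units = ["U1", "U2"]
    grid = build_slot_grid(units, dt.date(2015, 3, 2), dt.date(2015, 3, 10), 30)
    stays = random_stays(rng, units, "2015-03-02", 400, max_hours=48)
    events, _ = count_events(stays, grid)
    ts = grid.timestamps()
    for unit in units:
        sub = events[events["unit_id"] == unit].sort_values("timestamp")
        s = stays[stays["unit_id"] == unit]
        adm = s.loc[s["entry_kind"] == "admission", "entry_ts"]
        np.testing.assert_array_equal(
            sub["n_admissions"].to_numpy(), brute_force_event_tally(adm, ts, 30)
        )
        dis = s.loc[s["exit_kind"] == "discharge", "exit_ts"]
        np.testing.assert_array_equal(
            sub["n_discharges"].to_numpy(), brute_force_event_tally(dis, ts, 30)
        )


def test_normalisation_divides_by_census_and_keeps_counts_at_zero_census():
    grid = build_slot_grid(["U1"], dt.date(2015, 1, 1), dt.date(2015, 1, 1), 30)
    stays = _stays(
        [("U1", "2015-01-01 06:00:01", "2015-01-01 23:00:01", "admission", "discharge")] * 20
        + [("U1", "2015-01-01 10:10:01", "2015-01-01 23:30:01", "admission", "discharge")] * 2
    )
    census = build_census(stays, pd.DataFrame(columns=["nurse_id", "unit_id", "group", "start_ts", "end_ts"]), grid)
    events, _ = count_events(stays, grid)
    points = normalize(events, census)
    at = points.set_index(points["timestamp"].dt.strftime("%H:%M"))
    # 2 admissions in the 10:00 slot with 20 patients present at 10:00
    assert at.loc["10:00", "n_admissions"] == 2
    assert at.loc["10:00", "r_admissions"] == pytest.approx(0.1)
    # before any admission the census is zero: counts kept, ratio missing
    assert at.loc["06:00", "n_admissions"] == 20
    assert np.isnan(at.loc["06:00", "r_admissions"])


def test_normalize_rejects_mismatched_grids():
    grid = build_slot_grid(["U1"], dt.date(2015, 1, 1), dt.date(2015, 1, 1), 30)
    other = build_slot_grid(["U1"], dt.date(2015, 1, 2), dt.date(2015, 1, 2), 30)
    stays = _stays([("U1", "2015-01-01 09:00:01", "2015-01-01 10:00:01", "admission", "discharge")])
    events, _ = count_events(stays, grid)
    census = count_patients(stays, other)
    with pytest.raises(ValueError, match="different grids"):
        normalize(events, census)


def test_single_unit_profile_equals_unit_series_and_signs():
    grid = build_slot_grid(["U1"], dt.date(2015, 1, 5), dt.date(2015, 1, 9), 30)  # weekdays
    stays = _stays(
        [
            ("U1", f"2015-01-0{d} 09:10:01", f"2015-01-0{d} 14:40:01", "admission", "discharge")
            for d in range(5, 10)
        ]
        + [("U1", "2015-01-05 00:00:01", "2015-01-10 00:00:01", "admission", "discharge")]
    )
    census = build_census(stays, pd.DataFrame(columns=["nurse_id", "unit_id", "group", "start_ts", "end_ts"]), grid)
    events, _ = count_events(stays, grid)
    points = normalize(events, census)
    profiles = aggregate_profiles(points, {"U1": "D"})
    assert set(profiles["daytype"]) == {"weekday"}
    adm = profiles[(profiles["event"] == "admissions") & (profiles["tod"] == "09:00")].iloc[0]
    unit_mean = points.loc[
        points["timestamp"].dt.strftime("%H:%M") == "09:00", "r_admissions"
    ].mean()
    assert adm["mean_ratio"] == pytest.approx(unit_mean)
    assert adm["signed_ratio"] == adm["mean_ratio"] and adm["side"] == "incoming"
    dis = profiles[(profiles["event"] == "discharges") & (profiles["tod"] == "14:30")].iloc[0]
    assert dis["signed_ratio"] == -dis["mean_ratio"] and dis["side"] == "leaving"


def test_department_profile_is_mean_of_unit_profiles():
    grid = build_slot_grid(["U1", "U2"], dt.date(2015, 1, 5), dt.date(2015, 1, 5), 30)
    stays = _stays(
        [
            ("U1", "2015-01-05 00:00:01", "2015-01-05 23:59:59", "admission", "discharge"),
            ("U1", "2015-01-05 09:01:01", "2015-01-05 22:00:01", "admission", "discharge"),
            ("U2", "2015-01-05 00:00:01", "2015-01-05 23:59:59", "admission", "discharge"),
            ("U2", "2015-01-05 00:00:02", "2015-01-05 23:59:58", "admission", "discharge"),
            ("U2", "2015-01-05 09:15:01", "2015-01-05 22:00:01", "admission", "discharge"),
        ]
    )
    census = build_census(stays, pd.DataFrame(columns=["nurse_id", "unit_id", "group", "start_ts", "end_ts"]), grid)
    events, _ = count_events(stays, grid)
    points = normalize(events, census)
    profiles = aggregate_profiles(points, {"U1": "D", "U2": "D"})
    adm = profiles[(profiles["event"] == "admissions") & (profiles["tod"] == "09:00")].iloc[0]
    # U1: 1 admission / 1 present; U2: 1 admission / 2 present -> mean 0.75
    assert adm["mean_ratio"] == pytest.approx((1.0 + 0.5) / 2)


def test_no_nocturnal_events_means_zero_night_turnover():
    # all entries/exits within 08:00-20:00 -> night slots are exactly zero
    rng = np.random.default_rng(11)
    rows = []
    for i in range(150):
        day = 5 + rng.integers(0, 5)
        e_min = int(rng.integers(8 * 60, 18 * 60))
        x_min = int(rng.integers(e_min + 30, 20 * 60))
        rows.append(
            (
                "U1",
                pd.Timestamp(f"2015-01-{day:02d}") + pd.Timedelta(minutes=e_min, seconds=1),
                pd.Timestamp(f"2015-01-{day:02d}") + pd.Timedelta(minutes=x_min, seconds=1),
                "admission",
                "discharge",
            )
        )
    stays = _stays(rows)
    grid = build_slot_grid(["U1"], dt.date(2015, 1, 5), dt.date(2015, 1, 9), 30)
    events, _ = count_events(stays, grid)
    night = events[~events["timestamp"].dt.hour.between(8, 19)]
    assert night[EVENT_COUNT_COLUMNS].to_numpy().sum() == 0


def test_hospital_wide_transfer_balance(bundle, grid):
    events, _ = count_events(bundle.truth.stays, grid)
    assert events["n_transfers_in"].sum() == events["n_transfers_out"].sum()


def test_census_first_difference_equals_entries_minus_exits(bundle, census_df, grid):
    events, _ = count_events(bundle.truth.stays, grid)
    for unit in grid.units:
        c = census_df[census_df["unit_id"] == unit].sort_values("timestamp")
        e = events[events["unit_id"] == unit].sort_values("timestamp")
        dn = np.diff(c["n_patients"].to_numpy())
        net = (
            e["n_admissions"] + e["n_transfers_in"] - e["n_discharges"] - e["n_transfers_out"]
        ).to_numpy()[:-1]
        np.testing.assert_array_equal(dn, net)
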