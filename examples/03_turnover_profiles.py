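"""Census-normalised patient turnover profiles.

Counts admissions, discharges and transfers in/out per 30-minute slot,
divides them by the patients present at the same instant (so units of
different sizes are comparable), and averages the unit series into
department profiles split by weekday/weekend.  Exits carry a negative
sign, matching the leaving side of a vertical bar chart.
"""

import wardflow as wf
from wardflow.census import build_census, build_slot_grid
from wardflow.synthetic import make_bundle
from wardflow.turnover import aggregate_profiles, count_events, normalize

config = wf.demo_config(seed=42)
bundle = make_bundle(config)
grid = build_slot_grid(config.units, config.start_date, config.end_date, 30)
census = build_census(bundle.truth.stays, bundle.truth.segments, grid)

events, excluded = count_events(bundle.truth.stays, grid)
print(f"{events[['n_admissions', 'n_discharges']].sum().sum()} admission/discharge events, "
      f"{events['n_transfers_in'].sum()} transfers "
      f"(in == out: {events['n_transfers_in'].sum() == events['n_transfers_out'].sum()}), "
      f"{len(excluded)} events outside the grid span.")

points = normalize(events, census)
profiles = aggregate_profiles(points, config.unit_department)

morning = profiles[
    (profiles["department"] == "Internal Medicine")
    & (profiles["daytype"] == "weekday")
    & profiles["tod"].between("08:00", "11:30")
]
print("\nInternal Medicine, weekday mid-morning turnover "
      "(mean ratio = events per patient present):")
print(
    morning.pivot(index="tod", columns="event", values="signed_ratio")
    .round(3)
    .to_string()
)
print("\nPositive columns are incoming patients (admissions, transfers in); "
      "negative are leaving (discharges, transfers out). The morning peak in "
      "both directions is the workload the plain census does not show.")
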