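"""Department-level descriptive overview, end to end.

Runs the whole pipeline (simulate -> link -> census -> descriptives) and
prints the department table: volumes, age and length-of-stay summaries,
the noon census per unit and day, and the two most common diagnoses at
ICD-10 chapter level with incidence n/N (%).
"""

import wardflow as wf

result = wf.run(wf.demo_config(seed=42))
overview = result.overview

cols = [
    "department", "n_patients", "n_units",
    "age_mean", "age_sd", "age_median",
    "los_median", "los_q1", "los_q3",
    "patients_day_unit_median",
]
print(overview[cols].round(1).to_string(index=False))
print()
for row in overview.itertuples(index=False):
    print(
        f"{row.department}: top diagnoses {row.dx1_chapter} "
        f"{row.dx1_n}/{row.n_patients} ({row.dx1_pct}%), "
        f"then {row.dx2_chapter} {row.dx2_n}/{row.n_patients} ({row.dx2_pct}%)"
    )
print("\nIncidence percentages are per-department shares of the linked cases; "
      "patients/day/unit is the patient census sampled at the daily noon slot.")

summary = result.presence_summary
if not summary.empty:
    print("\nStudents/external nurses (daily presence only):")
    print(summary.round(2).to_string(index=False))
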