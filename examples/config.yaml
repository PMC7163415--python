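# Example generator configuration for `wardflow simulate` / `wardflow run`.
# Departments may map to unit counts (units auto-named U01, U02, ...) or to
# explicit unit-id lists.  Omitted sections fall back to library defaults
# (three-shift roster, lognormal LOS, peaked admission profile).
departments:
  Internal Medicine: 2
  Maternity & Gynecology: 1
start_date: 2015-01-01
end_date: 2015-02-28
seed: 42

admission_rate:
  base: 0.14            # mean admissions per unit-hour (daily/weekly profile applied)

los_dist:
  "*": {family: lognormal, params: {median_days: 3.0, sigma: 0.6}}
  Maternity & Gynecology: {family: lognormal, params: {median_days: 3.5, sigma: 0.4}}

age_dist:
  "*": [62.0, 17.0]
  Maternity & Gynecology: [36.5, 15.4]

transfer_prob: 0.04     # transfers per patient-day

icd10_chapter_weights:
  "*": {IX: 0.3, II: 0.2, XI: 0.25, X: 0.25}
  Maternity & Gynecology: {XV: 0.6, II: 0.2, XIV: 0.2}

maternity_department: Maternity & Gynecology

defect_rates:
  missing_working_hours: 0.02
  outpatient: 0.12
  newborn: 0.25
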