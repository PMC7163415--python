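# Input sheet schemas

Five delimited tables (CSV or Parquet, one file per sheet, named
`<sheet>.csv` / `<sheet>.parquet`) form the input bundle.  The
machine-readable version of this contract lives in
`wardflow.schemas.SHEET_SCHEMAS`; reading validates it — a missing
column is a hard error, malformed rows go to a reject report.

Common conventions: dates are ISO `YYYY-MM-DD`; clock times are
`HH:MM:SS`; identifiers are opaque strings.

## activity

One row per nurse, case and day a time allocation was recorded.

| column | type | notes |
| --- | --- | --- |
| nurse_id | str | |
| contract_id | str | deleted during linkage |
| case_id | str, nullable | empty for non-care rows |
| unit_id | str | |
| date | date | working date of the nurse |
| activity_type | enum | care, administrative, teaching, continuous_education, absence |
| setting | enum | inpatient, outpatient |

## nurses

| column | type | notes |
| --- | --- | --- |
| nurse_id | str | |
| contract_id | str | a nurse can hold several contracts |
| group | int | 1 RN, 2 LPN, 3 other, 4 student, 5 external |

## working_hours

One row per contiguous working segment (breaks split a shift).

| column | type | notes |
| --- | --- | --- |
| nurse_id | str | |
| contract_id | str | |
| date | date | calendar date the segment starts |
| start_time | time | begin work / return from break |
| end_time | time | stop work / start break; end <= start means the segment crosses midnight |

## movements

Patient ADT events; for transfer rows `unit_id` is the destination.

| column | type | notes |
| --- | --- | --- |
| case_id | str | |
| unit_id | str | |
| event | enum | admission, discharge, transfer |
| date | date | |
| time | time | |
| setting | enum | inpatient, outpatient |

## discharge

One row per case from the medical discharge source.

| column | type | notes |
| --- | --- | --- |
| case_id | str | |
| age_years | float >= 0 | age at admission |
| admission_date | date | |
| discharge_date | date | not before admission_date |
| main_dx | ICD-10(-GM) code | `[A-Z][0-9]{2}` prefix |
| department | str | label, survives deidentification |
| healthy_newborn | bool | maternity newborn flag |
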