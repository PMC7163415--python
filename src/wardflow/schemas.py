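"""Column schemas of the five input sheets.

These are the on-disk contracts shared by the synthetic generator
(writer) and the ingest stage (reader); docs/schema.md renders the same
information for humans.  Kinds: ``str`` (opaque key/label), ``date``
(ISO yyyy-mm-dd), ``time`` (HH:MM:SS), ``int``, ``float``, ``bool``,
``enum:<v1|v2|...>``, ``icd10``.  A trailing ``?`` marks a nullable
column.
"""

from __future__ import annotations

ACTIVITY = "activity"
NURSES = "nurses"
WORKING_HOURS = "working_hours"
MOVEMENTS = "movements"
DISCHARGE = "discharge"

SHEETS = (ACTIVITY, NURSES, WORKING_HOURS, MOVEMENTS, DISCHARGE)

SHEET_SCHEMAS: dict[str, dict[str, str]] = {
    ACTIVITY: {
        "nurse_id": "str",
        "contract_id": "str",
        "case_id": "str?",  # empty for administrative/teaching/education/absence rows
        "unit_id": "str",
        "date": "date",
        "activity_type": "enum:care|administrative|teaching|continuous_education|absence",
        "setting": "enum:inpatient|outpatient",
    },
    NURSES: {
        "nurse_id": "str",
        "contract_id": "str",
        "group": "int",  # 1 RN, 2 LPN, 3 other, 4 student, 5 external
    },
    WORKING_HOURS: {
        "nurse_id": "str",
        "contract_id": "str",
        "date": "date",   # calendar date the segment starts
        "start_time": "time",
        "end_time": "time",  # end <= start means the segment crosses midnight
    },
    MOVEMENTS: {
        "case_id": "str",
        "unit_id": "str",  # for transfer rows: the destination unit
        "event": "enum:admission|discharge|transfer",
        "date": "date",
        "time": "time",
        "setting": "enum:inpatient|outpatient",
    },
    DISCHARGE: {
        "case_id": "str",
        "age_years": "float",
        "admission_date": "date",
        "discharge_date": "date",
        "main_dx": "icd10",
        "department": "str",
        "healthy_newborn": "bool",
    },
}
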