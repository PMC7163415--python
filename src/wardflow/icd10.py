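"""ICD-10 chapter lookup.

Main diagnoses are coded with ICD-10-GM; at chapter granularity the GM
modification coincides with the WHO chapter ranges, so codes are grouped
here purely by their three-character prefix.  The table is embedded as
data: (first code, last code, chapter numeral, label).
"""

from __future__ import annotations

import re

#: (start, end, numeral, label) — inclusive three-character code ranges.
CHAPTERS: tuple[tuple[str, str, str, str], ...] = (
    ("A00", "B99", "I", "Infectious and parasitic diseases"),
    ("C00", "D48", "II", "Tumors"),
    ("D50", "D89", "III", "Diseases of the blood and immune mechanism"),
    ("E00", "E90", "IV", "Endocrine, nutritional, and metabolic diseases"),
    ("F00", "F99", "V", "Mental and behavioural disorders"),
    ("G00", "G99", "VI", "Nervous system diseases"),
    ("H00", "H59", "VII", "Eye and adnexa diseases"),
    ("H60", "H95", "VIII", "Ear and mastoid diseases"),
    ("I00", "I99", "IX", "Circulatory system diseases"),
    ("J00", "J99", "X", "Respiratory system diseases"),
    ("K00", "K93", "XI", "Digestive system diseases"),
    ("L00", "L99", "XII", "Skin and subcutaneous tissue diseases"),
    ("M00", "M99", "XIII", "Diseases of the osteo-articular system, muscles and connective tissue"),
    ("N00", "N99", "XIV", "Genitourinary system diseases"),
    ("O00", "O99", "XV", "Pregnancy, childbirth, and the puerperium"),
    ("P00", "P96", "XVI", "Some conditions whose origin is the perinatal period"),
    ("Q00", "Q99", "XVII", "Congenital malformations and chromosomal abnormalities"),
    ("R00", "R99", "XVIII", "Symptoms and abnormal clinical and laboratory findings"),
    ("S00", "T98", "XIX", "Traumatic injuries, poisonings, and other consequences of external causes"),
    ("V01", "Y98", "XX", "External causes of morbidity and mortality"),
    ("Z00", "Z99", "XXI", "Factors influencing health status"),
    ("U00", "U99", "XXII", "Codes for special purposes"),
)

UNKNOWN = "unknown"

_CODE_RE = re.compile(r"^([A-Z])([0-9]{2})")


def _key(prefix: str) -> tuple[str, int]:
    return prefix[0], int(prefix[1:3])


def icd10_chapter(code: str, label: bool = True) -> str:
    """Map an ICD-10(-GM) code to its chapter.

    Parameters
    ----------
    code
        A diagnosis code such as ``"I21.0"`` or ``"C34"``.
    label
        Return the chapter label (default) or the roman numeral.

    Returns
    -------
    The chapter label/numeral, or ``"unknown"`` for unmappable codes.
    """
    if not isinstance(code, str):
        return UNKNOWN
    m = _CODE_RE.match(code.strip().upper())
    if m is None:
        return UNKNOWN
    k = (m.group(1), int(m.group(2)))
    for start, end, numeral, name in CHAPTERS:
        if _key(start) <= k <= _key(end):
            return name if label else numeral
    return UNKNOWN


def chapter_label(numeral: str) -> str:
    """Label for a chapter numeral (e.g. ``"IX"`` -> circulatory diseases)."""
    for _, _, num, name in CHAPTERS:
        if num == numeral:
            return name
    raise KeyError(f"unknown ICD-10 chapter numeral: {numeral!r}")


def chapter_codes(numeral: str) -> list[str]:
    """All valid three-character prefixes of a chapter, in code order."""
    for start, end, num, _ in CHAPTERS:
        if num == numeral:
            out = []
            (l0, n0), (l1, n1) = _key(start), _key(end)
            for letter in (chr(c) for c in range(ord(l0), ord(l1) + 1)):
                lo = n0 if letter == l0 else 0
                hi = n1 if letter == l1 else 99
                out.extend(f"{letter}{n:02d}" for n in range(lo, hi + 1))
            return out
    raise KeyError(f"unknown ICD-10 chapter numeral: {numeral!r}")
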