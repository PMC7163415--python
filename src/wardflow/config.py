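"""Simulation configuration for the synthetic hospital event generator.

The generator emulates the two event-log sources the analysis consumes —
nurse-staffing sheets (activities, nurses, working hours, patient
movements) and medical discharge records — for a hospital organised as
departments containing inpatient units.  All knobs that shape the
statistical structure of those sources live here: admission intensity by
hour-of-day and day-of-week, length-of-stay distributions, transfer
rates, shift templates with break rules, the five-group nurse skill mix,
and data-quality defect rates.

Everything is a plain dataclass with eager validation; a YAML loader
(:func:`load_config`) covers the CLI use case.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

#: Nurse qualification groups (five-group scheme).
NURSE_GROUPS = {1: "RN", 2: "LPN", 3: "other", 4: "student", 5: "external"}
#: Groups with exact working-hours records.
HOURLY_GROUPS = (1, 2, 3)
#: Groups recorded with daily presence only (no time breakdown).
DAILY_GROUPS = (4, 5)

ACTIVITY_TYPES = ("care", "administrative", "teaching", "continuous_education", "absence")


def _parse_time(v) -> dt.time:
    if isinstance(v, dt.time):
        return v
    return dt.time.fromisoformat(str(v))


def _parse_date(v) -> dt.date:
    if isinstance(v, dt.datetime):
        return v.date()
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))


@dataclass(frozen=True)
class AdmissionRate:
    """Time-inhomogeneous Poisson admission intensity.

    The hourly intensity for a unit is ``base * hour_of_day[h] *
    day_of_week[d] * unit_weights.get(unit, 1)``.  With the multiplier
    profiles normalised to mean one (see :meth:`default`), ``base`` is the
    average number of admissions per unit per hour.
    """

    base: float
    hour_of_day: tuple[float, ...] = (1.0,) * 24
    day_of_week: tuple[float, ...] = (1.0,) * 7  # Monday .. Sunday
    unit_weights: dict[str, float] | None = None

    def __post_init__(self):
        if self.base < 0:
            raise ValueError(f"admission rate must be nonnegative, got {self.base}")
        if len(self.hour_of_day) != 24 or len(self.day_of_week) != 7:
            raise ValueError("hour_of_day needs 24 multipliers and day_of_week 7")
        if any(m < 0 for m in self.hour_of_day + self.day_of_week):
            raise ValueError("rate multipliers must be nonnegative")
        if self.unit_weights and any(w < 0 for w in self.unit_weights.values()):
            raise ValueError("unit weights must be nonnegative")

    @classmethod
    def constant(cls, per_hour: float) -> "AdmissionRate":
        return cls(base=per_hour)

    @classmethod
    def default(cls, base: float = 0.14) -> "AdmissionRate":
        """Realistic daily shape: a marked 08:00–10:00 admission peak,
        a quiet night, and reduced weekend intake."""
        hod = np.array(
            [0.15, 0.10, 0.08, 0.08, 0.10, 0.20,
             0.60, 1.40, 2.60, 2.60, 2.10, 1.70,
             1.50, 1.60, 1.70, 1.50, 1.20, 1.00,
             0.80, 0.60, 0.45, 0.35, 0.25, 0.20]
        )
        dow = np.array([1.10, 1.10, 1.10, 1.15, 1.05, 0.55, 0.45])
        return cls(
            base=base,
            hour_of_day=tuple(hod / hod.mean()),
            day_of_week=tuple(dow / dow.mean()),
        )

    def rate(self, hour: np.ndarray, dow: np.ndarray, unit: str) -> np.ndarray:
        """Vector of hourly intensities for arrays of hour-of-day/weekday."""
        w = 1.0 if not self.unit_weights else self.unit_weights.get(unit, 1.0)
        hod = np.asarray(self.hour_of_day)
        dw = np.asarray(self.day_of_week)
        return self.base * hod[hour] * dw[dow] * w


@dataclass(frozen=True)
class LosDistribution:
    """Length-of-stay distribution, parameterised in days.

    families: ``lognormal`` (median_days, sigma of the log), ``gamma``
    (shape, scale_days) or ``exponential`` (mean_days).  Hospital LOS is
    right-skewed, hence the lognormal default elsewhere.
    """

    family: str = "lognormal"
    params: dict = field(default_factory=lambda: {"median_days": 3.0, "sigma": 0.6})

    _FAMILIES = ("lognormal", "gamma", "exponential")

    def __post_init__(self):
        if self.family not in self._FAMILIES:
            raise ValueError(f"LOS family must be one of {self._FAMILIES}, got {self.family!r}")
        if any(v <= 0 for v in self.params.values()):
            raise ValueError("LOS parameters must be positive")

    def mean_days(self) -> float:
        p = self.params
        if self.family == "lognormal":
            return p["median_days"] * float(np.exp(p["sigma"] ** 2 / 2))
        if self.family == "gamma":
            return p["shape"] * p["scale_days"]
        return p["mean_days"]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "lognormal":
            draws = rng.lognormal(mean=np.log(p["median_days"]), sigma=p["sigma"], size=n)
        elif self.family == "gamma":
            draws = rng.gamma(shape=p["shape"], scale=p["scale_days"], size=n)
        else:
            draws = rng.exponential(scale=p["mean_days"], size=n)
        # a stay must outlast at least a couple of minutes to be an interval
        return np.maximum(draws, 2.0 / 1440.0)


@dataclass(frozen=True)
class ShiftSpec:
    """One shift of the roster template.

    ``end`` at or before ``start`` means the shift crosses midnight (the
    night shift).  ``break_window`` is a clock window inside which each
    nurse takes one break of ``break_minutes``, splitting the shift into
    two working segments.
    """

    label: str
    start: dt.time
    end: dt.time
    weekday_staff: dict[int, int] = field(default_factory=dict)
    weekend_staff: dict[int, int] = field(default_factory=dict)
    break_window: tuple[dt.time, dt.time] | None = None
    break_minutes: int = 0

    def __post_init__(self):
        for staff in (self.weekday_staff, self.weekend_staff):
            for g, k in staff.items():
                if g not in NURSE_GROUPS or g in DAILY_GROUPS:
                    raise ValueError(f"shift staffing refers to non-hourly group {g}")
                if k < 0:
                    raise ValueError(f"staffing level negative for group {g}: {k}")
        if self.break_minutes < 0:
            raise ValueError("break_minutes must be nonnegative")


def default_shift_template() -> tuple[ShiftSpec, ...]:
    """Three-shift template (night/morning/evening) with a thinner weekend
    roster; levels echo the typical acute-ward pattern of a morning
    maximum and a small night crew."""
    return (
        ShiftSpec(
            "night", dt.time(23, 0), dt.time(7, 15),
            weekday_staff={1: 2}, weekend_staff={1: 2},
            break_window=(dt.time(2, 30), dt.time(5, 0)), break_minutes=30,
        ),
        ShiftSpec(
            "morning", dt.time(7, 0), dt.time(15, 45),
            weekday_staff={1: 4, 2: 1, 3: 1}, weekend_staff={1: 3, 2: 1},
            break_window=(dt.time(11, 30), dt.time(13, 30)), break_minutes=30,
        ),
        ShiftSpec(
            "evening", dt.time(15, 0), dt.time(23, 15),
            weekday_staff={1: 3, 2: 1, 3: 1}, weekend_staff={1: 2},
            break_window=(dt.time(18, 0), dt.time(20, 0)), break_minutes=30,
        ),
    )


@dataclass(frozen=True)
class DefectRates:
    """Data-quality defects the linkage stage must survive."""

    missing_working_hours: float = 0.0  # fraction of hourly-group nurses with no hours rows
    outpatient: float = 0.0             # fraction of cases flagged outpatient
    newborn: float = 0.0                # fraction of maternity cases that are healthy newborns

    def __post_init__(self):
        for name in ("missing_working_hours", "outpatient", "newborn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"defect rate {name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; see the module docstring."""

    departments: dict[str, tuple[str, ...]]  # department -> unit ids
    start_date: dt.date
    end_date: dt.date
    admission_rate: AdmissionRate
    los_dist: dict[str, LosDistribution] = field(
        default_factory=lambda: {"*": LosDistribution()}
    )
    age_dist: dict[str, tuple[float, float]] = field(  # (mean, sd) truncated to [0, 110]
        default_factory=lambda: {"*": (58.0, 18.0)}
    )
    transfer_prob: float = 0.04  # transfers per patient-day
    transfer_weights: dict[str, float] | None = None
    shift_template: tuple[ShiftSpec, ...] = field(default_factory=default_shift_template)
    group_mix: tuple[float, float, float, float, float] = (0.72, 0.10, 0.12, 0.04, 0.02)
    daily_presence_rate: dict[int, float] = field(  # Poisson mean per unit-day, groups 4/5
        default_factory=lambda: {4: 0.25, 5: 0.08}
    )
    activity_mix: dict[str, float] = field(  # per nurse-day probability of a non-care row
        default_factory=lambda: {
            "administrative": 0.5,
            "teaching": 0.08,
            "continuous_education": 0.05,
            "absence": 0.03,
        }
    )
    activity_outpatient_frac: float = 0.0  # fraction of care rows on outpatient services
    defect_rates: DefectRates = field(default_factory=DefectRates)
    icd10_chapter_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"*": {"IX": 0.3, "II": 0.25, "XI": 0.2, "X": 0.15, "XIX": 0.1}}
    )
    maternity_department: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.end_date < self.start_date:
            raise ValueError("horizon empty: end_date precedes start_date")
        if not self.departments or not any(self.departments.values()):
            raise ValueError("at least one department with one unit is required")
        units = [u for us in self.departments.values() for u in us]
        if len(set(units)) != len(units):
            raise ValueError("unit ids must be unique across departments")
        if self.transfer_prob < 0:
            raise ValueError("transfer_prob must be nonnegative")
        if abs(sum(self.group_mix) - 1.0) > 1e-9:
            raise ValueError("group_mix must sum to 1")
        if any(m < 0 for m in self.group_mix):
            raise ValueError("group_mix proportions must be nonnegative")
        for t, p in self.activity_mix.items():
            if t not in ACTIVITY_TYPES or t == "care":
                raise ValueError(f"activity_mix key must be a non-care activity type, got {t!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"activity_mix[{t!r}] must be a probability")
        if not 0 <= self.activity_outpatient_frac <= 1:
            raise ValueError("activity_outpatient_frac must be in [0, 1]")
        for g, lam in self.daily_presence_rate.items():
            if g not in DAILY_GROUPS:
                raise ValueError(f"daily_presence_rate keys must be in {DAILY_GROUPS}")
            if lam < 0:
                raise ValueError("daily presence rate must be nonnegative")
        if self.maternity_department is not None and self.maternity_department not in self.departments:
            raise ValueError(f"maternity_department {self.maternity_department!r} not a department")
        if self.defect_rates.newborn > 0 and self.maternity_department is None:
            raise ValueError("newborn defect rate requires a maternity_department")

    # -- derived views -------------------------------------------------
    @property
    def units(self) -> list[str]:
        return [u for us in self.departments.values() for u in us]

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_department(self) -> dict[str, str]:
        return {u: d for d, us in self.departments.items() for u in us}

    @property
    def dates(self):
        import pandas as pd

        return pd.date_range(self.start_date, self.end_date, freq="D")

    def _per_department(self, mapping: dict, department: str):
        if department in mapping:
            return mapping[department]
        if "*" in mapping:
            return mapping["*"]
        raise KeyError(f"no entry (and no '*' default) for department {department!r}")

    def los_for(self, department: str) -> LosDistribution:
        return self._per_department(self.los_dist, department)

    def age_for(self, department: str) -> tuple[float, float]:
        return self._per_department(self.age_dist, department)

    def chapter_weights_for(self, department: str) -> dict[str, float]:
        return self._per_department(self.icd10_chapter_weights, department)

    def with_(self, **changes) -> "SimConfig":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# Ready-made configurations
# ---------------------------------------------------------------------------

#: The ten departments of a large university hospital with the unit counts
#: of the reference setting (70 inpatient units overall).
FULL_DEPARTMENTS = {
    "Cardiology & Cardiovascular Surgery": 12,
    "Neurology, Neurosurgery, Otolaryngology, Head & Neck Surgery, & Ophthalmology": 10,
    "Intensive Care": 8,
    "Pediatrics": 10,
    "Dermatology, Urology, Rheumatology, & Nephrology": 7,
    "Visceral Surgery and Medicine, Gastroenterology, Thoracic Surgery, & Pulmonology": 5,
    "Internal Medicine": 6,
    "Maternity & Gynecology": 3,
    "Orthopedics & Plastic Surgery": 5,
    "Hematology & Oncology": 4,
}


def _unit_layout(departments: dict[str, int]) -> dict[str, tuple[str, ...]]:
    out, i = {}, 0
    for dept, n in departments.items():
        out[dept] = tuple(f"U{i + k + 1:02d}" for k in range(n))
        i += n
    return out


def default_config(seed: int = 0) -> SimConfig:
    """Hospital-scale configuration: 10 departments, 70 units, the full
    three-year horizon 2015-01-01..2017-12-31.  Expensive to simulate;
    use :func:`demo_config` for interactive work and tests."""
    return SimConfig(
        departments=_unit_layout(FULL_DEPARTMENTS),
        start_date=dt.date(2015, 1, 1),
        end_date=dt.date(2017, 12, 31),
        admission_rate=AdmissionRate.default(base=0.14),
        age_dist={
            "*": (58.0, 18.0),
            "Pediatrics": (3.8, 5.0),
            "Maternity & Gynecology": (36.5, 15.4),
        },
        icd10_chapter_weights={
            "*": {"IX": 0.25, "II": 0.2, "XI": 0.2, "X": 0.15, "XIX": 0.2},
            "Cardiology & Cardiovascular Surgery": {"IX": 0.86, "XIX": 0.05, "II": 0.09},
            "Hematology & Oncology": {"II": 0.83, "IV": 0.05, "I": 0.12},
            "Maternity & Gynecology": {"XV": 0.6, "II": 0.17, "XIV": 0.23},
            "Pediatrics": {"XVI": 0.2, "X": 0.18, "I": 0.3, "XIX": 0.32},
        },
        maternity_department="Maternity & Gynecology",
        defect_rates=DefectRates(missing_working_hours=0.02, outpatient=0.13, newborn=0.25),
        seed=seed,
    )


def demo_config(seed: int = 0, n_weeks: int = 4) -> SimConfig:
    """Small three-unit, two-department configuration for examples and
    fast tests; same statistical structure as :func:`default_config`."""
    return SimConfig(
        departments={
            "Internal Medicine": ("U01", "U02"),
            "Maternity & Gynecology": ("U03",),
        },
        start_date=dt.date(2015, 1, 1),
        end_date=dt.date(2015, 1, 1) + dt.timedelta(days=7 * n_weeks - 1),
        admission_rate=AdmissionRate.default(base=0.14),
        age_dist={"*": (62.0, 17.0), "Maternity & Gynecology": (36.5, 15.4)},
        icd10_chapter_weights={
            "*": {"IX": 0.3, "II": 0.2, "XI": 0.25, "X": 0.25},
            "Maternity & Gynecology": {"XV": 0.6, "II": 0.2, "XIV": 0.2},
        },
        maternity_department="Maternity & Gynecology",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML loading (CLI)
# ---------------------------------------------------------------------------

def config_from_dict(raw: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a plain (YAML-shaped) mapping.

    Unspecified sections fall back to the defaults of :class:`SimConfig`.
    ``departments`` may map names either to unit-id lists or to unit
    counts (units are then auto-named U01, U02, ...).
    """
    kw: dict = {}
    deps = raw.get("departments")
    if deps is None:
        raise ValueError("config requires a 'departments' mapping")
    if all(isinstance(v, int) for v in deps.values()):
        kw["departments"] = _unit_layout(deps)
    else:
        kw["departments"] = {d: tuple(us) for d, us in deps.items()}
    kw["start_date"] = _parse_date(raw["start_date"])
    kw["end_date"] = _parse_date(raw["end_date"])
    adm = raw.get("admission_rate", {})
    if isinstance(adm, (int, float)):
        kw["admission_rate"] = AdmissionRate.constant(float(adm))
    else:
        base = float(adm.get("base", 0.14))
        if "hour_of_day" in adm or "day_of_week" in adm:
            kw["admission_rate"] = AdmissionRate(
                base=base,
                hour_of_day=tuple(adm.get("hour_of_day", (1.0,) * 24)),
                day_of_week=tuple(adm.get("day_of_week", (1.0,) * 7)),
                unit_weights=adm.get("unit_weights"),
            )
        else:
            kw["admission_rate"] = AdmissionRate.default(base=base)
    if "los_dist" in raw:
        kw["los_dist"] = {
            d: LosDistribution(family=s.get("family", "lognormal"), params=dict(s.get("params", {})))
            for d, s in raw["los_dist"].items()
        }
    if "age_dist" in raw:
        kw["age_dist"] = {d: (float(m), float(s)) for d, (m, s) in raw["age_dist"].items()}
    for key in ("transfer_prob", "activity_outpatient_frac", "seed", "maternity_department"):
        if key in raw:
            kw[key] = raw[key]
    if "shift_template" in raw:
        kw["shift_template"] = tuple(
            ShiftSpec(
                label=s["label"],
                start=_parse_time(s["start"]),
                end=_parse_time(s["end"]),
                weekday_staff={int(g): int(k) for g, k in s.get("weekday_staff", {}).items()},
                weekend_staff={int(g): int(k) for g, k in s.get("weekend_staff", {}).items()},
                break_window=(
                    (_parse_time(s["break_window"][0]), _parse_time(s["break_window"][1]))
                    if s.get("break_window")
                    else None
                ),
                break_minutes=int(s.get("break_minutes", 0)),
            )
            for s in raw["shift_template"]
        )
    if "group_mix" in raw:
        kw["group_mix"] = tuple(float(x) for x in raw["group_mix"])
    if "daily_presence_rate" in raw:
        kw["daily_presence_rate"] = {int(g): float(v) for g, v in raw["daily_presence_rate"].items()}
    if "activity_mix" in raw:
        kw["activity_mix"] = {t: float(p) for t, p in raw["activity_mix"].items()}
    if "defect_rates" in raw:
        kw["defect_rates"] = DefectRates(**raw["defect_rates"])
    if "icd10_chapter_weights" in raw:
        kw["icd10_chapter_weights"] = {
            d: {c: float(w) for c, w in ws.items()} for d, ws in raw["icd10_chapter_weights"].items()
        }
    return SimConfig(**kw)


def load_config(path) -> SimConfig:
    """Read a YAML configuration file into a :class:`SimConfig`."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
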