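# Methods

wardflow analyses the supply of and demand for nursing care on hospital
units at sub-shift resolution.  Two event-log sources drive everything:
nurse-staffing sheets (per-shift activity records, a nurse register,
working-hours segments, patient movement events) and medical discharge
records (demographics, admission/discharge dates, ICD-10-GM main
diagnosis).  The pipeline links the sources, expands them onto a
30-minute lattice, and derives four families of quantities: the patient
and nurse census, patient-to-nurse ratios with an extreme-mismatch
statistic, census-normalised patient turnover, and a department-level
descriptive overview.

## The slot lattice and counting conventions

All interval quantities live on the unit × calendar-day × slot lattice.
With the default 30-minute interval each day has 48 data points labelled
by clock time; any divisor of 1440 minutes is accepted (20-, 40- and
60-minute grids are used for sensitivity checks).  Days are naive
wall-clock days: every day has exactly 1440/interval slots and DST
transitions are treated as ordinary labelled slots, since source sheets
carry local clock times with no zone information.

Counting is **point-in-time at the slot start with half-open
membership**: an interval [start, end) contributes to slot *t* iff
`start <= t < end`.  Consequences worth spelling out:

* an instantaneous transfer (exit and entry share one timestamp) never
  double-counts a patient in two units at the same slot;
* a nurse whose break covers the slot instant is not counted;
* a stay of 55 minutes straddling one slot instant is counted once, a
  stay of 55 minutes between two instants is counted zero times — at
  30-minute resolution this sampling error is negligible against daily
  occupancy, which is why the lattice is this fine in the first place.
  An interval-average occupancy mode (`method="interval_mean"`) exists
  for sensitivity analyses but is not the default, because the analysis
  is defined on counts "at each data point".

ADT events (admission, discharge, transfer in/out) are assigned to the
slot whose half-open window [t, t + interval) contains their timestamp.
With event windows and point sampling so defined, the conservation
identity

    n(t + Δ) = n(t) + entries[t, t+Δ) − exits[t, t+Δ)

holds exactly **provided no event falls exactly on a slot boundary** (a
boundary entry is already inside n(t) yet would be re-counted in the
window).  The synthetic generator therefore draws every movement
timestamp with a seconds component in 1..59 — never exactly :00 of any
minute — so no event can sit on a slot boundary for any admissible
interval choice, and conservation is a theorem on synthetic data rather
than a numerical coincidence.  Real minute-resolution extracts would
need a stated tie rule here; the package's convention (membership at
entry instant, exclusion at exit instant) is the one all tests pin down.

## Linkage

The sheets join on six keys: case, nurse, contract, unit, date, time.
Stages, each recorded in a funnel with numerator, denominator and a
half-up percentage to one decimal:

1. **Activity subset.**  Full-row duplicates are dropped, then only
   rows on inpatient settings with direct/indirect-care activity are
   kept (administrative, teaching, continuous-education and absence
   rows describe the nurse's day, not patient demand).
2. **Nurse side.**  Distinct (nurse, contract, unit, date) care days
   join the nurse register and then the working-hours sheet on (nurse,
   contract, date).  Working-hours rows duplicated on (nurse, contract,
   date, start) are deduplicated and counted.  A nurse-day with care
   activity but no working-time rows is excluded *for that day only*
   and tallied as an excluded person-day.  Students (group 4) and
   external/agency nurses (group 5) carry no time breakdown in the
   source system, so they are routed to a daily-presence table instead
   of the segment census.  Midnight-crossing segments (end <= start)
   end on the next calendar day; a segment's sheet date is the date it
   starts.  Contract identifiers are dropped after the join.
3. **Patient side.**  Each case's movement events are ordered in time
   (ties broken admission < transfer < discharge) and folded by a state
   machine into per-unit stay intervals: admission or transfer-in
   opens, transfer-out or discharge closes, a transfer's exit and entry
   share one timestamp.  Sequences that cannot be paired (double
   admission, discharge before admission, missing discharge) are
   rejected with a reason, never silently dropped.  Case-level
   exclusions: outpatient cases (movement setting) and healthy newborns
   — identified by a boolean flag in the discharge sheet, restricted to
   the maternity department when one is named; real-world ICD/DRG-based
   newborn detection is out of scope.  A case is an admission episode,
   not a person: re-admissions are distinct cases.
4. **Deidentification.**  Stable pseudonyms Patient1…, Nurse1…, Unit1…
   assigned in sorted raw-id order; only department names survive.  The
   mapping is discarded unless `keep_map` is set (tests use it to
   compare against generator truth).

## Ratios and the extreme-mismatch statistic

The patient-to-nurse ratio at a data point is patients present divided
by nurses of one qualification group present, per unit.  Zero-nurse
points give a *missing* ratio rather than an infinity: they are left
out of medians and percentage denominators, and the count of such
points is reported alongside so the information is not lost.

Per stratum (unit × group over the full study period) the package
reports the median and IQR and two cut-offs derived from the median m:

    ELT = m − m/2 = m/2        EHT = m + m/2 = 1.5 m

together with the percentage of non-missing points strictly below ELT
(extreme overstaffing), strictly above EHT (extreme understaffing), and
the remainder.  The thresholds are deliberately arbitrary illustrations
of ±50% workload per nurse, not clinically validated cut-offs; the
algebra EHT = 3·ELT and the three-way percentage partition are tested
invariants.  Boundary handling (strict inequalities) is a package
convention — a point sitting exactly on a threshold is "normal".
Strata with median 0 (typically LPN/other groups at night) are reported
but flagged degenerate, since both thresholds collapse to zero.  All
quantiles use the linear-interpolation sample-quantile convention.

Key-timepoint tables report the median (IQR) at 02:00, 10:00 and 18:00
split by weekday/weekend (weekend = Saturday and Sunday) per department
and group.  Department mean profiles per slot-of-week average each
unit's own mean and attach a t-interval across units (single-unit
departments get a missing CI).  A normal-approximation interval would
be the large-sample equivalent; with a handful of units per department
the t quantile is the defensible small-sample choice and is what the
closed-form test checks.

## Turnover

Admissions, discharges, transfers-in and transfers-out are counted per
slot window and divided by the patients present at the slot instant —
the census *before* the window's events, consistent with point sampling
at the slot start.  Ratios at zero-census points are missing (counts
kept); ratios may exceed 1 (three admissions onto a two-patient unit)
and are not capped.  Department profiles average unit means per
(daytype, slot), and exits carry a negative sign for the leaving side
of bar charts.  One transfer contributes exactly one out-event and one
in-event hospital-wide, so total transfers-in equal transfers-out over
any closed span — a tested invariant.

## Descriptive overview

Per department: case volume and unit count; age mean (SD) and median
(IQR); length of stay, computed as discharge date minus admission date
in whole days (clock times ignored, same-day = 0); patients per day per
unit; and the two most common main diagnoses grouped at ICD-10 chapter
level with incidence n/N (%).  The chapter table is embedded as data
(A00–B99 infectious, C00–D48 tumors, I00–I99 circulatory, …);
ICD-10-GM agrees with the WHO ranges at this granularity, and
unmappable codes go to an "unknown" bucket.  Ties in the top-2 ranking
break by chapter code order.  "Patients per day per unit" collapses the
48 intraday points to the census at a daily reference slot, noon by
default and configurable — a reporting convention, since nothing in the
underlying definitions fixes how a day's 48 values become one.

## The synthetic generator

No real hospital extract ships with the package, so a discrete-event
generator emulates both sources with the statistical structure the
analysis assumes, plus the generating truth (stay intervals, shift
segments, daily presence) for oracle tests.

* **Admissions** follow a time-inhomogeneous Poisson process with
  hour-of-day × day-of-week intensity per unit.  The default profile
  peaks between 08:00 and 10:00, is quiet at night and drops at the
  weekend; the default base rate (0.14 admissions per unit-hour)
  together with the default length of stay gives a realistic acute-ward
  occupancy of roughly 10–15 patients per unit.
* **Length of stay** is lognormal by default (median 3 days,
  sigma 0.6 — right-skewed, as hospital LOS is); gamma and exponential
  are available, the latter making the constant-rate configuration an
  M/G/inf queue whose mean occupancy λ·E[LOS] the test suite recovers
  via batch-means (Little's law).
* **Transfers** occur at a configurable rate per patient-day (default
  0.04), relocating the patient instantaneously to a weighted random
  other unit and splitting the hospital stay into per-unit intervals.
* **Roster**: a three-shift template (night/morning/evening) with
  per-group weekday/weekend levels — morning largest, night smallest —
  and one break per shift inside a clock window, splitting each shift
  into two working segments.  Nurse pools are sized at twice the daily
  requirement so consecutive night shifts never force an overlapping
  assignment; groups 4–5 appear as daily presence draws (Poisson, small
  means) without clock times.
* **Ages** are truncated normal per department (default mean 58, SD 18,
  truncated to [0, 110]); diagnoses sample an ICD-10 chapter from
  per-department weights and then a concrete code within the chapter's
  range, so chapter grouping can be verified by round trip.
* **Defects**: a fraction of hourly-group nurses lose all working-hours
  rows, a fraction of cases is flagged outpatient (on their movement
  rows), and a fraction of maternity cases becomes healthy newborns
  (age 0, flagged in the discharge sheet).  Defaults in the small demo
  configuration are zero; the hospital-scale configuration uses 2%,
  13% and 25% respectively.

Everything is deterministic given the seed; identical configurations
produce byte-identical sheets.

What the generator does **not** emulate: clinical pathways and
acuity/severity (all patients are exchangeable within a department),
bed-capacity constraints, correlated absence waves, seasonal trends,
and the real source system's identifier formats.  Passing tests
therefore demonstrate that the *pipeline arithmetic* is right under the
assumed event structure — not that any particular hospital looks like
the synthetic one.

## Problem sizes and numerical choices

The test suite exercises a three-unit, two-department hospital over
four weeks (a few hundred cases, ~2,000 shift segments, ~4,000 lattice
points), chosen so the whole suite runs in seconds while every code
path (transfers, night shifts, weekend rosters, all defect classes) is
hit.  The stochastic checks use dedicated configurations: a one-unit
constant-rate year for Little's law (warm-up of ten mean stay lengths
discarded, 20 batch means, tolerance three standard errors) and a
four-month smooth-flow simulation for the grid-increment sensitivity
check (20/40/60-minute daily occupancy within 1% of the 30-minute
value).  Percentages reported by the funnel and the overview are exact
decimal computations rounded half-up to one decimal; internal
statistics stay at float precision.

## Known limitations

* The census is unweighted head counts; no acuity or severity
  adjustment.
* The extreme-mismatch cut-offs are illustrative; identifying
  clinically meaningful thresholds is out of scope.
* Newborn identification relies on an explicit flag column; coded
  (ICD/DRG) detection is not implemented.
* Probabilistic record linkage is out of scope — joins are exact on
  keys, as in the source systems emulated here.
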