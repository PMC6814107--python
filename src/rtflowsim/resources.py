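"""Machines, staff agendas and planner skills.

Machines (CT / MRI / PET-CT) are modeled as dated slot calendars built
lazily from weekly templates; bookings claim whole slots.  Doctors carry
weekly agendas of busy blocks whose complement within the shift is the
time available for contouring; treatment-planning RTTs carry a skill level
with downward compatibility (P4 covers P3 and P2, P3 covers P2) and a
concurrency limit (two simultaneous plans at P3/P4 level, one at P2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, ResourceConfig, SimConfig
from .des import MINUTES_PER_DAY, is_weekend

__all__ = [
    "Slot",
    "SlotCalendar",
    "find_earliest_slot",
    "CapacityError",
    "StaffAgenda",
    "doctor_free_intervals",
    "SkillMatrix",
    "eligible_planners",
    "Planner",
    "build_slot_calendars",
    "build_doctors",
    "build_planners",
]

SKILL_COVERS = {"P2": {"P2"}, "P3": {"P3", "P2"}, "P4": {"P4", "P3", "P2"}}


class CapacityError(RuntimeError):
    """No admissible slot within the booking horizon (misconfigured capacity)."""


@dataclass
class Slot:
    machine: str
    day: int
    start: int           # sim minutes
    duration: int
    label: str = "unrestricted"   # unrestricted | no_iv_contrast | acute_reserved
    booked_by: int | None = None

    @property
    def end(self) -> int:
        return self.start + self.duration


class SlotCalendar:
    """Dated appointment slots for one machine, built from a weekly template.

    ``template(day) -> list[Slot]`` materialises the slots for a workday;
    weekends and holidays yield none.  Days are generated on demand and
    cached so bookings persist.
    """

    def __init__(self, machine_id: str, kind: str, template, holidays: set):
        self.machine_id = machine_id
        self.kind = kind
        self._template = template
        self._holidays = holidays
        self._days: dict[int, list[Slot]] = {}

    def slots_on(self, day: int) -> list[Slot]:
        if day not in self._days:
            if is_weekend(day) or day in self._holidays:
                self._days[day] = []
            else:
                self._days[day] = self._template(day)
        return self._days[day]

    def book(self, slot: Slot, patient_id: int) -> None:
        if slot.booked_by is not None:
            raise CapacityError(
                f"double booking on {self.machine_id} day {slot.day}"
            )
        slot.booked_by = patient_id


def slot_admissible(slot: Slot, *, acute: bool, iv_contrast: bool) -> bool:
    """Slot-label admission rule.

    IV-contrast patients are excluded from the first morning slots (the
    supervising doctor may not have started their shift); slots reserved
    for acute patients admit only acute patients.
    """
    if slot.booked_by is not None:
        return False
    if slot.label == "no_iv_contrast" and iv_contrast:
        return False
    if slot.label == "acute_reserved" and not acute:
        return False
    return True


def find_earliest_slot(
    calendars,
    earliest_time: int,
    *,
    acute: bool = False,
    iv_contrast: bool = False,
    horizon_days: int = 120,
) -> Slot:
    """First-come-first-planned: chronologically first admissible free slot
    at/after ``earliest_time`` over one or more calendars of a machine kind.
    """
    if not isinstance(calendars, (list, tuple)):
        calendars = [calendars]
    day0 = earliest_time // MINUTES_PER_DAY
    for day in range(day0, day0 + horizon_days):
        best: Slot | None = None
        for cal in calendars:
            for slot in cal.slots_on(day):
                if slot.start < earliest_time:
                    continue
                if not slot_admissible(slot, acute=acute, iv_contrast=iv_contrast):
                    continue
                if best is None or slot.start < best.start:
                    best = slot
        if best is not None:
            return best
    raise CapacityError(
        f"no admissible {calendars[0].kind} slot within {horizon_days} days "
        f"of t={earliest_time}"
    )


def build_slot_calendars(res: ResourceConfig, holidays: set) -> dict:
    """Materialise the department's machine calendars from the config."""

    def ct_template(scanner_index):
        def make(day):
            slots = []
            for k in range(res.ct_slots_per_scanner):
                start = day * MINUTES_PER_DAY + res.ct_day_start + k * res.ct_slot_minutes
                label = "unrestricted"
                if res.iv_excluded_morning_slots and k < res.iv_excluded_morning_slots:
                    if res.iv_restriction_per_scanner or scanner_index == 0:
                        label = "no_iv_contrast"
                # the daily acute-reserved slot lives on the first scanner,
                # last slot of the day; unused it expires unreleased
                if (
                    res.acute_reserved_slots_per_day
                    and scanner_index == 0
                    and k >= res.ct_slots_per_scanner - res.acute_reserved_slots_per_day
                ):
                    label = "acute_reserved"
                slots.append(Slot(f"CT{scanner_index + 1}", day, start,
                                  res.ct_slot_minutes, label))
            return slots
        return make

    def weekly_template(machine, counts, start_minute, dur):
        def make(day):
            n = counts[day % 7] if day % 7 < 5 else 0
            return [
                Slot(machine, day, day * MINUTES_PER_DAY + start_minute + k * dur, dur)
                for k in range(n)
            ]
        return make

    cts = [
        SlotCalendar(f"CT{i + 1}", "CT", ct_template(i), holidays)
        for i in range(res.ct_scanners)
    ]
    mri = SlotCalendar(
        "MRI1", "MRI",
        weekly_template("MRI1", res.mri_slots_per_weekday, res.mri_day_start,
                        res.mri_slot_minutes),
        holidays,
    )
    petct = SlotCalendar(
        "PETCT1", "PETCT",
        weekly_template("PETCT1", res.petct_slots_per_weekday, res.petct_day_start,
                        res.petct_slot_minutes),
        holidays,
    )
    return {"CT": cts, "MRI": [mri], "PETCT": [petct]}


# ---------------------------------------------------------------------------
# staff
# ---------------------------------------------------------------------------


@dataclass
class StaffAgenda:
    """One staff member's availability.

    ``weekly_free`` lists, per weekday 0..4, the intervals (start, end) in
    minutes-of-day during which the person is free for the modeled task
    (contouring for doctors); the complement within the shift is occupied
    by consultations, meetings and admin.  Absence days (holidays, leave,
    conferences) remove the whole day.
    """

    person_id: int
    role: str                       # "doctor" | "planning_rtt"
    team: str = ""                  # doctors: specialty team
    skill: str = ""                 # planners: P2/P3/P4
    shift: tuple = (8 * 60, 17 * 60)
    weekly_free: list = field(default_factory=list)   # [[(s,e),...] x 5]
    absence_days: set = field(default_factory=set)

    def validate(self):
        for wd, ivs in enumerate(self.weekly_free):
            prev_end = None
            for s, e in ivs:
                if not self.shift[0] <= s < e <= self.shift[1]:
                    raise ConfigError(
                        f"agenda {self.person_id}: interval outside shift on wd {wd}"
                    )
                if prev_end is not None and s < prev_end:
                    raise ConfigError(
                        f"agenda {self.person_id}: overlapping intervals on wd {wd}"
                    )
                prev_end = e


def doctor_free_intervals(agenda: StaffAgenda, day: int, holidays: set = frozenset()) -> list:
    """Free (start, end) sim-minute intervals of a doctor on ``day``.

    Empty on weekends, department holidays and personal absence days.
    """
    if is_weekend(day) or day in holidays or day in agenda.absence_days:
        return []
    base = day * MINUTES_PER_DAY
    return [(base + s, base + e) for s, e in agenda.weekly_free[day % 7]]


def _staff_horizon_days(config: SimConfig) -> int:
    exp = config.experiment
    return exp.warmup_days + exp.horizon_days + exp.drain_days + \
        config.resources.booking_horizon_days


def draw_absence_days(
    horizon_days: int,
    rng: np.random.Generator,
    incidental_rate: float,
    vacation_weeks_per_year: float,
) -> set:
    """Week-long vacation blocks plus incidental Bernoulli absence days.

    Clustered leave is what produces the multi-day capacity dips of real
    agendas; i.i.d. daily absences would wash them out.
    """
    absent: set[int] = set()
    n_weeks = horizon_days // 7
    n_vac = int(round(vacation_weeks_per_year * horizon_days / 365.0))
    if n_vac > 0 and n_weeks > 0:
        weeks = rng.choice(n_weeks, size=min(n_vac, n_weeks), replace=False)
        for w in weeks:
            absent.update(int(w) * 7 + d for d in range(5))
    if incidental_rate > 0:
        draws = rng.random(horizon_days)
        absent.update(
            d for d in range(horizon_days) if d % 7 < 5 and draws[d] < incidental_rate
        )
    return absent


def team_contour_hours(config: SimConfig, team: str) -> list[float]:
    """Weekday contouring hours for one team's doctors.

    In ``consult_coupled`` mode a team's availability varies inversely
    with its consultation load per weekday (the same doctors hold the
    clinics), keeping the weekly total at the configured hours; spreading
    consultations over the week therefore also evens out contouring
    capacity.  In ``pattern`` mode the explicit weekday pattern is used.
    """
    from .config import SITE_TO_TEAMS

    res = config.resources
    total = res.doctor_weekly_contour_hours
    if res.doctor_availability_mode == "pattern":
        return list(res.doctor_free_hours_pattern)
    rates = config.arrivals.rates()
    load = np.zeros(5)
    for site, teams in SITE_TO_TEAMS.items():
        if team in teams:
            load += np.asarray(rates[site]) / len(teams)
    if load.sum() <= 0:
        return [total / 5.0] * 5
    rel = load / load.mean()
    weights = np.maximum(res.availability_coupling_floor, 2.0 - rel)
    hours = total * weights / weights.sum()
    return [float(h) for h in hours]


def build_doctors(config: SimConfig, rng: np.random.Generator) -> list[StaffAgenda]:
    """Synthetic doctor agendas.

    Doctors in a team share the team's weekday contouring-availability
    profile (a free block at the end of the shift); absences are
    week-long vacation blocks plus incidental days.
    """
    res = config.resources
    shift = res.doctor_shift
    doctors: list[StaffAgenda] = []
    pid = 0
    horizon = _staff_horizon_days(config)
    for team, count in res.doctor_teams.items():
        pattern = team_contour_hours(config, team)
        weekly = []
        for wd in range(5):
            mins = int(round(pattern[wd] * 60))
            start = max(shift[0], shift[1] - mins)
            weekly.append([(start, shift[1])] if mins > 0 else [])
        for _ in range(count):
            absences = draw_absence_days(
                horizon, rng, res.absence_rate, res.vacation_weeks_per_year
            )
            doctors.append(
                StaffAgenda(person_id=pid, role="doctor", team=team, shift=shift,
                            weekly_free=[list(iv) for iv in weekly],
                            absence_days=absences)
            )
            pid += 1
    return doctors


# ---------------------------------------------------------------------------
# planners
# ---------------------------------------------------------------------------


class SkillMatrix:
    """Downward-compatible planner skills with concurrency limits."""

    def __init__(self, concurrency: dict | None = None,
                 p3_extra_sites: set | None = None):
        self.concurrency = dict(concurrency or {"P2": 1, "P3": 2, "P4": 2})
        # scenario S4: sites whose plans P3-level planners may also serve
        self.p3_extra_sites = set(p3_extra_sites or ())

    def covers(self, skill: str, plan_type: str, site: str = "") -> bool:
        if plan_type in SKILL_COVERS[skill]:
            return True
        if (plan_type == "P4" and skill == "P3" and site in self.p3_extra_sites):
            return True
        return False

    def capacity(self, skill: str) -> int:
        return self.concurrency[skill]


@dataclass
class Planner:
    """A treatment-planning RTT with a skill level and live task count."""

    person_id: int
    skill: str
    shift: tuple = (8 * 60, 16 * 60 + 30)
    absence_days: set = field(default_factory=set)
    active_tasks: int = 0

    def on_shift(self, t: int, holidays: set = frozenset()) -> bool:
        day, mod = divmod(t, MINUTES_PER_DAY)
        if is_weekend(day) or day in holidays or day in self.absence_days:
            return False
        return self.shift[0] <= mod < self.shift[1]


def eligible_planners(
    plan_type: str,
    planners: list[Planner],
    skill_matrix: SkillMatrix,
    t: int,
    *,
    site: str = "",
    holidays: set = frozenset(),
) -> list[Planner]:
    """Planners able to take a ``plan_type`` task now: skill covers the
    plan (downward-compatible), on shift, with a free concurrency token."""
    out = []
    for p in planners:
        if not skill_matrix.covers(p.skill, plan_type, site):
            continue
        if not p.on_shift(t, holidays):
            continue
        if p.active_tasks >= skill_matrix.capacity(p.skill):
            continue
        out.append(p)
    return out


def agendas_to_dataframe(staff) -> "pandas.DataFrame":  # noqa: F821
    """Flatten staff agendas to one row per person/weekday for inspection
    (write with ``df.to_csv(...)``)."""
    import pandas as pd

    rows = []
    for person in staff:
        weekly = getattr(person, "weekly_free", None)
        for wd in range(5):
            ivs = weekly[wd] if weekly else []
            rows.append({
                "person_id": person.person_id,
                "role": getattr(person, "role", "planning_rtt"),
                "team": getattr(person, "team", ""),
                "skill": getattr(person, "skill", ""),
                "weekday": wd,
                "free_intervals": ";".join(f"{s}-{e}" for s, e in ivs),
                "free_minutes": sum(e - s for s, e in ivs),
                "n_absence_days": len(person.absence_days),
            })
    return pd.DataFrame(rows)


def build_planners(config: SimConfig, rng: np.random.Generator) -> list[Planner]:
    res = config.resources
    horizon = _staff_horizon_days(config)
    planners = []
    pid = 0
    for skill in ("P2", "P3", "P4"):
        for _ in range(res.planners.get(skill, 0)):
            absences = draw_absence_days(
                horizon, rng, res.absence_rate, res.vacation_weeks_per_year
            )
            planners.append(Planner(person_id=pid, skill=skill,
                                    shift=res.planner_shift, absence_days=absences))
            pid += 1
    return planners
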