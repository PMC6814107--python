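"""Pull/push booking logic and first-fraction timing.

Two scheduling moments exist in the workflow.  At consultation (Moment 1)
every patient is booked their imaging appointments; *pull* patients are
additionally given a first-fraction date drawn from an empirical
time-to-treatment table.  *Push* patients get their date only when
treatment planning starts (Moment 2), as a 1-7 day gap.  Pull patients
whose pre-treatment is not finished in time have their start postponed
(rebooked) at a daily checkpoint.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigError, SimConfig, CarePlanSpec
from .des import MINUTES_PER_DAY, is_weekend
from .casemix import Patient
from .resources import find_earliest_slot, Slot

__all__ = [
    "ttt_distribution",
    "draw_ttt",
    "pull_policy",
    "schedule_start_pull",
    "schedule_start_push",
    "book_imaging",
    "next_admissible_day",
    "check_and_rebook",
    "due_day",
]


def next_admissible_day(day: int, start_weekday: int | None, holidays: set) -> int:
    """First day strictly after ``day`` on which treatment may start."""
    d = day + 1
    while True:
        ok = not is_weekend(d) and d not in holidays
        if ok and (start_weekday is None or d % 7 == start_weekday):
            return d
        d += 1


def ttt_distribution(
    config: SimConfig,
    urgency: str,
    weekday: int,
    start_weekday: int | None = None,
    arrival_weekday: int | None = None,
) -> dict:
    """Time-to-treatment mass function for a pull patient.

    Looks up the (urgency, request-weekday) table and, if the care plan
    constrains the start weekday (e.g. head-and-neck starts on Mondays),
    conditions the distribution on offsets landing on that weekday.
    """
    try:
        dist = config.policies.ttt_pull[urgency][weekday]
    except KeyError:
        raise ConfigError(f"no TTT table for urgency={urgency!r} weekday={weekday}")
    if start_weekday is not None:
        awd = weekday if arrival_weekday is None else arrival_weekday
        dist = {d: m for d, m in dist.items() if (awd + d) % 7 == start_weekday}
        if not dist:
            raise ConfigError(
                f"TTT table for {urgency!r}/wd{weekday} has no mass on "
                f"start weekday {start_weekday}"
            )
        total = sum(dist.values())
        dist = {d: m / total for d, m in dist.items()}
    return dist


def draw_ttt(dist: dict, rng: np.random.Generator) -> int:
    days = sorted(dist)
    p = np.array([dist[d] for d in days], dtype=float)
    return int(days[rng.choice(len(days), p=p / p.sum())])


def pull_policy(patient: Patient, config: SimConfig) -> str:
    """Baseline workflow-control rule, plus promoted tumor sites.

    Pull: acute, subacute, and regular patients on a combined-modality
    trajectory; plus every patient of a promoted tumor site.  Everyone
    else is push.
    """
    promoted = set(config.policies.pull_promoted_sites)
    for s in promoted:
        if s not in config.site_probs():
            raise ConfigError(f"unknown promoted site {s!r}")
    if patient.urgency in ("acute", "subacute"):
        return "pull"
    if patient.combined_modality:
        return "pull"
    if patient.tumor_site in promoted:
        return "pull"
    return "push"


def schedule_start_pull(
    patient: Patient,
    plan: CarePlanSpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> int:
    """Moment 1: draw the first-fraction day for a pull patient.

    start = arrival day + planned delay + TTT draw; the draw honours the
    plan's start-weekday constraint.  Bone metastasis shares the subacute
    time-to-treatment support (1-8 days).
    """
    if patient.strategy != "pull":
        raise ConfigError("schedule_start_pull called for a push patient")
    arrival_day = patient.arrival_day()
    base_day = arrival_day + 7 * patient.planned_delay_weeks
    urgency = patient.urgency
    if patient.tumor_site == "bone_metastasis" and urgency == "regular":
        urgency = "subacute"  # bone metastasis follows the 1-8 day support
    wd = base_day % 7
    if wd >= 5:  # delay landing on a weekend: use next Monday's table
        base_day += 7 - wd
        wd = 0
    # start-weekday constraints bind regular trajectories only; urgent
    # patients start as soon as the drawn time-to-treatment allows
    constraint = plan.start_weekday if patient.urgency == "regular" else None
    dist = ttt_distribution(config, urgency, wd, constraint, arrival_weekday=wd)
    start = base_day + draw_ttt(dist, rng)
    holidays = config.holiday_days()
    while is_weekend(start) or start in holidays:
        start = next_admissible_day(start, constraint, holidays)
    patient.scheduled_start_day = start
    return start


def schedule_start_push(
    patient: Patient,
    plan: CarePlanSpec,
    config: SimConfig,
    rng: np.random.Generator,
    planning_start_time: int,
) -> int:
    """Moment 2: draw the first-fraction day for a push patient.

    start = planning-start day + a 1-7 day gap from the push table; the
    date respects the plan's start-weekday constraint and is adjusted
    forward (not counted as a rebook) if planning completes later.
    """
    if patient.strategy != "push":
        raise ConfigError("schedule_start_push called for a pull patient")
    day = planning_start_time // MINUTES_PER_DAY
    wd = day % 7
    dist = config.policies.ttt_push.get(min(wd, 4))
    if not dist:
        raise ConfigError(f"no push gap table for weekday {wd}")
    if plan.start_weekday is not None:
        cdist = {d: m for d, m in dist.items() if (wd + d) % 7 == plan.start_weekday}
        if cdist:
            tot = sum(cdist.values())
            dist = {d: m / tot for d, m in cdist.items()}
    start = day + draw_ttt(dist, rng)
    holidays = config.holiday_days()
    while is_weekend(start) or start in holidays:
        start = next_admissible_day(start, plan.start_weekday, holidays)
    patient.scheduled_start_day = start
    return start


def book_imaging(
    patient: Patient,
    calendars: dict,
    config: SimConfig,
    now: int,
) -> dict[str, Slot]:
    """Moment 1: book CT (always) and MRI/PET-CT (if flagged), in pathway
    order — each subsequent scan at/after the previous scan's end.

    The CT earliest date is the arrival day plus the planned delay; the
    IV-contrast and acute-reservation slot labels restrict admission.
    """
    horizon = config.resources.booking_horizon_days
    delay_min = patient.planned_delay_weeks * 7 * MINUTES_PER_DAY
    earliest = max(now, patient.arrival_day() * MINUTES_PER_DAY + delay_min)
    appts: dict[str, Slot] = {}
    ct = find_earliest_slot(
        calendars["CT"], earliest,
        acute=patient.urgency == "acute",
        iv_contrast=patient.needs_iv_contrast,
        horizon_days=horizon,
    )
    for cal in calendars["CT"]:
        if cal.machine_id == ct.machine:
            cal.book(ct, patient.id)
    appts["CT"] = ct
    prev_end = ct.end
    for kind, flag in (("MRI", patient.needs_mri), ("PETCT", patient.needs_petct)):
        if not flag:
            continue
        slot = find_earliest_slot(calendars[kind], prev_end, horizon_days=horizon)
        calendars[kind][0].book(slot, patient.id)
        appts[kind] = slot
        prev_end = slot.end
    return appts


def due_day(patient: Patient, config: SimConfig) -> int:
    """EDD key: scheduled start for pull patients; arrival + national
    waiting-time target for (not yet scheduled) push patients."""
    if patient.strategy == "pull" and patient.scheduled_start_day is not None:
        return patient.scheduled_start_day
    if patient.strategy == "push" and patient.scheduled_start_day is not None:
        return patient.scheduled_start_day
    target = config.policies.targets_days[patient.urgency]
    return patient.arrival_day() + target


def check_and_rebook(
    patient: Patient,
    plan: CarePlanSpec,
    config: SimConfig,
    now: int,
    rng: np.random.Generator | None = None,
) -> int | None:
    """Daily rebook checkpoint for a pull patient.

    If the treatment plan is not finished by the checkpoint, the start is
    postponed and one rebook is recorded: under the default
    ``next_admissible`` rule to the next admissible day (honouring the
    start-weekday constraint); under ``redraw`` to a day re-drawn from
    the tail of the patient's time-to-treatment table beyond the missed
    date (falling back to the next admissible day when the tail is empty
    or no rng is supplied).  Returns the new start day, or None if no
    rebook was needed.
    """
    if patient.strategy != "pull" or patient.scheduled_start_day is None:
        return None
    if patient.plan_done_time is not None and patient.plan_done_time <= now:
        return None
    old = patient.scheduled_start_day
    constraint = plan.start_weekday if patient.urgency == "regular" else None
    holidays = config.holiday_days()
    new = None
    if config.policies.rebook_rule == "redraw" and rng is not None:
        urgency = patient.urgency
        if patient.tumor_site == "bone_metastasis" and urgency == "regular":
            urgency = "subacute"
        base = patient.arrival_day() + 7 * patient.planned_delay_weeks
        dist = config.policies.ttt_pull.get(urgency, {}).get(base % 7) or \
            config.policies.ttt_pull.get(urgency, {}).get(0, {})
        tail = {d: m for d, m in dist.items() if base + d > old}
        if tail:
            total = sum(tail.values())
            new = base + draw_ttt({d: m / total for d, m in tail.items()}, rng)
            while is_weekend(new) or new in holidays:
                new = next_admissible_day(new, constraint, holidays)
    if new is None:
        new = next_admissible_day(old, constraint, holidays)
    patient.scheduled_start_day = new
    patient.rebook_count += 1
    patient.rebook_history.append((old, new, now))
    return new
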