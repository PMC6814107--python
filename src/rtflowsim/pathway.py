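"""Execution of the pre-treatment pathway on the simulated department.

:class:`Simulation` wires the event engine, case-mix generator, resource
model and booking policies into one replication of the department:

* a daily generator draws per-site Poisson arrivals and spreads the
  consultation instants over the working day;
* at consultation the patient's care content is assigned, imaging is
  booked (Moment 1) and pull patients draw their first-fraction date;
* scans occupy their booked slots; image post-processing adds lognormal
  lags; contouring (with peer review appended) runs on the assigned
  specialty doctor — any doctor for palliative patients — and treatment
  planning on skill-eligible planning RTTs, both dispatched earliest due
  date first;
* pull patients are checked the evening before and at their start
  instant, and rebooked if the plan is not ready; push patients get their
  date at planning start (Moment 2).

Contouring is non-preemptive and needs one contiguous free agenda
interval; treatment planning is software-driven and resumes across day
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import policies
from .casemix import Patient, assign_care_content, sample_daily_arrivals
from .config import SITE_TO_TEAMS, SimConfig
from .des import (
    Engine,
    EventLog,
    MINUTES_PER_DAY,
    PRIORITY_RELEASE,
    PRIORITY_REQUEST,
    RngStreams,
    is_weekend,
)
from .ipp import sample_ipp_delay_minutes
from .resources import (
    SkillMatrix,
    build_doctors,
    build_planners,
    build_slot_calendars,
    doctor_free_intervals,
    eligible_planners,
)

__all__ = ["Simulation", "SimResult"]

_SKILL_RANK = {"P2": 0, "P3": 1, "P4": 2}


@dataclass
class SimResult:
    """Raw output of one replication: the patient records and event log."""

    config: SimConfig
    replication: int
    patients: list = field(default_factory=list)
    log: EventLog | None = None
    events_processed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "id": p.id,
                    "arrival_day": p.arrival_day(),
                    "arrival_time": p.arrival_time,
                    "tumor_site": p.tumor_site,
                    "care_plan": p.care_plan,
                    "urgency": p.urgency,
                    "strategy": p.strategy,
                    "planning_type": p.planning_type,
                    "planned_delay_weeks": p.planned_delay_weeks,
                    "scheduled_start_day": p.scheduled_start_day,
                    "actual_start_day": p.actual_start_day,
                    "rebook_count": p.rebook_count,
                    "ct_time": p.ct_time,
                    "last_scan_time": p.last_scan_time,
                    "ipp_done_time": p.ipp_done_time,
                    "contour_done_time": p.contour_done_time,
                    "plan_done_time": p.plan_done_time,
                }
            )
        return pd.DataFrame(rows)


class Simulation:
    """One replication of the department model."""

    def __init__(
        self,
        config: SimConfig,
        replication: int = 0,
        base_seed: int | None = None,
        trace: bool = False,
    ):
        self.config = config
        self.replication = replication
        seed = config.experiment.base_seed if base_seed is None else base_seed
        self.rng = RngStreams(seed, replication)
        self.engine = Engine()
        self.holidays = config.holiday_days()
        self.log = EventLog(origin=config.origin(), enabled=trace)
        self.calendars = build_slot_calendars(config.resources, self.holidays)
        self.doctors = build_doctors(config, self.rng.agenda)
        self.planners = build_planners(config, self.rng.agenda)
        self.skill_matrix = SkillMatrix(
            config.resources.planner_concurrency,
            set(config.resources.p3_extra_sites),
        )
        self.patients: list[Patient] = []
        self._contour_queue: list[Patient] = []
        self._planning_queue: list[Patient] = []
        # live free intervals per (doctor_id, day), consumed by bookings
        self._doc_free: dict[tuple[int, int], list] = {}
        self._doctors_by_team: dict[str, list] = {}
        for d in self.doctors:
            self._doctors_by_team.setdefault(d.team, []).append(d)
        self._next_pid = 0
        self._arrival_days = 0
        self._pall_rr = 0

    # ---- helpers ---------------------------------------------------------

    def _plan_of(self, patient: Patient):
        return self.config.plan_by_id(patient.care_plan)

    def _workday(self, day: int) -> bool:
        return not is_weekend(day) and day not in self.holidays

    def _edd_sorted(self, queue):
        return sorted(queue, key=lambda p: (policies.due_day(p, self.config), p.id))

    # ---- setup -----------------------------------------------------------

    def schedule_arrival_generation(self, n_days: int) -> None:
        """One generator event per workday at 00:00 over ``n_days``."""
        self._arrival_days = n_days
        for day in range(n_days):
            if self._workday(day):
                self.engine.schedule(
                    day * MINUTES_PER_DAY, self._on_arrival_day, kind="arrival_day",
                    payload=day,
                )
        # dispatch wake-ups: doctors' agenda intervals open during the day
        starts_by_wd = [
            sorted({s for d in self.doctors for (s, _e) in d.weekly_free[wd]})
            for wd in range(5)
        ]
        for day in range(n_days + self.config.experiment.drain_days):
            if not self._workday(day):
                continue
            base = day * MINUTES_PER_DAY
            for m in starts_by_wd[day % 7]:
                self.engine.schedule(base + m, self._on_dispatch_tick,
                                     kind="contour_window_opens",
                                     priority=PRIORITY_REQUEST)
            self.engine.schedule(
                base + self.config.resources.planner_shift[0],
                self._on_dispatch_tick, kind="planner_shift_start",
                priority=PRIORITY_REQUEST,
            )

    def inject_consultation(self, site: str, time: int) -> None:
        """Schedule a single consultation by hand (micro-scenario runs)."""
        self.engine.schedule(time, self._on_consultation, kind="consultation",
                             payload=site)

    # ---- event handlers --------------------------------------------------

    def _on_arrival_day(self, ev) -> None:
        day = ev.payload
        rng = self.rng.arrivals
        counts = sample_daily_arrivals(day % 7, self.config.arrivals.rates(), rng)
        w0, w1 = self.config.arrivals.consult_window
        base = day * MINUTES_PER_DAY
        arrivals = []
        for site, n in counts.items():
            for _ in range(n):
                t = base + int(rng.integers(w0, w1))
                arrivals.append((t, site))
        for t, site in sorted(arrivals):
            self.engine.schedule(t, self._on_consultation, kind="consultation",
                                 payload=site)

    def _on_consultation(self, ev) -> None:
        now = self.engine.now
        p = Patient(id=self._next_pid, arrival_time=now, tumor_site=ev.payload)
        self._next_pid += 1
        self.patients.append(p)
        assign_care_content(p, self.config, self.rng.care_content)
        p.strategy = policies.pull_policy(p, self.config)
        plan = self._plan_of(p)
        # assigned doctor: uniform over the site's specialty team(s)
        teams = SITE_TO_TEAMS[p.tumor_site]
        pool = [d for t in teams for d in self._doctors_by_team.get(t, [])]
        p.assigned_doctor = pool[
            int(self.rng.care_content.integers(0, len(pool)))
        ].person_id
        self.log.emit(now, "arrival", patient=p.id, site=p.tumor_site,
                      urgency=p.urgency, strategy=p.strategy)

        # Moment 1: imaging for everyone; start date for pull patients
        appts = policies.book_imaging(p, self.calendars, self.config, now)
        for kind, slot in appts.items():
            self.log.emit(now, f"book_{kind.lower()}", patient=p.id,
                          resource=slot.machine, slot_start=slot.start,
                          slot_end=slot.end)
            self.engine.schedule(slot.end, self._on_scan_done, kind="scan_done",
                                 priority=PRIORITY_RELEASE,
                                 payload=(p, kind, slot))
        p._n_scans = len(appts)  # type: ignore[attr-defined]
        p._scans_done = 0        # type: ignore[attr-defined]
        if p.strategy == "pull":
            policies.schedule_start_pull(p, plan, self.config, self.rng.ttt)
            self.log.emit(now, "pull_start_scheduled", patient=p.id,
                          start_day=p.scheduled_start_day)
            self._arm_start_checkpoints(p)

    def _on_scan_done(self, ev) -> None:
        p, kind, slot = ev.payload
        now = self.engine.now
        self.log.emit(now, f"{kind.lower()}_done", patient=p.id, resource=slot.machine,
                      occupied=slot.duration)
        if kind == "CT":
            p.ct_time = now
        p.last_scan_time = now if p.last_scan_time is None else max(p.last_scan_time, now)
        p._scans_done += 1
        if p._scans_done == p._n_scans:
            delay = sample_ipp_delay_minutes(p, self.config.ipp, self.rng.ipp)
            self.engine.schedule(now + delay, self._on_ipp_done, kind="ipp_done",
                                 payload=p)

    def _on_ipp_done(self, ev) -> None:
        p = ev.payload
        p.ipp_done_time = self.engine.now
        self.log.emit(self.engine.now, "ipp_done", patient=p.id)
        self._contour_queue.append(p)
        self._dispatch_contouring()

    def _on_dispatch_tick(self, ev) -> None:
        if self._contour_queue:
            self._dispatch_contouring()
        if self._planning_queue:
            self._dispatch_planning()

    # ---- contouring ------------------------------------------------------

    def _free_today(self, doctor, day: int) -> list:
        key = (doctor.person_id, day)
        if key not in self._doc_free:
            self._doc_free[key] = doctor_free_intervals(doctor, day, self.holidays)
        return self._doc_free[key]

    def _dispatch_contouring(self) -> None:
        now = self.engine.now
        day = now // MINUTES_PER_DAY
        if not self._workday(day):
            return
        started = []
        for p in self._edd_sorted(self._contour_queue):
            dur = self.config.service_times.contour_minutes(p.urgency)
            if p.palliative:
                # any doctor; spread the palliative load: most free time
                # left today first, round-robin among ties
                rr = self._pall_rr
                n_doc = len(self.doctors)
                candidates = sorted(
                    self.doctors,
                    key=lambda d: (
                        -sum(
                            e - max(s, now)
                            for s, e in self._free_today(d, day)
                            if e > now
                        ),
                        (d.person_id - rr) % n_doc,
                    ),
                )
                self._pall_rr += 1
            else:
                candidates = [d for d in self.doctors
                              if d.person_id == p.assigned_doctor]
            booked = False
            for doc in candidates:
                ivs = self._free_today(doc, day)
                for i, (s, e) in enumerate(ivs):
                    if s <= now and now + dur <= e:
                        # consume [now, now+dur) from the interval
                        rest = []
                        if s < now:
                            rest.append((s, now))
                        if now + dur < e:
                            rest.append((now + dur, e))
                        ivs[i:i + 1] = rest
                        self.engine.schedule(
                            now + dur, self._on_contour_done,
                            kind="contour_done", priority=PRIORITY_RELEASE,
                            payload=(p, doc),
                        )
                        self.log.emit(now, "contour_start", patient=p.id,
                                      resource=f"doc{doc.person_id}", duration=dur)
                        booked = True
                        break
                if booked:
                    break
            if booked:
                started.append(p)
        for p in started:
            self._contour_queue.remove(p)

    def _on_contour_done(self, ev) -> None:
        p, doc = ev.payload
        p.contour_done_time = self.engine.now
        self.log.emit(self.engine.now, "contour_done", patient=p.id,
                      resource=f"doc{doc.person_id}")
        self._planning_queue.append(p)
        self._dispatch_planning()
        if self._contour_queue:
            self._dispatch_contouring()

    # ---- treatment planning ---------------------------------------------

    def _planning_minutes(self, p: Patient) -> int:
        plan = self._plan_of(p)
        if p.planning_type == "P2":
            return plan.beam_setup_minutes
        minutes = plan.planning_minutes
        if p.needs_beam_setup:
            minutes += plan.beam_setup_minutes
        return minutes

    def _planner_finish_time(self, planner, start: int, minutes: int) -> int:
        """Walk the planner's shift calendar; planning resumes next morning."""
        remaining = minutes
        day, mod = divmod(start, MINUTES_PER_DAY)
        s, e = planner.shift
        while True:
            works = self._workday(day) and day not in planner.absence_days
            if works:
                cur = max(mod, s)
                avail = e - cur
                if avail >= remaining:
                    return day * MINUTES_PER_DAY + cur + remaining
                if avail > 0:
                    remaining -= avail
            day += 1
            mod = 0

    def _dispatch_planning(self) -> None:
        now = self.engine.now
        started = []
        for p in self._edd_sorted(self._planning_queue):
            elig = eligible_planners(
                p.planning_type, self.planners, self.skill_matrix, now,
                site=p.tumor_site, holidays=self.holidays,
            )
            if not elig:
                continue
            # least-skilled capable planner first, then least loaded
            elig.sort(key=lambda pl: (_SKILL_RANK[pl.skill], pl.active_tasks,
                                      pl.person_id))
            planner = elig[0]
            planner.active_tasks += 1
            minutes = self._planning_minutes(p)
            finish = self._planner_finish_time(planner, now, minutes)
            self.engine.schedule(finish, self._on_plan_done, kind="plan_done",
                                 priority=PRIORITY_RELEASE, payload=(p, planner))
            self.log.emit(now, "planning_start", patient=p.id,
                          resource=f"rtt{planner.person_id}", minutes=minutes)
            started.append(p)
            if p.strategy == "push":
                policies.schedule_start_push(
                    p, self._plan_of(p), self.config, self.rng.ttt, now
                )
                self.log.emit(now, "push_start_scheduled", patient=p.id,
                              start_day=p.scheduled_start_day)
        for p in started:
            self._planning_queue.remove(p)

    def _on_plan_done(self, ev) -> None:
        p, planner = ev.payload
        planner.active_tasks -= 1
        now = self.engine.now
        p.plan_done_time = now
        self.log.emit(now, "plan_done", patient=p.id,
                      resource=f"rtt{planner.person_id}")
        if p.strategy == "push":
            # a push start is never before plan completion; adjusting
            # forward here is not a rebook (the date was provisional)
            day = now // MINUTES_PER_DAY
            if p.scheduled_start_day is not None and p.scheduled_start_day <= day:
                plan = self._plan_of(p)
                p.scheduled_start_day = policies.next_admissible_day(
                    day, plan.start_weekday, self.holidays
                )
            self.engine.schedule(
                p.scheduled_start_day * MINUTES_PER_DAY
                + self.config.policies.start_instant_minute,
                self._on_treatment_start, kind="treatment_start", payload=p,
            )
        if self._planning_queue:
            self._dispatch_planning()

    # ---- first fraction (pull checkpoints) -------------------------------

    def _arm_start_checkpoints(self, p: Patient) -> None:
        now = self.engine.now
        chk = self.config.policies.rebook_checkpoint_minute
        eve = (p.scheduled_start_day - 1) * MINUTES_PER_DAY + chk
        if eve > now:
            self.engine.schedule(eve, self._on_pull_checkpoint,
                                 kind="rebook_checkpoint", payload=p)
        self.engine.schedule(
            max(now + 1,
                p.scheduled_start_day * MINUTES_PER_DAY
                + self.config.policies.start_instant_minute),
            self._on_pull_start_instant, kind="treatment_start", payload=p,
        )

    def _on_pull_checkpoint(self, ev) -> None:
        p = ev.payload
        if p.actual_start_day is not None:
            return
        # checkpoint belongs to the current scheduled date only
        if self.engine.now // MINUTES_PER_DAY != p.scheduled_start_day - 1:
            return
        if p.plan_done_time is None:
            self._rebook(p)

    def _on_pull_start_instant(self, ev) -> None:
        p = ev.payload
        if p.actual_start_day is not None:
            return
        if self.engine.now // MINUTES_PER_DAY != p.scheduled_start_day:
            return  # stale event from before a rebook
        if p.plan_done_time is None or p.plan_done_time > self.engine.now:
            self._rebook(p)
            return
        p.actual_start_day = p.scheduled_start_day
        self.log.emit(self.engine.now, "treatment_start", patient=p.id,
                      start_day=p.actual_start_day)

    def _rebook(self, p: Patient) -> None:
        plan = self._plan_of(p)
        old = p.scheduled_start_day
        policies.check_and_rebook(p, plan, self.config, self.engine.now,
                                  rng=self.rng.ttt)
        self.log.emit(self.engine.now, "rebook", patient=p.id, old_day=old,
                      new_day=p.scheduled_start_day)
        self._arm_start_checkpoints(p)

    def _on_treatment_start(self, ev) -> None:
        p = ev.payload
        if p.actual_start_day is not None:
            return
        p.actual_start_day = p.scheduled_start_day
        self.log.emit(self.engine.now, "treatment_start", patient=p.id,
                      start_day=p.actual_start_day)

    # ---- run -------------------------------------------------------------

    def run(self, n_days: int | None = None) -> SimResult:
        exp = self.config.experiment
        if n_days is None:
            n_days = exp.warmup_days + exp.horizon_days
        self.schedule_arrival_generation(n_days)
        horizon = (n_days + exp.drain_days) * MINUTES_PER_DAY
        self.engine.run_until(horizon)
        return SimResult(
            config=self.config,
            replication=self.replication,
            patients=self.patients,
            log=self.log,
            events_processed=self.engine.processed,
        )
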