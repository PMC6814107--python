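"""Deterministic event-calendar engine with stream-separated randomness.

All simulation time is kept as integer minutes since a configurable origin
(Monday 00:00).  Durations used throughout the department model (25/45/60/
120/150/960 min, whole days, whole weeks) are exact in this unit, so no
floating-point drift can creep into schedules.

Events are totally ordered by ``(time, priority, sequence)``.  Lower
priority numbers fire first at equal times; by convention resource
*release* events use a lower tier than resource *request* events so that
freed capacity is visible to requests arriving at the same instant.
"""

from __future__ import annotations

import datetime as _dt
import heapq
import json
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable

import numpy as np

__all__ = [
    "MINUTES_PER_DAY",
    "MINUTES_PER_WEEK",
    "PRIORITY_RELEASE",
    "PRIORITY_DEFAULT",
    "PRIORITY_REQUEST",
    "WEEKDAY_NAMES",
    "day_of",
    "minute_of_day",
    "weekday_of",
    "is_weekend",
    "day_start",
    "hm",
    "to_datetime",
    "Event",
    "Engine",
    "SimulationError",
    "RngStreams",
    "EventLog",
]

MINUTES_PER_DAY = 24 * 60
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY

# priority tiers: releases fire before requests at equal times
PRIORITY_RELEASE = 0
PRIORITY_DEFAULT = 1
PRIORITY_REQUEST = 2

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def day_of(t: int) -> int:
    """Simulation day index (day 0 starts at the origin, a Monday)."""
    return t // MINUTES_PER_DAY


def minute_of_day(t: int) -> int:
    return t % MINUTES_PER_DAY


def weekday_of(t_or_day: int, *, is_day: bool = False) -> int:
    """Weekday index 0=Mon .. 6=Sun.  Origin is a Monday."""
    day = t_or_day if is_day else day_of(t_or_day)
    return day % 7


def is_weekend(day: int) -> bool:
    return day % 7 >= 5


def day_start(day: int) -> int:
    return day * MINUTES_PER_DAY


def hm(hours: int, mins: int = 0) -> int:
    """Minutes-of-day for a wall-clock ``hours:mins``."""
    return hours * 60 + mins


def to_datetime(t: int, origin: _dt.date) -> _dt.datetime:
    """Map a simulation time to a calendar datetime given the origin date."""
    base = _dt.datetime.combine(origin, _dt.time())
    return base + _dt.timedelta(minutes=int(t))


class SimulationError(RuntimeError):
    """Logic error in the event calendar (e.g. scheduling in the past)."""


@dataclass(order=False)
class Event:
    """A scheduled occurrence.  Total order: (time, priority, sequence)."""

    time: int
    priority: int
    sequence: int
    kind: str
    payload: Any = None
    callback: Callable[["Event"], None] | None = None
    cancelled: bool = field(default=False, compare=False)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.time, self.priority, self.sequence)

    def __lt__(self, other: "Event") -> bool:
        return self.sort_key() < other.sort_key()

    def cancel(self) -> None:
        """Mark the event dead; it will be skipped when popped (O(1))."""
        self.cancelled = True


class Engine:
    """Minimal heapq-based discrete-event engine.

    Handlers are plain callables receiving the fired :class:`Event`.  A
    handler exception aborts the run with the offending event attached to
    the raised :class:`SimulationError` for post-mortem inspection.
    """

    def __init__(self, start_time: int = 0):
        self.now: int = start_time
        self._heap: list[Event] = []
        self._seq: int = 0
        self.processed: int = 0

    def schedule(
        self,
        time: int,
        callback: Callable[[Event], None],
        *,
        priority: int = PRIORITY_DEFAULT,
        kind: str = "",
        payload: Any = None,
    ) -> Event:
        if time < self.now:
            raise SimulationError(
                f"event {kind!r} scheduled at t={time} before clock t={self.now}"
            )
        ev = Event(int(time), priority, self._seq, kind, payload, callback)
        self._seq += 1
        heapq.heappush(self._heap, ev)
        return ev

    def schedule_in(self, delay: int, callback, **kw) -> Event:
        return self.schedule(self.now + int(delay), callback, **kw)

    def peek_time(self) -> int | None:
        while self._heap and self._heap[0].cancelled:
            heapq.heappop(self._heap)
        return self._heap[0].time if self._heap else None

    def run_until(self, horizon: int) -> int:
        """Process events with time <= ``horizon`` in order; returns count.

        On return the clock equals ``min(horizon, last event time)`` if any
        event fired, otherwise ``horizon``.
        """
        count = 0
        while True:
            t = self.peek_time()
            if t is None or t > horizon:
                break
            ev = heapq.heappop(self._heap)
            if ev.cancelled:
                continue
            if ev.time < self.now:  # pragma: no cover - guarded by schedule()
                raise SimulationError("clock would move backwards")
            self.now = ev.time
            if ev.callback is not None:
                try:
                    ev.callback(ev)
                except SimulationError:
                    raise
                except Exception as exc:
                    err = SimulationError(
                        f"handler failed for event kind={ev.kind!r} "
                        f"t={ev.time} seq={ev.sequence}: {exc!r}"
                    )
                    err.event = ev  # type: ignore[attr-defined]
                    raise err from exc
            count += 1
            self.processed += 1
        self.now = max(self.now, horizon)
        return count


# fixed stream registry: one substream per stochastic model component so a
# scenario edit (say, dropping CT slot labels) leaves unrelated draws
# untouched -- common random numbers across scenario comparisons.
STREAM_NAMES = (
    "arrivals",
    "care_content",
    "ttt",
    "ipp",
    "service",
    "scenario",
    "agenda",
)


class RngStreams:
    """Named independent random substreams.

    Each stream is a :class:`numpy.random.Generator` seeded from
    ``(base_seed, stream_index, replication_index)`` via
    :class:`numpy.random.SeedSequence`, so the same ``(base_seed,
    replication)`` pair reproduces a bit-identical event trace while
    different replications are statistically independent.
    """

    def __init__(self, base_seed: int, replication: int = 0):
        self.base_seed = int(base_seed)
        self.replication = int(replication)
        self._gens: dict[str, np.random.Generator] = {}

    def stream(self, name: str) -> np.random.Generator:
        if name not in STREAM_NAMES:
            raise KeyError(f"unknown RNG stream {name!r}; valid: {STREAM_NAMES}")
        if name not in self._gens:
            idx = STREAM_NAMES.index(name)
            ss = np.random.SeedSequence((self.base_seed, idx, self.replication))
            self._gens[name] = np.random.Generator(np.random.PCG64(ss))
        return self._gens[name]

    def __getattr__(self, name: str) -> np.random.Generator:
        if name.startswith("_"):
            raise AttributeError(name)
        if name in STREAM_NAMES:
            return self.stream(name)
        raise AttributeError(name)


class EventLog:
    """Append-only structured log of simulation events.

    Records are plain dicts; writable as JSONL (one record per line, time
    rendered as ISO-8601 using the configured origin date) or CSV with the
    same columns.
    """

    COLUMNS = ("time", "kind", "patient", "resource")

    def __init__(self, origin: _dt.date | None = None, enabled: bool = True):
        self.origin = origin or _dt.date(2017, 1, 2)
        self.enabled = enabled
        self.records: list[dict] = []

    def emit(self, time: int, kind: str, patient=None, resource=None, **extra) -> None:
        if not self.enabled:
            return
        rec = {"time": int(time), "kind": kind, "patient": patient, "resource": resource}
        if extra:
            rec.update(extra)
        self.records.append(rec)

    def _iso(self, t: int) -> str:
        return to_datetime(t, self.origin).isoformat()

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                out = dict(rec)
                out["time_iso"] = self._iso(rec["time"])
                fh.write(json.dumps(out) + "\n")

    def write_csv(self, path) -> None:
        import csv

        keys: list[str] = list(self.COLUMNS) + ["time_iso"]
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=keys, extrasaction="ignore")
            w.writeheader()
            for rec in self.records:
                out = dict(rec)
                out["time_iso"] = self._iso(rec["time"])
                w.writerow(out)

    def by_kind(self, kind: str) -> Iterable[dict]:
        return (r for r in self.records if r["kind"] == kind)
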