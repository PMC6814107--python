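"""Waiting-time KPIs, warm-up analysis and replication statistics.

The primary KPI is the waiting time in calendar days from consultation
(PlanRT creation) to the first irradiation.  Weekends count; a medically
intended planned delay is excluded by default (it is patient-chosen or
clinically required, not departmental congestion — configurable).  A
target breach is a waiting time strictly greater than the national
maximum for the patient's urgency (1 / 10 / 28 calendar days: "within" is
inclusive).

Across-replication precision uses the classic t-based relative-error
criterion: with n replication means, sample mean x-bar and SD s, the 95%
CI halfwidth is ``t_{n-1,0.975} * s / sqrt(n)`` and replications are added
until halfwidth / x-bar drops below a threshold (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig, URGENCIES
from .casemix import Patient

__all__ = [
    "waiting_time",
    "count_breaches",
    "KPISummary",
    "summarize_run",
    "replication_halfwidth",
    "replication_relative_error",
    "required_replications",
    "warmup_curve",
    "ReplicationStats",
    "aggregate_replications",
]


def waiting_time(patient: Patient, config: SimConfig) -> int | None:
    """Calendar days from arrival to first fraction, minus planned delay.

    Returns None for patients still in progress (no start recorded).
    """
    if patient.actual_start_day is None:
        return None
    days = patient.actual_start_day - patient.arrival_day()
    if config.policies.exclude_planned_delay_from_wt:
        days -= 7 * patient.planned_delay_weeks
    return max(0, int(days))


def count_breaches(patients, config: SimConfig) -> int:
    """Patients whose waiting time strictly exceeds their urgency target."""
    targets = config.policies.targets_days
    n = 0
    for p in patients:
        wt = waiting_time(p, config)
        if wt is not None and wt > targets[p.urgency]:
            n += 1
    return n


@dataclass
class KPISummary:
    """Timeliness KPIs of one replication's measured window."""

    n_patients: int = 0
    n_completed: int = 0
    n_wip: int = 0                  # still in progress at the horizon
    mean_wt: float = float("nan")
    mean_wt_pull: float = float("nan")
    mean_wt_push: float = float("nan")
    breaches: int = 0
    rebooks: int = 0
    pull_fraction: float = float("nan")
    per_urgency_wt: dict = field(default_factory=dict)
    per_urgency_breaches: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "n_patients": self.n_patients,
            "n_completed": self.n_completed,
            "n_wip": self.n_wip,
            "mean_wt": self.mean_wt,
            "mean_wt_pull": self.mean_wt_pull,
            "mean_wt_push": self.mean_wt_push,
            "breaches": self.breaches,
            "rebooks": self.rebooks,
            "pull_fraction": self.pull_fraction,
        }
        for u in URGENCIES:
            row[f"wt_{u}"] = self.per_urgency_wt.get(u, float("nan"))
            row[f"breaches_{u}"] = self.per_urgency_breaches.get(u, 0)
        return row


def summarize_run(result, window: tuple[int, int] | None = None) -> KPISummary:
    """KPIs over patients whose *arrival* falls in the measured window.

    ``window`` is (first_day, last_day_exclusive); by default the year
    after the warm-up period.  Warm-up truncation is post-hoc on the
    records: it never changes any event time.
    """
    cfg = result.config
    if window is None:
        w0 = cfg.experiment.warmup_days
        window = (w0, w0 + cfg.experiment.horizon_days)
    sel = [p for p in result.patients if window[0] <= p.arrival_day() < window[1]]
    out = KPISummary(n_patients=len(sel))
    wts, wts_pull, wts_push = [], [], []
    per_u: dict[str, list] = {u: [] for u in URGENCIES}
    targets = cfg.policies.targets_days
    breaches = 0
    per_u_breach = {u: 0 for u in URGENCIES}
    rebooks = 0
    n_pull = 0
    for p in sel:
        if p.strategy == "pull":
            n_pull += 1
        rebooks += p.rebook_count
        wt = waiting_time(p, cfg)
        if wt is None:
            out.n_wip += 1
            continue
        wts.append(wt)
        per_u[p.urgency].append(wt)
        (wts_pull if p.strategy == "pull" else wts_push).append(wt)
        if wt > targets[p.urgency]:
            breaches += 1
            per_u_breach[p.urgency] += 1
    out.n_completed = len(wts)
    out.mean_wt = float(np.mean(wts)) if wts else float("nan")
    out.mean_wt_pull = float(np.mean(wts_pull)) if wts_pull else float("nan")
    out.mean_wt_push = float(np.mean(wts_push)) if wts_push else float("nan")
    out.breaches = breaches
    out.rebooks = rebooks
    out.pull_fraction = n_pull / len(sel) if sel else float("nan")
    out.per_urgency_wt = {
        u: (float(np.mean(v)) if v else float("nan")) for u, v in per_u.items()
    }
    out.per_urgency_breaches = per_u_breach
    return out


# ---------------------------------------------------------------------------
# replication statistics
# ---------------------------------------------------------------------------


def replication_halfwidth(values, alpha: float = 0.05) -> float:
    """t-based CI halfwidth of the mean of replication outputs."""
    x = np.asarray(list(values), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 replications")
    s = x.std(ddof=1)
    t = stats.t.ppf(1 - alpha / 2, df=n - 1)
    return float(t * s / np.sqrt(n))


def replication_relative_error(values, alpha: float = 0.05) -> float:
    """Relative error of the CI halfwidth: halfwidth / |mean|."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replications")
    xbar = x.mean()
    if xbar == 0:
        raise ValueError("relative error undefined for zero mean")
    return replication_halfwidth(x, alpha) / abs(float(xbar))


def required_replications(
    simulate_fn,
    gamma: float = 0.05,
    alpha: float = 0.05,
    n_max: int = 100,
) -> tuple[int, list]:
    """Smallest n >= 2 whose accumulated replications achieve relative
    error < gamma; returns (n, values).  ``simulate_fn(i)`` produces the
    i-th replication output.  If n_max is reached the best achieved n is
    returned (its relative error may still exceed gamma).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    values = [float(simulate_fn(0)), float(simulate_fn(1))]
    n = 2
    while True:
        err = replication_relative_error(values, alpha)
        if err < gamma or n >= n_max:
            return n, values
        values.append(float(simulate_fn(n)))
        n += 1


@dataclass
class ReplicationStats:
    """Across-replication summary of one KPI."""

    name: str
    n: int
    mean: float
    sd: float
    halfwidth: float
    rel_error: float
    minimum: float
    maximum: float
    alpha: float = 0.05

    @classmethod
    def from_values(cls, name: str, values, alpha: float = 0.05) -> "ReplicationStats":
        x = np.asarray(list(values), dtype=float)
        hw = replication_halfwidth(x, alpha) if x.size >= 2 else float("nan")
        mean = float(x.mean())
        rel = hw / abs(mean) if mean != 0 and np.isfinite(hw) else float("nan")
        return cls(name=name, n=int(x.size), mean=mean, sd=float(x.std(ddof=1)),
                   halfwidth=hw, rel_error=rel, minimum=float(x.min()),
                   maximum=float(x.max()), alpha=alpha)

    def ci(self) -> tuple[float, float]:
        return (self.mean - self.halfwidth, self.mean + self.halfwidth)

    def to_dict(self) -> dict:
        lo, hi = self.ci()
        return {
            "n": self.n, "mean": self.mean, "sd": self.sd,
            "ci_low": lo, "ci_high": hi, "rel_error": self.rel_error,
            "min": self.minimum, "max": self.maximum,
        }


def aggregate_replications(rows: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Per-KPI mean, SD, 95% CI, min and max over replication rows."""
    out = {}
    for col in ("mean_wt", "mean_wt_pull", "mean_wt_push", "breaches",
                "rebooks", "pull_fraction"):
        if col in rows:
            vals = rows[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size >= 2:
                out[col] = ReplicationStats.from_values(col, vals, alpha).to_dict()
    return out


# ---------------------------------------------------------------------------
# warm-up analysis
# ---------------------------------------------------------------------------


def warmup_curve(
    patients,
    config: SimConfig,
    band: float = 0.02,
    min_days: int = 30,
) -> tuple[pd.DataFrame, int]:
    """Cumulative-average waiting time by start day, with a plateau day.

    Patients are ordered by their start day; the curve is the running mean
    of waiting times.  The plateau estimate is the first day after which
    the cumulative mean stays within ``band`` (relative) of its final
    value.  Refuses streams spanning fewer than ``min_days`` days.
    """
    recs = [
        (p.actual_start_day, waiting_time(p, config))
        for p in patients
        if p.actual_start_day is not None
    ]
    recs.sort()
    if not recs or recs[-1][0] - recs[0][0] < min_days:
        raise ValueError(f"stream shorter than {min_days} days")
    days = np.array([r[0] for r in recs], dtype=float)
    wts = np.array([r[1] for r in recs], dtype=float)
    cum = np.cumsum(wts) / np.arange(1, wts.size + 1)
    final = cum[-1]
    within = np.abs(cum - final) <= band * max(abs(final), 1e-12)
    # first index from which the curve never leaves the band again
    idx = wts.size - 1
    for i in range(wts.size - 1, -1, -1):
        if within[i]:
            idx = i
        else:
            break
    plateau_day = int(days[idx])
    curve = pd.DataFrame({"start_day": days, "cumulative_mean_wt": cum})
    return curve, plateau_day
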