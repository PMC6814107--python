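"""Computational experiments: baseline, scenario analysis, pull sweep.

Scenarios are pure transforms of a baseline configuration:

* ``S1_spread_consultations`` — equalise each care trajectory's arrival
  rate over the five weekdays (weekly mass preserved exactly);
* ``S2_no_ct_preallocation`` — drop the IV-contrast and acute-reservation
  slot labels from the CT calendars;
* ``S3_balance_contouring`` — flatten every doctor's contouring
  availability to the same hours each day (>= 2 h/day, weekly hours
  preserved);
* ``S4_p3_lung_chestwall`` — let P3-level planners serve lung and chest
  wall plans;
* ``S5_extra_p4_planner`` — add one full-time P4-level planning RTT.

Replications share random-number streams across scenarios (common random
numbers): a scenario edit only perturbs the draws of the components it
touches.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .kpi import aggregate_replications, summarize_run
from .pathway import Simulation

__all__ = [
    "SCENARIOS",
    "apply_scenario",
    "transform_spread_consultations",
    "transform_no_ct_preallocation",
    "transform_balance_contouring",
    "transform_skill_upgrade",
    "transform_extra_p4_planner",
    "run_experiment",
    "nested_sweep",
    "run_pull_sweep",
    "ExperimentResult",
]


def transform_spread_consultations(config: SimConfig) -> SimConfig:
    """S1: same mean arrival rate on every weekday per care trajectory.

    Trajectory selection probabilities are per-site constants, so
    equalising each site's weekday rates equalises every trajectory's
    while preserving its weekly total exactly.
    """
    cfg = config.copy()
    rates = config.arrivals.rates()
    cfg.arrivals.site_weekday_rates = {
        site: [sum(v) / 5.0] * 5 for site, v in rates.items()
    }
    return cfg


def transform_no_ct_preallocation(config: SimConfig) -> SimConfig:
    """S2: all CT slots unrestricted (no IV-contrast or acute labels)."""
    cfg = config.copy()
    cfg.resources.iv_excluded_morning_slots = 0
    cfg.resources.acute_reserved_slots_per_day = 0
    return cfg


def transform_balance_contouring(config: SimConfig) -> SimConfig:
    """S3: each doctor available for contouring the same hours every day.

    Flattens availability to weekly_hours / 5 per day, preserving each
    doctor's weekly contouring hours and guaranteeing at least 2 h/day.
    """
    cfg = config.copy()
    res = config.resources
    if res.doctor_availability_mode == "pattern":
        weekly = sum(res.doctor_free_hours_pattern)
    else:
        weekly = res.doctor_weekly_contour_hours
    daily = weekly / 5.0
    if daily < 2.0:
        raise ConfigError(
            "balancing requires >= 10 weekly contouring hours (2 h/day)"
        )
    cfg.resources.doctor_availability_mode = "pattern"
    cfg.resources.doctor_free_hours_pattern = [daily] * 5
    return cfg


def transform_skill_upgrade(config: SimConfig) -> SimConfig:
    """S4: P3 planners may also serve lung and chest wall plans."""
    cfg = config.copy()
    extra = set(cfg.resources.p3_extra_sites) | {"lung", "chest_wall"}
    cfg.resources.p3_extra_sites = sorted(extra)
    return cfg


def transform_extra_p4_planner(config: SimConfig) -> SimConfig:
    """S5: one more full-time P4-level planning RTT."""
    cfg = config.copy()
    cfg.resources.planners = dict(cfg.resources.planners)
    cfg.resources.planners["P4"] = cfg.resources.planners.get("P4", 0) + 1
    return cfg


SCENARIOS = {
    "baseline": lambda c: c.copy(),
    "S1_spread_consultations": transform_spread_consultations,
    "S2_no_ct_preallocation": transform_no_ct_preallocation,
    "S3_balance_contouring": transform_balance_contouring,
    "S4_p3_lung_chestwall": transform_skill_upgrade,
    "S5_extra_p4_planner": transform_extra_p4_planner,
}


def apply_scenario(config: SimConfig, scenario: str) -> SimConfig:
    if scenario not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; valid: {sorted(SCENARIOS)}"
        )
    return SCENARIOS[scenario](config).validate()


class ExperimentResult:
    """Per-replication KPI rows plus across-replication aggregates."""

    def __init__(self, scenario: str, rows: pd.DataFrame, aggregate: dict):
        self.scenario = scenario
        self.replications = rows
        self.aggregate = aggregate

    def to_json(self, path=None) -> str:
        payload = {
            "scenario": self.scenario,
            "n_replications": int(len(self.replications)),
            "aggregate": self.aggregate,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_experiment(
    config: SimConfig,
    scenario: str = "baseline",
    n_replications: int | None = None,
    seed: int | None = None,
    trace: bool = False,
) -> ExperimentResult:
    """Run n independent replications of a scenario and aggregate KPIs.

    Each replication simulates the warm-up period plus the measured
    horizon (plus drain days so work in progress completes); KPIs cover
    patients arriving in the measured window only.
    """
    cfg = apply_scenario(config, scenario)
    n = n_replications or cfg.experiment.replications
    if n < 1:
        raise ConfigError("need at least one replication")
    seed = cfg.experiment.base_seed if seed is None else seed
    rows = []
    for rep in range(n):
        sim = Simulation(cfg, replication=rep, base_seed=seed, trace=trace)
        result = sim.run()
        rows.append(summarize_run(result).to_row())
    df = pd.DataFrame(rows)
    df.insert(0, "replication", np.arange(n))
    agg = aggregate_replications(df) if n >= 2 else {}
    return ExperimentResult(scenario, df, agg)


def nested_sweep(config: SimConfig) -> list[list[str]]:
    """The workflow-control sweep: cumulatively promote tumor sites to
    pull, simplest pre-treatment first, ending with every site (100% pull).
    """
    order = config.site_complexity_order
    return [order[:k] for k in range(len(order) + 1)]


def run_pull_sweep(
    config: SimConfig,
    sweep: list[list[str]] | None = None,
    n_replications: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """KPIs at each pull-promotion step (the data behind the box plots).

    ``sweep`` must be nested (each step adds sites).  Returns one row per
    sweep point with the realised pull fraction and the aggregate KPIs.
    """
    if sweep is None:
        sweep = nested_sweep(config)
    for a, b in zip(sweep, sweep[1:]):
        if not set(a) <= set(b):
            raise ConfigError("sweep must be nested (each step adds sites)")
    out = []
    for sites in sweep:
        cfg = config.copy()
        cfg.policies.pull_promoted_sites = list(sites)
        res = run_experiment(cfg, "baseline", n_replications, seed)
        row = {
            "promoted_sites": ",".join(sites) if sites else "(baseline)",
            "n_promoted": len(sites),
            "pull_fraction": float(res.replications["pull_fraction"].mean()),
        }
        for col in ("mean_wt", "breaches", "rebooks"):
            stats = res.aggregate.get(col)
            row[col] = float(res.replications[col].mean())
            if stats:
                row[f"{col}_ci_low"] = stats["ci_low"]
                row[f"{col}_ci_high"] = stats["ci_high"]
                row[f"{col}_min"] = stats["min"]
                row[f"{col}_max"] = stats["max"]
        out.append(row)
    return pd.DataFrame(out)
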