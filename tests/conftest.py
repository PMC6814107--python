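"""Shared fixtures: the default department preset and generated cohorts."""

import numpy as np
import pytest

import rtflowsim as rfs
from rtflowsim.config import CarePlanSpec, SimConfig, TUMOR_SITES


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return rfs.default_config()


@pytest.fixture(scope="session")
def population_100k(default_cfg):
    """One large care-content draw shared by the input-recovery tests."""
    rng = np.random.default_rng(20231115)
    return rfs.generate_population(default_cfg, 100_000, rng)


def make_micro_config(
    *,
    site: str = "brain",
    urgency: str = "regular",
    strategy_push: bool = True,
    planning_minutes: int = 300,
    push_gap_day: int = 2,
    ttt_day: int = 7,
    needs: dict | None = None,
    planned_delay_weeks_mass: dict | None = None,
) -> SimConfig:
    """A degenerate single-trajectory department for hand-traceable runs.

    All probabilities are 0/1, all stochastic delays are off, staff never
    take leave, and machine/staff capacity is ample, so every milestone
    is a deterministic function of the arrival instant.
    """
    cfg = rfs.default_config()
    needs = needs or {}
    urgency_mix = {u: (1.0 if u == urgency else 0.0)
                   for u in ("acute", "subacute", "regular")}
    plans = []
    for s in TUMOR_SITES:
        plans.append(
            CarePlanSpec(
                id=f"{s}_only",
                tumor_site=s,
                p_select=1.0,
                urgency_mix=dict(urgency_mix),
                p_mri=1.0 if needs.get("mri") else 0.0,
                p_petct=1.0 if needs.get("petct") else 0.0,
                p_warping=0.0,
                p_image_registration=0.0,
                p_p2=0.0,
                p_beam_conjunction=0.0,
                auto_p3=False,
                p_iv_contrast=0.0,
                p_planned_delay=1.0 if planned_delay_weeks_mass else 0.0,
                delay_weeks_probs=planned_delay_weeks_mass
                or {w: 1 / 8 for w in range(1, 9)},
                p_combined_given_regular=0.0 if strategy_push else 1.0,
                beam_setup_minutes=60,
                planning_minutes=planning_minutes,
                start_weekday=None,
            )
        )
    cfg.care_plans = plans
    # degenerate start-date tables
    cfg.policies.ttt_pull = {
        u: {wd: {ttt_day if u == "regular" else 1: 1.0} for wd in range(5)}
        for u in ("acute", "subacute", "regular")
    }
    cfg.policies.ttt_pull["acute"] = {wd: {1: 1.0} for wd in range(5)}
    cfg.policies.ttt_push = {wd: {push_gap_day: 1.0} for wd in range(5)}
    # ample, deterministic staffing
    cfg.resources.absence_rate = 0.0
    cfg.resources.vacation_weeks_per_year = 0.0
    cfg.resources.doctor_availability_mode = "pattern"
    cfg.resources.doctor_free_hours_pattern = [9.0] * 5
    cfg.holidays = []
    cfg.arrivals.site_weekday_rates = {s: [0.0] * 5 for s in TUMOR_SITES}
    cfg.validate()
    return cfg
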