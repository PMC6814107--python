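"""Patient arrival and care-content generation.

Arrivals follow independent Poisson processes per tumor site with
weekday-dependent rates (no weekend or holiday arrivals).  Each arriving
patient is then assigned a full care content — care trajectory, urgency,
imaging steps, planning type, planned delay, pull/push eligibility — by
sampling the configured care-plan catalogue, the synthetic stand-in for a
department's historical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, SimConfig, CarePlanSpec, TUMOR_SITES, URGENCIES

__all__ = [
    "Patient",
    "sample_daily_arrivals",
    "split_rates_by_site",
    "assign_care_content",
    "sample_planned_delay",
    "generate_population",
]


@dataclass
class Patient:
    """One simulated care trajectory from consultation to first fraction."""

    id: int
    arrival_time: int = 0          # sim minutes of PlanRT creation
    tumor_site: str = ""
    care_plan: str = ""
    urgency: str = ""
    strategy: str = ""             # "pull" | "push"
    combined_modality: bool = False
    needs_mri: bool = False
    needs_petct: bool = False
    needs_warping: bool = False
    needs_image_registration: bool = False
    needs_beam_setup: bool = False
    needs_iv_contrast: bool = False
    planning_type: str = ""        # P2 | P3 | P4
    planned_delay_weeks: int = 0
    assigned_doctor: int | None = None
    scheduled_start_day: int | None = None
    actual_start_day: int | None = None
    rebook_count: int = 0
    # milestones, sim minutes (None until reached)
    ct_time: int | None = None
    last_scan_time: int | None = None
    ipp_done_time: int | None = None
    contour_done_time: int | None = None
    plan_done_time: int | None = None
    rebook_history: list = field(default_factory=list)

    @property
    def palliative(self) -> bool:
        """Acute or bone-metastasis: contour/plan by any available staff."""
        return self.urgency == "acute" or self.tumor_site == "bone_metastasis"

    def arrival_day(self) -> int:
        return self.arrival_time // (24 * 60)


def sample_daily_arrivals(weekday: int, site_rates: dict, rng: np.random.Generator) -> dict:
    """Poisson counts per tumor site for one workday.

    ``site_rates`` maps site -> [Mon..Fri] mean arrivals/day.
    """
    if not 0 <= weekday <= 4:
        raise ConfigError(f"arrivals only on workdays, got weekday {weekday}")
    counts = {}
    for site in TUMOR_SITES:
        rate = site_rates[site][weekday]
        if rate < 0:
            raise ConfigError(f"negative arrival rate for {site}")
        counts[site] = int(rng.poisson(rate)) if rate > 0 else 0
    return counts


def split_rates_by_site(weekday_totals, site_proportions: dict) -> dict:
    """Thin weekday total rates into per-site rates (Poisson-preserving)."""
    total_p = sum(site_proportions.values())
    if abs(total_p - 1.0) > 1e-9:
        raise ConfigError(f"site proportions sum to {total_p}, expected 1")
    return {
        site: [share * tot for tot in weekday_totals]
        for site, share in site_proportions.items()
    }


def _draw(rng: np.random.Generator, items, probs) -> object:
    probs = np.asarray(list(probs), dtype=float)
    return list(items)[rng.choice(len(probs), p=probs / probs.sum())]


def sample_planned_delay(plan: CarePlanSpec, rng: np.random.Generator) -> int:
    """Weeks of medically intended delay before pre-treatment (0 or 1..8)."""
    if plan.p_planned_delay <= 0 or rng.random() >= plan.p_planned_delay:
        return 0
    weeks = sorted(plan.delay_weeks_probs)
    return int(_draw(rng, weeks, [plan.delay_weeks_probs[w] for w in weeks]))


def assign_care_content(patient: Patient, config: SimConfig, rng: np.random.Generator) -> Patient:
    """Complete a patient's care content from the catalogue.

    Draws, in order: care plan given tumor site, urgency, imaging steps,
    planning type (P2 per plan; else P3 on automated-planning sites, P4
    otherwise), IV-contrast need, planned delay and the combined-modality
    flag for regular patients.  CT, contouring and treatment planning are
    always required and carry no flags.
    """
    plans = config.plans_for_site(patient.tumor_site)
    if not plans:
        raise ConfigError(f"no care plan for site {patient.tumor_site!r}")
    plan = _draw(rng, plans, [p.p_select for p in plans])
    patient.care_plan = plan.id
    patient.urgency = str(
        _draw(rng, URGENCIES, [plan.urgency_mix[u] for u in URGENCIES])
    )
    patient.needs_mri = rng.random() < plan.p_mri
    patient.needs_petct = rng.random() < plan.p_petct
    patient.needs_warping = rng.random() < plan.p_warping
    patient.needs_image_registration = rng.random() < plan.p_image_registration
    patient.needs_iv_contrast = rng.random() < plan.p_iv_contrast

    if rng.random() < plan.p_p2:
        patient.planning_type = "P2"
        patient.needs_beam_setup = True
    else:
        patient.planning_type = "P3" if plan.auto_p3 else "P4"
        patient.needs_beam_setup = rng.random() < plan.p_beam_conjunction

    patient.planned_delay_weeks = sample_planned_delay(plan, rng)
    patient.combined_modality = (
        patient.urgency == "regular" and rng.random() < plan.p_combined_given_regular
    )
    return patient


def generate_population(
    config: SimConfig,
    n: int,
    rng: np.random.Generator,
    site: str | None = None,
) -> list[Patient]:
    """Draw ``n`` patients' care content (no timing), for input validation.

    Sites are drawn from the overall mix implied by the arrival rates
    unless ``site`` pins them to one tumor site.
    """
    site_probs = config.site_probs()
    sites = list(TUMOR_SITES)
    probs = [site_probs[s] for s in sites]
    out = []
    for i in range(n):
        s = site if site is not None else str(_draw(rng, sites, probs))
        p = Patient(id=i, tumor_site=s)
        assign_care_content(p, config, rng)
        out.append(p)
    return out
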