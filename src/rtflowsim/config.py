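"""Department configuration: care-plan catalogue, resources, policies.

A :class:`SimConfig` is a plain, YAML-serialisable description of a
radiotherapy department: weekday arrival rates split over tumor sites, a
care-plan catalogue (the probability tables that drive each patient's care
content), machine slot templates, staff rosters, waiting-time targets and
experiment settings.

:func:`default_config` builds the bundled preset emulating a large Dutch
department in 2017.  The catalogue defines two plans per tumor site whose
mixture reproduces, exactly, every department-level marginal the preset is
calibrated to: urgency mix 1.3/30.8/67.9%, MRI 18.5%, PET-CT 3.9%, warping
12.4%, image registration 29.7%, beam set-up 34.7%, planned-delay fraction
13%, baseline pull share 40.8%, and a 93% beam-set-up-only (P2) share for
bone metastasis.  Per-site values are the preset's own choices; only the
mixture totals are pinned.
"""

from __future__ import annotations

import copy
import datetime as _dt
from dataclasses import dataclass, field, asdict

import yaml

__all__ = [
    "TUMOR_SITES",
    "URGENCIES",
    "DOCTOR_TEAMS",
    "PLAN_TYPES",
    "ConfigError",
    "ServiceTimes",
    "IPPConfig",
    "CarePlanSpec",
    "ArrivalConfig",
    "ResourceConfig",
    "PolicyConfig",
    "ExperimentConfig",
    "SimConfig",
    "default_config",
    "load_config",
    "save_config",
]

TUMOR_SITES = (
    "bone_metastasis",
    "breast",
    "lung",
    "brain",
    "prostate",
    "head_and_neck",
    "chest_wall",
    "others",
)

URGENCIES = ("acute", "subacute", "regular")

PLAN_TYPES = ("P2", "P3", "P4")

DOCTOR_TEAMS = (
    "lung",
    "head_and_neck",
    "breast",
    "cns",
    "gynecology",
    "gastrointestinal",
    "urology",
)

# which specialty team(s) contour each (non-palliative) tumor site
SITE_TO_TEAMS = {
    "bone_metastasis": list(DOCTOR_TEAMS),  # palliative: any doctor
    "breast": ["breast"],
    "chest_wall": ["breast"],
    "lung": ["lung"],
    "head_and_neck": ["head_and_neck"],
    "brain": ["cns"],
    "prostate": ["urology"],
    "others": ["gastrointestinal", "gynecology"],
}


class ConfigError(ValueError):
    """Invalid or inconsistent department configuration."""


def _check_probs(vec, name, tol=1e-9):
    total = float(sum(vec))
    if any(p < -tol or p > 1 + tol for p in vec):
        raise ConfigError(f"{name}: probabilities outside [0,1]: {vec}")
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {total}, expected 1")


@dataclass
class ServiceTimes:
    """Deterministic stage durations, minutes."""

    ct: int = 25
    mri: int = 45
    petct: int = 45
    contour_acute_subacute: int = 30
    contour_regular: int = 60
    peer_review: int = 60  # appended to every contouring

    def contour_minutes(self, urgency: str) -> int:
        base = self.contour_regular if urgency == "regular" else self.contour_acute_subacute
        return base + self.peer_review

    def validate(self):
        for f in ("ct", "mri", "petct", "contour_acute_subacute", "contour_regular", "peer_review"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"service time {f} must be positive")


@dataclass
class IPPConfig:
    """Image post-processing lags in days (lognormal, moment-matched)."""

    warp_mean_days: float = 0.4
    warp_sd_days: float = 0.6
    reg_mean_days: float = 0.1
    reg_sd_days: float = 1.0

    def validate(self):
        for f in ("warp_mean_days", "reg_mean_days"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"IPP {f} must be positive")
        for f in ("warp_sd_days", "reg_sd_days"):
            if getattr(self, f) < 0:
                raise ConfigError(f"IPP {f} must be non-negative")


@dataclass
class CarePlanSpec:
    """One care trajectory: probabilities and durations for its patients.

    CT, contouring and treatment planning are implicitly always required;
    the optional steps carry per-plan probabilities.  ``p_p2`` is the
    probability the patient gets a beam-set-up-only (P2) plan; failing
    that, sites with ``auto_p3`` get automated planning (P3) and everyone
    else conventional planning (P4).  ``p_beam_conjunction`` is the chance
    that a non-P2 patient additionally needs a beam set-up alongside
    regular planning.
    """

    id: str
    tumor_site: str
    p_select: float
    urgency_mix: dict = field(default_factory=dict)  # urgency -> prob
    p_mri: float = 0.0
    p_petct: float = 0.0
    p_warping: float = 0.0
    p_image_registration: float = 0.0
    p_p2: float = 0.0
    p_beam_conjunction: float = 0.0
    auto_p3: bool = False
    p_iv_contrast: float = 0.25
    p_planned_delay: float = 0.13
    delay_weeks_probs: dict = field(
        default_factory=lambda: {w: 1.0 / 8.0 for w in range(1, 9)}
    )  # weeks 1..8 -> prob, conditional on having a delay
    p_combined_given_regular: float = 0.0  # pull-eligible regular subgroup
    beam_setup_minutes: int = 90
    planning_minutes: int = 300
    start_weekday: int | None = None  # e.g. 0 => first fraction on Mondays

    def validate(self):
        if self.tumor_site not in TUMOR_SITES:
            raise ConfigError(f"plan {self.id}: unknown tumor site {self.tumor_site!r}")
        if not 0 <= self.p_select <= 1:
            raise ConfigError(f"plan {self.id}: p_select out of range")
        if set(self.urgency_mix) != set(URGENCIES):
            raise ConfigError(f"plan {self.id}: urgency_mix must cover {URGENCIES}")
        _check_probs(self.urgency_mix.values(), f"plan {self.id} urgency_mix")
        for f in ("p_mri", "p_petct", "p_warping", "p_image_registration", "p_p2",
                  "p_beam_conjunction", "p_iv_contrast", "p_planned_delay",
                  "p_combined_given_regular"):
            v = getattr(self, f)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ConfigError(f"plan {self.id}: {f}={v} outside [0,1]")
        if self.delay_weeks_probs:
            _check_probs(self.delay_weeks_probs.values(), f"plan {self.id} delay weeks")
            if not set(self.delay_weeks_probs) <= set(range(1, 9)):
                raise ConfigError(f"plan {self.id}: delay lengths must be 1..8 weeks")
        if self.beam_setup_minutes <= 0 or self.planning_minutes <= 0:
            raise ConfigError(f"plan {self.id}: durations must be positive")
        if self.start_weekday is not None and not 0 <= self.start_weekday <= 4:
            raise ConfigError(f"plan {self.id}: start_weekday must be a workday index")


@dataclass
class ArrivalConfig:
    """Poisson arrival rates: weekday totals split over tumor sites."""

    weekday_totals: list = field(
        default_factory=lambda: [17.5, 20.9, 23.2, 21.7, 15.5]
    )  # Mon..Fri
    site_shares: dict = field(default_factory=dict)  # site -> proportion
    # per-site per-weekday override; if set it takes precedence over the
    # totals x shares product (used by the consultation-spreading scenario)
    site_weekday_rates: dict | None = None
    consult_window: tuple = (8 * 60, 17 * 60)  # consult instants 08:00-17:00

    def rates(self) -> dict:
        """site -> [Mon..Fri] mean arrivals/day."""
        if self.site_weekday_rates is not None:
            return {s: list(map(float, v)) for s, v in self.site_weekday_rates.items()}
        return {
            s: [share * tot for tot in self.weekday_totals]
            for s, share in self.site_shares.items()
        }

    def validate(self):
        if len(self.weekday_totals) != 5 or any(r < 0 for r in self.weekday_totals):
            raise ConfigError("weekday_totals must be 5 non-negative rates Mon..Fri")
        if self.site_weekday_rates is None:
            if set(self.site_shares) != set(TUMOR_SITES):
                raise ConfigError("site_shares must cover all 8 tumor sites")
            _check_probs(self.site_shares.values(), "site_shares")
        else:
            for s, v in self.site_weekday_rates.items():
                if s not in TUMOR_SITES or len(v) != 5 or any(r < 0 for r in v):
                    raise ConfigError(f"bad site_weekday_rates entry for {s!r}")


@dataclass
class ResourceConfig:
    """Machines, doctor teams and treatment-planning staff."""

    # CT: 2 scanners, 13 slots each => 26 x 25-min slots/day
    ct_scanners: int = 2
    ct_slots_per_scanner: int = 13
    ct_slot_minutes: int = 25
    ct_day_start: int = 7 * 60 + 30
    iv_excluded_morning_slots: int = 2   # per scanner; 0 disables the label
    acute_reserved_slots_per_day: int = 1  # on the first scanner
    iv_restriction_per_scanner: bool = True

    mri_slots_per_weekday: list = field(default_factory=lambda: [8, 7, 8, 7, 7])
    mri_slot_minutes: int = 45
    mri_day_start: int = 8 * 60
    petct_slots_per_weekday: list = field(default_factory=lambda: [1, 1, 1, 1, 1])
    petct_slot_minutes: int = 45
    petct_day_start: int = 9 * 60

    booking_horizon_days: int = 120

    doctor_teams: dict = field(
        default_factory=lambda: {
            "lung": 7, "head_and_neck": 9, "breast": 9, "cns": 3,
            "gynecology": 4, "gastrointestinal": 5, "urology": 7,
        }
    )
    doctor_shift: tuple = (8 * 60, 17 * 60)
    # weekly hours a doctor has left for contouring once consultations,
    # meetings and admin are accounted for
    doctor_weekly_contour_hours: float = 14.0
    # "consult_coupled": each team's daily contouring availability varies
    # inversely with that team's consultation load on the weekday (the
    # same doctors hold the consultations); "pattern": use the explicit
    # weekday pattern below for every doctor
    doctor_availability_mode: str = "consult_coupled"
    # lower bound on a weekday's relative availability weight in coupled
    # mode (keeps heavy consultation days from losing contouring entirely)
    availability_coupling_floor: float = 0.6
    doctor_free_hours_pattern: list = field(
        default_factory=lambda: [2.4, 2.4, 2.4, 2.4, 2.4]
    )
    absence_rate: float = 0.04        # incidental P(absent)/workday
    vacation_weeks_per_year: float = 5.0  # week-long leave blocks/person

    planners: dict = field(default_factory=lambda: {"P2": 3, "P3": 7, "P4": 14})
    planner_shift: tuple = (8 * 60, 16 * 60 + 30)
    planner_concurrency: dict = field(default_factory=lambda: {"P2": 1, "P3": 2, "P4": 2})
    # tumor sites whose conventional (P4) plans P3-level planners may also
    # serve (empty at baseline; the skill-upgrade scenario adds lung and
    # chest wall)
    p3_extra_sites: list = field(default_factory=list)

    def validate(self):
        if self.ct_scanners < 1 or self.ct_slots_per_scanner < 1:
            raise ConfigError("need at least one CT scanner with slots")
        if len(self.mri_slots_per_weekday) != 5 or len(self.petct_slots_per_weekday) != 5:
            raise ConfigError("machine weekly slot templates must have 5 entries")
        if set(self.doctor_teams) != set(DOCTOR_TEAMS):
            raise ConfigError(f"doctor_teams must cover {DOCTOR_TEAMS}")
        if any(n < 0 for n in self.doctor_teams.values()):
            raise ConfigError("negative doctor count")
        if not set(self.planners) <= set(PLAN_TYPES):
            raise ConfigError("planner skill levels must be P2/P3/P4")
        if not 0 <= self.absence_rate < 1:
            raise ConfigError("absence_rate must be in [0,1)")
        if len(self.doctor_free_hours_pattern) != 5:
            raise ConfigError("doctor_free_hours_pattern must have 5 entries")
        if self.doctor_availability_mode not in ("consult_coupled", "pattern"):
            raise ConfigError("doctor_availability_mode must be "
                              "'consult_coupled' or 'pattern'")
        if self.doctor_weekly_contour_hours <= 0:
            raise ConfigError("doctor_weekly_contour_hours must be positive")


@dataclass
class PolicyConfig:
    """Workflow-control policy and first-fraction scheduling tables."""

    # tumor sites promoted to pull beyond acute/subacute/combined-regular
    pull_promoted_sites: list = field(default_factory=list)
    # (urgency, weekday) -> {days: mass}; bone metastasis shares the
    # subacute table per the printed support (1-8 days)
    ttt_pull: dict = field(default_factory=dict)
    # weekday -> {days: mass}, gap between planning start and first fraction
    ttt_push: dict = field(default_factory=dict)
    rebook_checkpoint_minute: int = 17 * 60 + 30
    # the first fraction is delivered by the end of the start day; the
    # start-instant feasibility check runs at this minute
    start_instant_minute: int = 17 * 60
    # rebook rule: "next_admissible" shifts +1 admissible day; "redraw"
    # re-draws the start from the TTT tail beyond the missed date
    rebook_rule: str = "next_admissible"
    # reserved flag for a backward-scheduling variant of pull imaging
    # (book scans backwards from the start date); not implemented — both
    # strategies share the forward flow
    backward_imaging_scheduling: bool = False
    targets_days: dict = field(
        default_factory=lambda: {"acute": 1, "subacute": 10, "regular": 28}
    )
    # waiting time excludes the medically intended planned delay
    exclude_planned_delay_from_wt: bool = True

    def validate(self):
        for s in self.pull_promoted_sites:
            if s not in TUMOR_SITES:
                raise ConfigError(f"unknown tumor site in pull policy: {s!r}")
        if self.rebook_rule not in ("next_admissible", "redraw"):
            raise ConfigError(f"unknown rebook rule {self.rebook_rule!r}")
        if self.backward_imaging_scheduling:
            raise ConfigError(
                "backward imaging scheduling is reserved but not implemented"
            )
        if set(self.targets_days) != set(URGENCIES):
            raise ConfigError("targets_days must cover acute/subacute/regular")
        t = self.targets_days
        if not 0 < t["acute"] < t["subacute"] < t["regular"]:
            raise ConfigError("targets must satisfy 0 < acute < subacute < regular")
        for urg, by_wd in self.ttt_pull.items():
            if urg not in URGENCIES:
                raise ConfigError(f"ttt_pull: unknown urgency {urg!r}")
            for wd, dist in by_wd.items():
                _check_probs(dist.values(), f"ttt_pull[{urg}][{wd}]")
        for wd, dist in self.ttt_push.items():
            _check_probs(dist.values(), f"ttt_push[{wd}]")
            if any(not 1 <= d <= 7 for d in dist):
                raise ConfigError("push gap support must be 1..7 days")


@dataclass
class ExperimentConfig:
    replications: int = 15
    warmup_days: int = 130
    horizon_days: int = 365
    drain_days: int = 60  # extra days to let work-in-progress finish
    base_seed: int = 20170101

    def validate(self):
        if self.replications < 1:
            raise ConfigError("need at least one replication")
        if self.warmup_days < 0 or self.horizon_days < 1:
            raise ConfigError("bad warm-up/horizon lengths")


@dataclass
class SimConfig:
    """Complete department + experiment description (YAML round-trippable)."""

    arrivals: ArrivalConfig = field(default_factory=ArrivalConfig)
    care_plans: list = field(default_factory=list)
    resources: ResourceConfig = field(default_factory=ResourceConfig)
    policies: PolicyConfig = field(default_factory=PolicyConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    service_times: ServiceTimes = field(default_factory=ServiceTimes)
    ipp: IPPConfig = field(default_factory=IPPConfig)
    origin_date: str = "2017-01-02"  # a Monday; simulation day 0
    holidays: list = field(default_factory=list)  # ISO dates, no arrivals/work
    # sweep order used by the workflow-control analysis, simplest first
    site_complexity_order: list = field(
        default_factory=lambda: [
            "bone_metastasis", "breast", "prostate", "chest_wall",
            "brain", "lung", "others", "head_and_neck",
        ]
    )

    # ---- derived helpers -------------------------------------------------
    def origin(self) -> _dt.date:
        return _dt.date.fromisoformat(self.origin_date)

    def holiday_days(self) -> set:
        o = self.origin()
        return {( _dt.date.fromisoformat(d) - o).days for d in self.holidays}

    def plans_for_site(self, site: str) -> list:
        return [p for p in self.care_plans if p.tumor_site == site]

    def plan_by_id(self, plan_id: str) -> CarePlanSpec:
        for p in self.care_plans:
            if p.id == plan_id:
                return p
        raise KeyError(plan_id)

    def site_probs(self) -> dict:
        """Overall tumor-site mix implied by the weekly arrival rates."""
        rates = self.arrivals.rates()
        weekly = {s: sum(v) for s, v in rates.items()}
        total = sum(weekly.values())
        return {s: w / total for s, w in weekly.items()}

    def validate(self) -> "SimConfig":
        self.arrivals.validate()
        self.resources.validate()
        self.policies.validate()
        self.experiment.validate()
        self.service_times.validate()
        self.ipp.validate()
        if self.origin().weekday() != 0:
            raise ConfigError("origin_date must be a Monday")
        if not self.care_plans:
            raise ConfigError("care-plan catalogue is empty")
        seen = set()
        for p in self.care_plans:
            p.validate()
            if p.id in seen:
                raise ConfigError(f"duplicate care plan id {p.id!r}")
            seen.add(p.id)
        for site in TUMOR_SITES:
            plans = self.plans_for_site(site)
            if not plans:
                raise ConfigError(f"no care plan configured for site {site!r}")
            _check_probs([p.p_select for p in plans], f"p_select for site {site}")
        if set(self.site_complexity_order) != set(TUMOR_SITES):
            raise ConfigError("site_complexity_order must be a permutation of the 8 sites")
        return self

    def copy(self) -> "SimConfig":
        return copy.deepcopy(self)

    # ---- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["resources"]["doctor_shift"] = list(self.resources.doctor_shift)
        d["resources"]["planner_shift"] = list(self.resources.planner_shift)
        d["arrivals"]["consult_window"] = list(self.arrivals.consult_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = copy.deepcopy(d)
        arr = ArrivalConfig(**d.pop("arrivals", {}))
        arr.consult_window = tuple(arr.consult_window)
        res = ResourceConfig(**d.pop("resources", {}))
        res.doctor_shift = tuple(res.doctor_shift)
        res.planner_shift = tuple(res.planner_shift)
        pol = PolicyConfig(**d.pop("policies", {}))
        # YAML represents integer dict keys as ints already; normalise
        pol.ttt_pull = {
            u: {int(w): {int(k): float(v) for k, v in dist.items()}
                for w, dist in by_wd.items()}
            for u, by_wd in pol.ttt_pull.items()
        }
        pol.ttt_push = {
            int(w): {int(k): float(v) for k, v in dist.items()}
            for w, dist in pol.ttt_push.items()
        }
        exp = ExperimentConfig(**d.pop("experiment", {}))
        st = ServiceTimes(**d.pop("service_times", {}))
        ipp = IPPConfig(**d.pop("ipp", {}))
        plans = []
        for pd in d.pop("care_plans", []):
            p = CarePlanSpec(**pd)
            p.delay_weeks_probs = {int(k): float(v) for k, v in p.delay_weeks_probs.items()}
            plans.append(p)
        return cls(arrivals=arr, care_plans=plans, resources=res, policies=pol,
                   experiment=exp, service_times=st, ipp=ipp, **d)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = SimConfig.from_dict(data)
    cfg.validate()
    return cfg


def save_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# default preset
# ---------------------------------------------------------------------------

# department-level marginals the default catalogue is calibrated to
CAL = {
    "urgency": {"acute": 0.013, "subacute": 0.308, "regular": 0.679},
    "mri": 0.185,
    "petct": 0.039,
    "warping": 0.124,
    "image_registration": 0.297,
    "beam_setup": 0.347,
    "planned_delay": 0.13,
    "pull_share": 0.408,
    "bone_metastasis_p2": 0.93,
}

# overall tumor-site mix (weekly); the printed weekday totals are split by
# these shares.  lung + chest wall = 16.4% by construction (their planning
# work is the share moved to P3 level in the skill-upgrade scenario).
SITE_SHARES = {
    "bone_metastasis": 0.16,
    "breast": 0.22,
    "lung": 0.125,
    "brain": 0.07,
    "prostate": 0.11,
    "head_and_neck": 0.09,
    "chest_wall": 0.039,
    "others": 0.186,
}

# per-site step probabilities; "others" absorbs the residual so the share-
# weighted mixture hits the department marginal exactly.
_SITE_STEP = {
    "mri": {"bone_metastasis": 0.05, "breast": 0.05, "lung": 0.10, "brain": 0.90,
            "prostate": 0.35, "head_and_neck": 0.45, "chest_wall": 0.05},
    "petct": {"bone_metastasis": 0.0, "breast": 0.0, "lung": 0.15, "brain": 0.0,
              "prostate": 0.0, "head_and_neck": 0.15, "chest_wall": 0.0},
    "warping": {"bone_metastasis": 0.02, "breast": 0.05, "lung": 0.60, "brain": 0.0,
                "prostate": 0.0, "head_and_neck": 0.05, "chest_wall": 0.30},
    "image_registration": {"bone_metastasis": 0.05, "breast": 0.10, "lung": 0.65,
                           "brain": 0.85, "prostate": 0.40, "head_and_neck": 0.60,
                           "chest_wall": 0.35},
}

_SITE_P2 = {
    "bone_metastasis": 0.93, "breast": 0.12, "lung": 0.0, "brain": 0.02,
    "prostate": 0.02, "head_and_neck": 0.0, "chest_wall": 0.05, "others": 0.05,
}

_AUTO_P3_SITES = {"breast", "prostate"}  # automated planning sites

_SITE_DURATIONS = {  # (planning minutes, beam set-up minutes)
    "bone_metastasis": (150, 60),
    "breast": (180, 120),
    "prostate": (150, 90),
    "chest_wall": (300, 90),
    "brain": (300, 90),
    "lung": (420, 90),
    "others": (360, 90),
    "head_and_neck": (960, 90),
}

# bone metastasis is predominantly palliative; the other sites share one
# urgency profile solved so the population mix matches the calibration
_BM_URGENCY = {"acute": 0.06, "subacute": 0.86, "regular": 0.08}

# relative weekday consultation preference per tumor site (each specialty
# holds its clinics on preferred days: e.g. lung consultations cluster on
# Wednesdays); fitted to the printed weekday totals below
_SITE_WEEKDAY_PREF = {
    "bone_metastasis": [1.0, 1.0, 1.0, 1.0, 1.0],
    "breast": [1.6, 1.4, 1.0, 0.7, 0.5],
    "lung": [0.5, 0.7, 2.5, 0.8, 0.5],
    "brain": [0.6, 1.6, 0.6, 1.6, 0.6],
    "prostate": [0.5, 0.8, 0.8, 1.8, 1.1],
    "head_and_neck": [1.8, 0.6, 0.6, 1.6, 0.4],
    "chest_wall": [1.6, 1.4, 1.0, 0.7, 0.5],
    "others": [1.0, 1.2, 1.0, 1.2, 0.6],
}


def _ipf_rates(weekday_totals, site_shares, pref, iters: int = 200) -> dict:
    """Per-site per-weekday rates matching both margins exactly.

    Iterative proportional fitting of the preference matrix to row targets
    (each site's weekly mass) and column targets (the printed weekday
    totals).
    """
    import numpy as _np

    sites = list(site_shares)
    m = _np.array([pref[s] for s in sites], dtype=float)
    week_total = float(sum(weekday_totals))
    rows = _np.array([site_shares[s] * week_total for s in sites])
    cols = _np.asarray(weekday_totals, dtype=float)
    for _ in range(iters):
        m *= (rows / m.sum(axis=1))[:, None]
        m *= cols / m.sum(axis=0)
    return {s: [float(v) for v in m[i]] for i, s in enumerate(sites)}

_COMPLEX_WEIGHT = 0.3  # p_select of the "complex" plan within each site


def _solve_residual(per_site: dict, target: float, name: str) -> dict:
    """Fill the 'others' entry so the share-weighted mean equals target."""
    out = dict(per_site)
    partial = sum(SITE_SHARES[s] * v for s, v in out.items())
    resid = (target - partial) / SITE_SHARES["others"]
    if not -1e-12 <= resid <= 1 + 1e-12:
        raise ConfigError(f"calibration for {name} infeasible: residual {resid}")
    out["others"] = min(1.0, max(0.0, resid))
    return out


def _split_two(p: float) -> tuple[float, float]:
    """Split a site marginal over (complex, standard) plans, exactly.

    complex gets min(1, 1.5p); standard takes the remainder so that
    0.3*complex + 0.7*standard == p.
    """
    hi = min(1.0, 1.5 * p)
    lo = (p - _COMPLEX_WEIGHT * hi) / (1.0 - _COMPLEX_WEIGHT)
    return hi, lo


def _geometric_like(support, mode, ratio) -> dict:
    """Normalized two-sided geometric masses peaked at ``mode``."""
    w = {d: ratio ** abs(d - mode) for d in support}
    total = sum(w.values())
    return {d: v / total for d, v in w.items()}


def default_ttt_tables() -> tuple[dict, dict]:
    """Default first-fraction timing tables (pull and push).

    Shapes are truncated geometric-like masses over the empirically
    observed supports: acute 0-1 days, subacute (and bone metastasis) 1-8,
    regular 3-21; push gap 1-7 days from start of treatment planning.  The
    same table is used on every request weekday; the per-weekday structure
    exists so an empirical table can be dropped in.
    """
    acute = {0: 0.2, 1: 0.8}
    subacute = _geometric_like(range(1, 9), mode=4, ratio=0.5)
    regular = _geometric_like(range(3, 22), mode=8, ratio=0.8)
    push = _geometric_like(range(1, 8), mode=2, ratio=0.6)
    ttt_pull = {
        "acute": {wd: dict(acute) for wd in range(5)},
        "subacute": {wd: dict(subacute) for wd in range(5)},
        "regular": {wd: dict(regular) for wd in range(5)},
    }
    ttt_push = {wd: dict(push) for wd in range(5)}
    return ttt_pull, ttt_push


def _default_holidays(origin: _dt.date) -> list:
    """A generic 8-holiday closure calendar (weekdays only)."""
    days = [18, 95, 123, 151, 359, 361, 382, 459]
    return [(origin + _dt.timedelta(days=d)).isoformat() for d in days]


def default_config() -> SimConfig:
    """The bundled department preset (NKI-like 2017 parameters)."""
    steps = {k: _solve_residual(v, CAL[k], k) for k, v in _SITE_STEP.items()}

    # urgency: bone metastasis fixed, remaining sites share one profile
    bm_share = SITE_SHARES["bone_metastasis"]
    rest_share = 1.0 - bm_share
    rest_urg = {
        u: (CAL["urgency"][u] - bm_share * _BM_URGENCY[u]) / rest_share
        for u in URGENCIES
    }
    if any(v < 0 for v in rest_urg.values()):
        raise ConfigError("urgency calibration infeasible")

    # beam set-up in conjunction with regular planning: solve the uniform
    # conditional probability so the overall beam set-up share is exact
    p2_total = sum(SITE_SHARES[s] * _SITE_P2[s] for s in TUMOR_SITES)
    p_conj = (CAL["beam_setup"] - p2_total) / (1.0 - p2_total)

    # pull-eligible regular subgroup (combined-modality treatment):
    # acute + subacute + q * regular == pull share
    base_pull = CAL["urgency"]["acute"] + CAL["urgency"]["subacute"]
    p_combined = (CAL["pull_share"] - base_pull) / CAL["urgency"]["regular"]

    plans: list[CarePlanSpec] = []
    for site in TUMOR_SITES:
        urg = _BM_URGENCY if site == "bone_metastasis" else rest_urg
        plan_min, beam_min = _SITE_DURATIONS[site]
        for label, weight in (("complex", _COMPLEX_WEIGHT), ("standard", 1 - _COMPLEX_WEIGHT)):
            hi = label == "complex"
            pick = (lambda p: _split_two(p)[0]) if hi else (lambda p: _split_two(p)[1])
            plans.append(
                CarePlanSpec(
                    id=f"{site}_{label}",
                    tumor_site=site,
                    p_select=weight,
                    urgency_mix={u: float(urg[u]) for u in URGENCIES},
                    p_mri=pick(steps["mri"][site]),
                    p_petct=pick(steps["petct"][site]),
                    p_warping=pick(steps["warping"][site]),
                    p_image_registration=pick(steps["image_registration"][site]),
                    p_p2=_SITE_P2[site],
                    p_beam_conjunction=p_conj,
                    auto_p3=site in _AUTO_P3_SITES,
                    p_iv_contrast=0.25,
                    p_planned_delay=CAL["planned_delay"],
                    p_combined_given_regular=p_combined,
                    beam_setup_minutes=beam_min,
                    planning_minutes=min(
                        960, max(150, int(round(plan_min * (1.2 if hi else 0.9))))
                    ),
                    start_weekday=0 if site == "head_and_neck" else None,
                )
            )

    ttt_pull, ttt_push = default_ttt_tables()
    origin = _dt.date(2017, 1, 2)
    weekday_totals = [17.5, 20.9, 23.2, 21.7, 15.5]
    cfg = SimConfig(
        arrivals=ArrivalConfig(
            weekday_totals=list(weekday_totals),
            site_shares=dict(SITE_SHARES),
            site_weekday_rates=_ipf_rates(weekday_totals, SITE_SHARES,
                                          _SITE_WEEKDAY_PREF),
        ),
        care_plans=plans,
        resources=ResourceConfig(),
        policies=PolicyConfig(ttt_pull=ttt_pull, ttt_push=ttt_push),
        experiment=ExperimentConfig(),
        holidays=_default_holidays(origin),
    )
    return cfg.validate()
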