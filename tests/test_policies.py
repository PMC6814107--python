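"""Pull/push booking rules, first-fraction timing, rebooks."""

import numpy as np
import pytest

import rtflowsim as rfs
from rtflowsim.casemix import Patient
from rtflowsim.config import ConfigError
from rtflowsim.des import MINUTES_PER_DAY
from rtflowsim import policies
from tests.conftest import make_micro_config


def _pull_patient(cfg, site="brain", urgency="regular", arrival_day=0,
                  delay_weeks=0):
    p = Patient(id=0, arrival_time=arrival_day * MINUTES_PER_DAY + 600,
                tumor_site=site, urgency=urgency, strategy="pull")
    p.planned_delay_weeks = delay_weeks
    p.care_plan = cfg.plans_for_site(site)[0].id
    return p


class TestTTTDistributions:
    def test_supports_match_printed_bounds(self, default_cfg):
        pol = default_cfg.policies
        assert set(pol.ttt_pull["acute"][0]) <= {0, 1}
        assert set(pol.ttt_pull["subacute"][0]) <= set(range(1, 9))
        assert set(pol.ttt_pull["regular"][0]) <= set(range(3, 22))
        for wd in range(5):
            assert set(pol.ttt_push[wd]) <= set(range(1, 8))

    def test_weekday_conditioning_renormalizes(self, default_cfg):
        # Monday-start plans consulted on Tuesday: admissible offsets from
        # the regular 3-21 support are 6, 13, 20
        dist = policies.ttt_distribution(default_cfg, "regular", 1,
                                         start_weekday=0, arrival_weekday=1)
        assert set(dist) == {6, 13, 20}
        assert sum(dist.values()) == pytest.approx(1.0)
        ranked = sorted(dist, key=dist.get, reverse=True)
        assert ranked[:2] == [6, 13]  # most likely 6 or 13 days

    def test_empty_conditioned_distribution_errors(self, default_cfg):
        with pytest.raises(ConfigError):
            policies.ttt_distribution(default_cfg, "acute", 2, start_weekday=0,
                                      arrival_weekday=2)


class TestSchedulePull:
    def test_point_mass_gives_arrival_plus_seven(self):
        cfg = make_micro_config(strategy_push=False, ttt_day=7)
        p = _pull_patient(cfg, arrival_day=0)
        start = policies.schedule_start_pull(
            p, cfg.plan_by_id(p.care_plan), cfg, np.random.default_rng(0))
        assert start == 7

    def test_acute_ttt_within_printed_range(self, default_cfg):
        rng = np.random.default_rng(4)
        for day in range(4):  # Mon-Thu arrivals (no weekend roll)
            for _ in range(50):
                p = _pull_patient(default_cfg, site="bone_metastasis",
                                  urgency="acute", arrival_day=day)
                start = policies.schedule_start_pull(
                    p, default_cfg.plan_by_id(p.care_plan), default_cfg, rng)
                assert 0 <= start - p.arrival_day() <= 1

    def test_head_and_neck_starts_on_monday(self, default_cfg):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = _pull_patient(default_cfg, site="head_and_neck",
                              urgency="regular", arrival_day=1)  # Tuesday
            start = policies.schedule_start_pull(
                p, default_cfg.plans_for_site("head_and_neck")[0],
                default_cfg, rng)
            assert start % 7 == 0
            assert start - p.arrival_day() in (6, 13, 20)

    def test_planned_delay_shifts_the_start(self):
        cfg = make_micro_config(strategy_push=False, ttt_day=7)
        p = _pull_patient(cfg, arrival_day=0, delay_weeks=2)
        start = policies.schedule_start_pull(
            p, cfg.plan_by_id(p.care_plan), cfg, np.random.default_rng(0))
        assert start == 14 + 7


class TestSchedulePush:
    def test_gap_support_one_to_seven(self, default_cfg):
        rng = np.random.default_rng(8)
        gaps = []
        for day in range(5):
            for _ in range(200):
                p = Patient(id=0, arrival_time=0, tumor_site="brain",
                            urgency="regular", strategy="push")
                p.care_plan = default_cfg.plans_for_site("brain")[0].id
                start = policies.schedule_start_push(
                    p, default_cfg.plan_by_id(p.care_plan), default_cfg, rng,
                    planning_start_time=day * MINUTES_PER_DAY + 600)
                gaps.append(start - day)
        # raw draws are 1..7 days; weekend/holiday rolls can extend to 9
        assert min(gaps) >= 1 and max(gaps) <= 9

    def test_wrong_strategy_rejected(self, default_cfg):
        p = _pull_patient(default_cfg)
        with pytest.raises(ConfigError):
            policies.schedule_start_push(
                p, default_cfg.plan_by_id(p.care_plan), default_cfg,
                np.random.default_rng(0), 0)


class TestRebook:
    def test_finished_plan_never_rebooks(self, default_cfg):
        p = _pull_patient(default_cfg)
        p.scheduled_start_day = 4
        p.plan_done_time = 2 * MINUTES_PER_DAY
        out = policies.check_and_rebook(
            p, default_cfg.plan_by_id(p.care_plan), default_cfg,
            3 * MINUTES_PER_DAY + 1050)
        assert out is None and p.rebook_count == 0

    def test_unfinished_plan_moves_to_next_workday(self, default_cfg):
        p = _pull_patient(default_cfg, site="brain")
        p.scheduled_start_day = 4  # Friday
        out = policies.check_and_rebook(
            p, default_cfg.plan_by_id(p.care_plan), default_cfg,
            3 * MINUTES_PER_DAY + 1050)
        assert out == 7  # next Monday (weekend skipped)
        assert p.rebook_count == 1
        assert p.rebook_history == [(4, 7, 3 * MINUTES_PER_DAY + 1050)]

    def test_head_and_neck_rebooks_to_next_monday(self, default_cfg):
        p = _pull_patient(default_cfg, site="head_and_neck")
        p.scheduled_start_day = 7  # a Monday
        out = policies.check_and_rebook(
            p, default_cfg.plans_for_site("head_and_neck")[0], default_cfg,
            6 * MINUTES_PER_DAY + 1050)
        assert out == 14  # the following Monday


class TestPullPolicy:
    def test_all_sites_promoted_means_everyone_pull(self, default_cfg,
                                                    population_100k):
        cfg = default_cfg.copy()
        cfg.policies.pull_promoted_sites = list(cfg.site_complexity_order)
        assert all(policies.pull_policy(p, cfg) == "pull"
                   for p in population_100k[:10000])

    def test_unknown_site_rejected(self, default_cfg):
        cfg = default_cfg.copy()
        cfg.policies.pull_promoted_sites = ["kidney"]
        p = Patient(id=0, tumor_site="breast", urgency="regular")
        with pytest.raises(ConfigError):
            policies.pull_policy(p, cfg)

    def test_promoting_breast_adds_its_noncombined_regulars(self, default_cfg,
                                                            population_100k):
        # arithmetic oracle from the configured shares
        cfg = default_cfg.copy()
        cfg.policies.pull_promoted_sites = ["breast"]
        pop = population_100k
        n = len(pop)
        base = sum(1 for p in pop if policies.pull_policy(p, default_cfg) == "pull")
        promoted = sum(1 for p in pop if policies.pull_policy(p, cfg) == "pull")
        extra = sum(
            1 for p in pop
            if p.tumor_site == "breast" and p.urgency == "regular"
            and not p.combined_modality
        )
        assert promoted - base == extra


class TestBookImaging:
    def test_ct_only_patient_gets_first_admissible_slot(self):
        from rtflowsim.resources import build_slot_calendars

        cfg = make_micro_config()
        cals = build_slot_calendars(cfg.resources, set())
        p = _pull_patient(cfg, arrival_day=0)
        p.strategy = "push"
        appts = policies.book_imaging(p, cals, cfg, now=p.arrival_time)
        assert set(appts) == {"CT"}
        assert appts["CT"].start >= p.arrival_time

    def test_planned_delay_defers_ct(self):
        from rtflowsim.resources import build_slot_calendars

        cfg = make_micro_config()
        cals = build_slot_calendars(cfg.resources, set())
        p = _pull_patient(cfg, arrival_day=0, delay_weeks=2)
        p.strategy = "push"
        appts = policies.book_imaging(p, cals, cfg, now=p.arrival_time)
        assert appts["CT"].day >= 14

    def test_mri_follows_ct(self):
        from rtflowsim.resources import build_slot_calendars

        cfg = make_micro_config(needs={"mri": True})
        cals = build_slot_calendars(cfg.resources, set())
        p = _pull_patient(cfg, arrival_day=0)
        p.strategy = "push"
        p.needs_mri = True
        appts = policies.book_imaging(p, cals, cfg, now=p.arrival_time)
        assert appts["MRI"].start >= appts["CT"].end


class TestRedrawRebookRule:
    def test_redraw_lands_in_the_ttt_tail(self, default_cfg):
        cfg = default_cfg.copy()
        cfg.policies.rebook_rule = "redraw"
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = _pull_patient(cfg, site="brain", urgency="regular",
                              arrival_day=0)
            p.scheduled_start_day = 5
            new = policies.check_and_rebook(
                p, cfg.plan_by_id(p.care_plan), cfg,
                4 * MINUTES_PER_DAY + 1050, rng=rng)
            assert new > 5
            assert new % 7 < 5  # never a weekend
            assert p.rebook_count == 1

    def test_without_rng_falls_back_to_next_admissible(self, default_cfg):
        cfg = default_cfg.copy()
        cfg.policies.rebook_rule = "redraw"
        p = _pull_patient(cfg, site="brain", urgency="regular")
        p.scheduled_start_day = 4  # Friday
        new = policies.check_and_rebook(
            p, cfg.plan_by_id(p.care_plan), cfg, 3 * MINUTES_PER_DAY + 1050)
        assert new == 7
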