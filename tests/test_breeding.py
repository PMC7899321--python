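"""The IBM core: schedules, daily fates, re-nesting, annual summaries."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from renestsim import (
    FemaleInit,
    SpeciesParams,
    build_schedule,
    clutch_size,
    draw_female_init,
    draw_season_start,
    fledge_count,
    renest_prob,
    simulate_female,
    simulate_nest,
    simulate_year,
    survive_to_independence,
)
from conftest import make_water_year


def no_mortality(**overrides) -> SpeciesParams:
    base = dict(dsr_egg=1.0, dsr_nestling=1.0, parasitism_prob=0.0, egg_to_fledgling_prob=1.0)
    base.update(overrides)
    return dataclasses.replace(SpeciesParams(), **base)


class TestInitialDraws:
    def test_zero_sd_degenerates_to_the_means(self, site, rng):
        p = dataclasses.replace(SpeciesParams(), season_mean_first_egg_sd=0.0, female_offset_sd=0.0)
        s = dataclasses.replace(site, ground_elev_sd=0.0, nest_height_sd=0.0)
        assert draw_season_start(p, rng) == 158
        init = draw_female_init(158, s, p, rng)
        assert (init.first_egg_doy, init.ground_elev, init.nest_height) == (158, 438.5, 2.1)

    def test_season_start_moments_and_range(self, params):
        # oracle: closed-form truncated-normal mean (the +3/-5 day bounds
        # are asymmetric, so the mean sits slightly above 158)
        from scipy.stats import truncnorm

        mu, sd = params.season_mean_first_egg_mu, params.season_mean_first_egg_sd
        lo, hi = params.season_mean_first_egg_range
        expected = truncnorm.mean((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)
        rng = np.random.default_rng(7)
        draws = np.array([draw_season_start(params, rng) for _ in range(10_000)])
        assert draws.min() >= 155 and draws.max() <= 163
        assert abs(draws.mean() - expected) < 0.1

    def test_female_draws_respect_truncation_ranges(self, params, site):
        # oracle: closed-form truncated-normal mean for nest height (the
        # 0.3-6.0 m bounds are asymmetric around 2.1 m)
        from scipy.stats import truncnorm

        mu, sd = site.nest_height_mu, site.nest_height_sd
        lo, hi = site.nest_height_range
        expected = truncnorm.mean((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)
        rng = np.random.default_rng(8)
        inits = [draw_female_init(158, site, params, rng) for _ in range(5_000)]
        elev = np.array([i.ground_elev for i in inits])
        height = np.array([i.nest_height for i in inits])
        assert elev.min() >= 435.6 and elev.max() <= 441.7
        assert height.min() >= 0.3 and height.max() <= 6.0
        assert abs(height.mean() - expected) < 0.05

    def test_same_seed_identical_draws(self, params, site):
        a = draw_female_init(158, site, params, np.random.default_rng(5))
        b = draw_female_init(158, site, params, np.random.default_rng(5))
        assert a == b


class TestClutchAndSchedule:
    @pytest.mark.parametrize("doy, expected", [(158, 4), (138, 5), (191, 3), (120, 6), (220, 2)])
    def test_clutch_declines_with_date_and_clamps(self, doy, expected, params):
        assert clutch_size(doy, params) == expected

    def test_four_egg_schedule_fledges_on_day_23(self):
        sched = build_schedule(158, 4)
        assert sched.hatch_doy == 171
        assert sched.fledge_doy == 180

    def test_five_egg_schedule_dates(self):
        sched = build_schedule(158, 5)
        assert (sched.last_egg_doy, sched.parasitism_check_doy) == (162, 161)
        assert (sched.hatch_doy, sched.fledge_doy) == (172, 181)

    @given(st.integers(min_value=130, max_value=200), st.integers(min_value=2, max_value=6))
    @settings(derandomize=True, max_examples=30)
    def test_fledge_offset_identity(self, first_egg, cs):
        sched = build_schedule(first_egg, cs)
        assert sched.fledge_doy - sched.first_egg_doy == cs + 18
        assert sched.hatch_doy < sched.fledge_doy


class TestRenestProb:
    @pytest.mark.parametrize(
        "doy, outcome, expected",
        [(160, "fail", 0.905), (180, "fail", 0.129), (160, "success", 0.637)],
    )
    def test_logistic_values(self, doy, outcome, expected, params):
        assert renest_prob(doy, outcome, params) == pytest.approx(expected, abs=2e-3)

    def test_declines_through_the_season(self, params):
        probs = [renest_prob(d, "fail", params) for d in range(140, 220, 5)]
        assert all(a > b for a, b in zip(probs, probs[1:]))


class TestSimulateNest:
    def test_no_mortality_sources_always_fledges(self, dry_year, rng):
        p = no_mortality()
        for _ in range(20):
            init = FemaleInit(158, 438.5, 2.1)
            out = simulate_nest(init, build_schedule(158, 4, p), dry_year, p, rng)
            assert out.fate == "fledged" and out.n_fledged == 4

    def test_water_above_nest_floods_immediately(self, rng):
        wy = make_water_year(439.0)
        init = FemaleInit(158, 436.0, 1.0)  # nest at 437 m, water at 439 m
        out = simulate_nest(init, build_schedule(158, 4), wy, SpeciesParams(), rng)
        assert out.fate == "flooded"
        assert out.end_doy == 159
        assert out.n_fledged == 0

    def test_nest_success_matches_daily_survival_product(self, dry_year, params):
        # closed-form oracle: dsr_egg^(cs+9) * dsr_nestling^9 with cs = 4
        p = dataclasses.replace(params, parasitism_prob=0.0)
        rng = np.random.default_rng(99)
        n = 20_000
        init = FemaleInit(158, 438.5, 2.1)
        sched = build_schedule(158, 4, p)
        fledged = sum(simulate_nest(init, sched, dry_year, p, rng).fate == "fledged" for _ in range(n))
        expected = p.dsr_egg ** 13 * p.dsr_nestling ** 9
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(fledged / n - expected) < 3 * se

    def test_parasitized_nest_loses_one_egg(self, dry_year, rng):
        p = no_mortality(parasitism_prob=1.0, abandon_prob_if_parasitized=0.0)
        out = simulate_nest(FemaleInit(158, 438.5, 2.1), build_schedule(158, 4, p), dry_year, p, rng)
        assert out.parasitized and out.fate == "fledged" and out.n_fledged == 3

    def test_certain_abandonment_ends_on_check_day(self, dry_year, rng):
        p = no_mortality(parasitism_prob=1.0, abandon_prob_if_parasitized=1.0)
        sched = build_schedule(158, 4, p)
        out = simulate_nest(FemaleInit(158, 438.5, 2.1), sched, dry_year, p, rng)
        assert out.fate == "abandoned"
        assert out.end_doy == sched.parasitism_check_doy == 160


class TestFledgeAndIndependence:
    def test_certain_fledging(self, rng):
        p = dataclasses.replace(SpeciesParams(), egg_to_fledgling_prob=1.0)
        assert fledge_count(4, False, p, rng) == 4
        assert fledge_count(4, True, p, rng) == 3

    def test_binomial_mean(self, params):
        rng = np.random.default_rng(11)
        draws = [fledge_count(4, False, params, rng) for _ in range(50_000)]
        assert np.mean(draws) == pytest.approx(4 * 0.83, abs=0.02)

    def test_empty_brood_survives_nobody(self, dry_year, params, rng):
        assert survive_to_independence(0, 180, 438.5, dry_year, params, rng) == (0, False)

    @pytest.mark.parametrize("level, expected_p, inundated", [(425.0, 0.729, False), (439.0, 0.214, True)])
    def test_survival_depends_on_inundation(self, level, expected_p, inundated, params):
        wy = make_water_year(level)
        rng = np.random.default_rng(13)
        out = [survive_to_independence(4, 180, 438.5, wy, params, rng) for _ in range(30_000)]
        assert all(flag == inundated for _, flag in out)
        assert np.mean([n for n, _ in out]) == pytest.approx(4 * expected_p, abs=0.03)


class TestSimulateFemale:
    def test_no_renesting_when_probability_is_zero(self, dry_year, site, rng):
        p = dataclasses.replace(SpeciesParams(), renest_fail_intercept=-50.0, renest_success_intercept=-50.0)
        for _ in range(20):
            season = simulate_female(158, dry_year, site, p, rng)
            assert len(season.attempts) == 1

    @staticmethod
    def _low_site(site):
        # pin every nest to 436.0 m so constant 437 m water floods it day one
        return dataclasses.replace(
            site, ground_elev_mu=435.7, ground_elev_sd=0.0, nest_height_mu=0.3, nest_height_sd=0.0
        )

    def test_attempt_cap_under_certain_renesting(self, site, rng):
        # water over every nest: each attempt floods on day one, renest prob ~1
        wy = make_water_year(437.0)
        p = dataclasses.replace(SpeciesParams(), renest_fail_intercept=80.0)
        for _ in range(20):
            season = simulate_female(150, wy, self._low_site(site), p, rng)
            assert len(season.attempts) == p.max_attempts == 3
            assert all(a.fate == "flooded" for a in season.attempts)

    def test_failure_delay_is_six_days(self, site, rng):
        wy = make_water_year(437.0)  # deterministic day-one flooding of low nests
        p = dataclasses.replace(SpeciesParams(), renest_fail_intercept=80.0, female_offset_sd=0.0)
        season = simulate_female(164, wy, self._low_site(site), p, rng)
        first, second = season.attempts[0], season.attempts[1]
        assert first.end_doy == 165
        assert second.schedule.first_egg_doy == 171

    def test_conservation_of_young(self, dry_year, site, params):
        rng = np.random.default_rng(21)
        for _ in range(200):
            season = simulate_female(158, dry_year, site, params, rng)
            assert season.total_independent <= season.total_fledged
            assert season.total_fledged <= sum(a.schedule.clutch_size for a in season.attempts)


class TestSimulateYear:
    def test_reports_the_requested_female_count(self, dry_year, site, params, rng):
        assert simulate_year(dry_year, site, params, rng).n_females == 35

    def test_total_mortality_means_zero_everything(self, dry_year, site, rng):
        p = dataclasses.replace(SpeciesParams(), dsr_egg=0.0, dsr_nestling=0.0)
        out = simulate_year(dry_year, site, p, rng)
        assert out.breeding_success == 0.0 and out.productivity == 0.0

    def test_productivity_never_exceeds_fledging_success(self, dry_year, site, params):
        rng = np.random.default_rng(31)
        for _ in range(20):
            out = simulate_year(dry_year, site, params, rng)
            assert out.productivity <= out.fledging_success

    def test_dry_year_has_no_flooding_or_inundation(self, site, params, rng):
        # nest sites start at 435.6 m; a year below that cannot flood anything
        wy = make_water_year(435.5)
        out = simulate_year(wy, site, params, rng)
        assert out.n_flooded_nests == 0 and out.n_inundated_broods == 0

    def test_bit_identical_reruns_under_a_fixed_seed(self, dry_year, site, params):
        a = simulate_year(dry_year, site, params, np.random.default_rng(77))
        b = simulate_year(dry_year, site, params, np.random.default_rng(77))
        assert a == b

    def test_higher_egg_survival_raises_expected_fledging(self, dry_year, site):
        lo = dataclasses.replace(SpeciesParams(), dsr_egg=0.95)
        hi = SpeciesParams()
        mean_lo = np.mean(
            [simulate_year(dry_year, site, lo, np.random.default_rng(1000 + i)).fledging_success for i in range(120)]
        )
        mean_hi = np.mean(
            [simulate_year(dry_year, site, hi, np.random.default_rng(1000 + i)).fledging_success for i in range(120)]
        )
        assert mean_hi > mean_lo
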