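"""The individual-based re-nesting model: nests, female-seasons, years.

One simulated year follows 35 females against a single water year.  Each
female lays a first clutch on a date drawn around the annual mean, at a
nest site with a drawn ground elevation and nest height.  Clutch size
declines with date (CS = 9.60 - 0.033*DOY, clamped to 2-6 eggs; a 4-egg
nest spans a 23-day cycle: laying, 11 d incubation from the penultimate
egg, 9 d nestlings).  Each day after initiation the nest can flood (water
level >= ground + nest height), be parasitized by a cowbird on the day
before the last egg (and possibly abandoned), or fail from other causes at
the stage-specific daily survival rate.  Surviving nests fledge a binomial
number of young; fledglings survive the 21-day dependence period with a
probability set by whether the territory (ground elevation) is inundated.
Females may re-nest after failure or success — probability logit-linear in
the end date — up to three attempts.

Daily stochastic fates are realised by sampling the failure day of each
stage directly from the geometric distribution, which is identical in
distribution to a day-by-day Bernoulli loop; within a day, events resolve
in the order flooding -> parasitism/abandonment -> background survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import SiteParams, SpeciesParams
from .sampling import geometric_failure_day, truncnorm_draw
from .water import WaterYear

#: first-egg dates are kept inside this DOY window by rejection
FIRST_EGG_WINDOW = (120, 220)

FATES = ("abandoned", "flooded", "depredated_or_other", "fledged")


@dataclass(frozen=True)
class FemaleInit:
    """A female's draw for one nesting attempt: date and nest site."""

    first_egg_doy: int
    ground_elev: float  # m a.s.l.
    nest_height: float  # m above ground

    @property
    def nest_elev(self) -> float:
        return self.ground_elev + self.nest_height


@dataclass(frozen=True)
class NestSchedule:
    """Key dates of one nesting attempt (all DOY, eggs laid daily)."""

    first_egg_doy: int
    clutch_size: int
    last_egg_doy: int
    parasitism_check_doy: int
    hatch_doy: int
    fledge_doy: int


@dataclass(frozen=True)
class NestAttempt:
    """Outcome of one nesting attempt."""

    schedule: NestSchedule
    parasitized: bool
    fate: str
    end_doy: int
    n_fledged: int
    nest_elev: float
    # post-fledging bookkeeping (0 / False unless the nest fledged)
    n_independent: int = 0
    brood_inundated: bool = False


@dataclass(frozen=True)
class FemaleSeason:
    """One female's season: up to max_attempts nesting attempts."""

    attempts: tuple[NestAttempt, ...]
    total_fledged: int
    total_independent: int


@dataclass(frozen=True)
class AnnualSummary:
    """Per-year summaries over females and nests."""

    nest_success: float  # proportion of initiated nests fledging >= 1 young
    breeding_success: float  # proportion of females with total_fledged > 0
    fledging_success: float  # mean fledglings per female
    productivity: float  # mean independent young per female
    n_females: int
    n_nests: int
    n_flooded_nests: int = 0
    n_inundated_broods: int = 0
    n_fledged_broods: int = 0


# ---------------------------------------------------------------------------
# elementary draws


def draw_season_start(params: SpeciesParams, rng: np.random.Generator) -> int:
    """Annual mean first-egg date: truncated-normal, rounded to integer DOY."""
    lo, hi = params.season_mean_first_egg_range
    x = truncnorm_draw(rng, params.season_mean_first_egg_mu, params.season_mean_first_egg_sd, lo, hi)
    return int(round(min(hi, max(lo, x))))


def draw_female_init(
    season_start: int,
    site: SiteParams,
    params: SpeciesParams,
    rng: np.random.Generator,
) -> FemaleInit:
    """Draw a female's first-egg date, nest ground elevation and nest height.

    The date is the season mean plus a truncated-normal individual offset;
    draws landing outside the plausible laying window are rejected.
    """
    lo, hi = params.female_offset_range
    for _ in range(10_000):
        offset = truncnorm_draw(rng, 0.0, params.female_offset_sd, lo, hi)
        first_egg = season_start + int(round(offset))
        if FIRST_EGG_WINDOW[0] <= first_egg <= FIRST_EGG_WINDOW[1]:
            break
    else:  # pragma: no cover - defensive
        raise RuntimeError("could not draw a first-egg date inside the season window")
    ground = truncnorm_draw(rng, site.ground_elev_mu, site.ground_elev_sd, *site.ground_elev_range)
    height = truncnorm_draw(rng, site.nest_height_mu, site.nest_height_sd, *site.nest_height_range)
    return FemaleInit(first_egg_doy=first_egg, ground_elev=ground, nest_height=height)


def clutch_size(doy: int, params: SpeciesParams) -> int:
    """Deterministic date-dependent clutch size, rounded then clamped to 2-6."""
    cs = math.floor(params.clutch_intercept + params.clutch_slope * doy + 0.5)
    lo, hi = params.clutch_range
    return int(min(hi, max(lo, cs)))


def build_schedule(first_egg_doy: int, cs: int, params: SpeciesParams | None = None) -> NestSchedule:
    """Lay out the nest cycle: one egg per day, incubation, nestling period.

    With the default 11-day incubation (starting on the penultimate egg)
    and 9-day nestling period, a 4-egg clutch begun on day 1 hatches on
    day 14 and fledges on day 23, i.e. fledge = first egg + CS + 18.
    """
    p = params or SpeciesParams()
    last_egg = first_egg_doy + cs - 1
    hatch = first_egg_doy + cs + p.incubation_days - 2
    fledge = first_egg_doy + cs + p.days_to_fledge_offset
    return NestSchedule(
        first_egg_doy=first_egg_doy,
        clutch_size=cs,
        last_egg_doy=last_egg,
        parasitism_check_doy=last_egg - 1,
        hatch_doy=hatch,
        fledge_doy=fledge,
    )


def renest_prob(doy: int, outcome: str, params: SpeciesParams) -> float:
    """Probability of re-nesting given the DOY the previous attempt ended."""
    if outcome == "fail":
        z = params.renest_fail_intercept + params.renest_fail_slope * doy
    elif outcome == "success":
        z = params.renest_success_intercept + params.renest_success_slope * doy
    else:
        raise ValueError(f"outcome must be 'fail' or 'success', got {outcome!r}")
    return 1.0 / (1.0 + math.exp(-z))


def fledge_count(cs: int, parasitized: bool, params: SpeciesParams, rng: np.random.Generator) -> int:
    """Fledglings from a surviving nest: binomial thinning of the clutch.

    Parasitism removes one host egg; each remaining egg independently
    becomes a fledgling with the combined hatch/nestling survival
    probability.
    """
    effective = cs - (params.parasitism_clutch_reduction if parasitized else 0)
    effective = max(effective, 0)
    return int(rng.binomial(effective, params.egg_to_fledgling_prob))


# ---------------------------------------------------------------------------
# nest, female, year


def simulate_nest(
    init: FemaleInit,
    sched: NestSchedule,
    wy: WaterYear,
    params: SpeciesParams,
    rng: np.random.Generator,
) -> NestAttempt:
    """Run one nesting attempt day by day against a water year.

    Daily fates are evaluated from the day after the first egg through the
    fledge day: flooding first (water >= ground + nest height), then the
    one-off parasitism/abandonment check on the day before the last egg,
    then stage-specific background survival (egg rate through the hatch
    day, nestling rate after).
    """
    fe = sched.first_egg_doy
    if fe < wy.doy_start or sched.fledge_doy > wy.doy_end:
        raise ValueError(
            f"nest schedule [{fe}, {sched.fledge_doy}] outside water-year range "
            f"[{wy.doy_start}, {wy.doy_end}]"
        )
    nest_elev = init.nest_elev

    # deterministic hazard: first day (after initiation) the water reaches the nest
    seg = wy.levels[fe + 1 - wy.doy_start : sched.fledge_doy + 1 - wy.doy_start]
    wet = seg >= nest_elev
    flood_day: float = math.inf
    if wet.any():
        flood_day = fe + 1 + int(np.argmax(wet))

    # background survival: failure day of each stage, sampled geometrically
    n_egg_days = sched.hatch_doy - fe  # days fe+1 .. hatch (egg rate)
    t_egg = geometric_failure_day(rng, params.dsr_egg)
    surv_fail_day: float = math.inf
    if t_egg <= n_egg_days:
        surv_fail_day = fe + t_egg
    else:
        t_nestling = geometric_failure_day(rng, params.dsr_nestling)
        if t_nestling <= sched.fledge_doy - sched.hatch_doy:
            surv_fail_day = sched.hatch_doy + t_nestling

    # one-off parasitism check, evaluated only if the nest is still alive
    # when the check day's parasitism step runs (floods resolve first,
    # background survival after)
    pc = sched.parasitism_check_doy
    parasitized = False
    abandon_day: float = math.inf
    if flood_day > pc and surv_fail_day >= pc:
        if rng.random() < params.parasitism_prob:
            parasitized = True
            if rng.random() < params.abandon_prob_if_parasitized:
                abandon_day = pc

    # earliest event wins; ties resolve by the within-day order
    events = [
        (flood_day, 0, "flooded"),
        (abandon_day, 1, "abandoned"),
        (surv_fail_day, 2, "depredated_or_other"),
    ]
    day, _, fate = min(events)
    if math.isinf(day):
        n = fledge_count(sched.clutch_size, parasitized, params, rng)
        return NestAttempt(sched, parasitized, "fledged", sched.fledge_doy, n, nest_elev)
    return NestAttempt(sched, parasitized, fate, int(day), 0, nest_elev)


def survive_to_independence(
    n_fledged: int,
    fledge_doy: int,
    ground_elev: float,
    wy: WaterYear,
    params: SpeciesParams,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    """Fledglings surviving the dependence period, and the inundation flag.

    The territory counts as inundated if the water level reaches the nest
    ground elevation at any point in the 21-day window after fledging.
    """
    if n_fledged <= 0:
        return 0, False
    end = min(fledge_doy + params.independence_days, wy.doy_end)
    inundated = wy.max_between(fledge_doy, end) >= ground_elev
    p = params.postfledge_survival_wet if inundated else params.postfledge_survival_dry
    return int(rng.binomial(n_fledged, p)), inundated


def simulate_female(
    season_start: int,
    wy: WaterYear,
    site: SiteParams,
    params: SpeciesParams,
    rng: np.random.Generator,
) -> FemaleSeason:
    """Simulate one female's season: up to ``max_attempts`` nesting attempts.

    After an attempt ending on day E the female re-nests with probability
    ``renest_prob(E, outcome)``; the next first egg follows 6 days after a
    failure (including abandonment and flooding) or 7 days after fledging,
    at a freshly drawn nest site.
    """
    attempts: list[NestAttempt] = []
    total_fledged = 0
    total_independent = 0
    init = draw_female_init(season_start, site, params, rng)
    first_egg = init.first_egg_doy

    for attempt_no in range(1, params.max_attempts + 1):
        if attempt_no > 1:
            ground = truncnorm_draw(rng, site.ground_elev_mu, site.ground_elev_sd, *site.ground_elev_range)
            height = truncnorm_draw(rng, site.nest_height_mu, site.nest_height_sd, *site.nest_height_range)
            init = FemaleInit(first_egg_doy=first_egg, ground_elev=ground, nest_height=height)
        cs = clutch_size(first_egg, params)
        sched = build_schedule(first_egg, cs, params)
        attempt = simulate_nest(init, sched, wy, params, rng)

        if attempt.fate == "fledged" and attempt.n_fledged > 0:
            n_ind, inundated = survive_to_independence(
                attempt.n_fledged, attempt.end_doy, init.ground_elev, wy, params, rng
            )
            attempt = NestAttempt(
                attempt.schedule,
                attempt.parasitized,
                attempt.fate,
                attempt.end_doy,
                attempt.n_fledged,
                attempt.nest_elev,
                n_independent=n_ind,
                brood_inundated=inundated,
            )
        attempts.append(attempt)
        total_fledged += attempt.n_fledged
        total_independent += attempt.n_independent

        if attempt_no == params.max_attempts:
            break
        outcome = "success" if attempt.fate == "fledged" else "fail"
        if rng.random() >= renest_prob(attempt.end_doy, outcome, params):
            break
        delay = params.renest_delay_success if outcome == "success" else params.renest_delay_fail
        first_egg = attempt.end_doy + delay
        if first_egg > FIRST_EGG_WINDOW[1]:
            break

    return FemaleSeason(tuple(attempts), total_fledged, total_independent)


def summarize_year(seasons: list[FemaleSeason]) -> AnnualSummary:
    """Aggregate female-seasons into the annual summary statistics."""
    n_females = len(seasons)
    all_attempts = [a for s in seasons for a in s.attempts]
    n_nests = len(all_attempts)
    n_success = sum(1 for a in all_attempts if a.fate == "fledged" and a.n_fledged >= 1)
    n_flooded = sum(1 for a in all_attempts if a.fate == "flooded")
    fledged_broods = [a for a in all_attempts if a.fate == "fledged" and a.n_fledged > 0]
    return AnnualSummary(
        nest_success=n_success / n_nests if n_nests else 0.0,
        breeding_success=sum(1 for s in seasons if s.total_fledged > 0) / n_females,
        fledging_success=sum(s.total_fledged for s in seasons) / n_females,
        productivity=sum(s.total_independent for s in seasons) / n_females,
        n_females=n_females,
        n_nests=n_nests,
        n_flooded_nests=n_flooded,
        n_inundated_broods=sum(1 for a in fledged_broods if a.brood_inundated),
        n_fledged_broods=len(fledged_broods),
    )


def simulate_year(
    wy: WaterYear,
    site: SiteParams,
    params: SpeciesParams,
    rng: np.random.Generator,
) -> AnnualSummary:
    """Simulate one breeding year: a shared season start, then each female."""
    season_start = draw_season_start(params, rng)
    seasons = [simulate_female(season_start, wy, site, params, rng) for _ in range(params.n_females)]
    return summarize_year(seasons)
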