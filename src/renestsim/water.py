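"""Daily reservoir water-level trajectories and management scenarios.

A :class:`WaterYear` is one breeding season of daily water-surface
elevations (m a.s.l.) for a storage reservoir that fluctuates between a
low of 419.65 m and full pool at 440.1 m.  The biology downstream cares
about when (and whether) the level crosses 435 m — the lowest elevation at
which willow shrubs, and hence nests, occur — so the synthetic generator
models the above-435 segment carefully (fill date, rise rate, peak) and
keeps the sub-435 base schematic.

Four management scenarios are supported:

``long_term``
    draw years mimicking the full historical record (7/50 never reach
    435 m; pooled median fill date DOY 163);
``early_fill``
    years reaching 435 m by June 12 (median fill DOY 158);
``late_fill``
    years filling after June 12 or never (7/28 never; median fill DOY 172
    among filling years);
``zero_flooding``
    levels never exceed 435 m.

All dates use the non-leap day-of-year convention (Jan 1 = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sampling import truncnorm_draw

log = logging.getLogger(__name__)

SCENARIO_KINDS = ("long_term", "early_fill", "late_fill", "zero_flooding")

#: reservoir operating bounds, m a.s.l.
LEVEL_MIN = 419.65
LEVEL_MAX = 440.1
#: elevation whose first crossing defines the fill date
FILL_THRESHOLD = 435.0
#: inclusive early/late boundary: "filled by June 12" (non-leap DOY 163)
EARLY_FILL_DOY = 163


class WaterError(ValueError):
    """Raised for malformed water-level inputs."""


@dataclass(frozen=True)
class WaterYear:
    """Daily water-surface elevations for one season (DOY 91-273 by default)."""

    year_id: str
    levels: np.ndarray  # one value per day, m a.s.l.
    doy_start: int = 91
    source: str = "synthetic"  # or "observed"

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "levels", levels)
        if levels.ndim != 1 or levels.size < 2:
            raise WaterError(f"year {self.year_id}: levels must be a 1-D daily series")
        if np.isnan(levels).any():
            raise WaterError(f"year {self.year_id}: missing days inside the index range")
        if levels.min() < LEVEL_MIN - 1e-9 or levels.max() > LEVEL_MAX + 1e-9:
            raise WaterError(
                f"year {self.year_id}: levels outside reservoir bounds "
                f"[{LEVEL_MIN}, {LEVEL_MAX}]: [{levels.min():.2f}, {levels.max():.2f}]"
            )

    @property
    def doy_end(self) -> int:
        return self.doy_start + self.levels.size - 1

    def level(self, doy: int) -> float:
        """Water level on a single day; raises if outside the index range."""
        i = doy - self.doy_start
        if not 0 <= i < self.levels.size:
            raise WaterError(f"year {self.year_id}: no water level for DOY {doy}")
        return float(self.levels[i])

    def max_between(self, doy_from: int, doy_to: int) -> float:
        """Maximum level over the inclusive window [doy_from, doy_to]."""
        i = doy_from - self.doy_start
        j = doy_to - self.doy_start
        if i < 0 or j >= self.levels.size or j < i:
            raise WaterError(
                f"year {self.year_id}: window [{doy_from}, {doy_to}] outside "
                f"[{self.doy_start}, {self.doy_end}]"
            )
        return float(self.levels[i : j + 1].max())


def fill_date(wy: WaterYear, threshold: float = FILL_THRESHOLD) -> Optional[int]:
    """First DOY on which the level reaches ``threshold``, or None if never."""
    above = wy.levels >= threshold
    if not above.any():
        return None
    return wy.doy_start + int(np.argmax(above))


def classify_year(wy: WaterYear) -> str:
    """``early_fill`` iff the year reaches 435 m by DOY 163, else ``late_fill``."""
    f = fill_date(wy)
    return "early_fill" if f is not None and f <= EARLY_FILL_DOY else "late_fill"


# ---------------------------------------------------------------------------
# synthetic hydrographs


@dataclass(frozen=True)
class HydroParams:
    """Free parameters of the synthetic hydrograph generator.

    Fill-date distributions are pre-truncation Normal(mu, sd) re-centred so
    the *truncated* medians reproduce the historical statistics (early
    median DOY 158, all <= 163; late median DOY 172, all >= 164; pooled
    median 163 with 7/50 no-fill years).  Peak levels are derived, not
    sampled: a rise rate (m/day) carries the trajectory from 435 m at the
    fill date to the peak day, so later fills peak lower; the rate and
    peak-day window are calibration constants (see docs/methods.md).
    """

    doy_start: int = 91
    doy_end: int = 273
    # fill-date components (DOY)
    fill_mu_early: float = 159.2
    fill_sd_early: float = 4.5
    fill_min_early: int = 130
    fill_mu_late: float = 170.4
    fill_sd_late: float = 7.0
    fill_max_late: int = 215
    # mixture weights
    p_nofill_long: float = 7.0 / 50.0
    p_early_given_fill_long: float = 22.0 / 43.0
    p_nofill_late: float = 7.0 / 28.0
    # peak timing ("peaks in July") and rise rate above 435 m
    peak_doy_range: tuple[int, int] = (186, 208)
    rise_rate_mu: float = 0.086
    rise_rate_sd: float = 0.022
    rise_rate_range: tuple[float, float] = (0.03, 0.15)
    min_rise_days: int = 5
    hold_days: int = 10
    fall_drop: float = 5.0
    # schematic sub-435 behaviour
    base_level_range: tuple[float, float] = (421.0, 428.0)
    nofill_peak_range: tuple[float, float] = (430.0, 434.9)


DEFAULT_HYDRO = HydroParams()


def _draw_fill_doy(rng: np.random.Generator, mu: float, sd: float, lo: int, hi: int) -> int:
    for _ in range(10_000):
        f = int(round(mu + sd * rng.standard_normal()))
        if lo <= f <= hi:
            return f
    raise RuntimeError("fill-date rejection sampling failed")  # pragma: no cover


def _sample_fill_doy(kind: str, rng: np.random.Generator, hp: HydroParams) -> Optional[int]:
    """Fill DOY for one synthetic year, or None for a no-fill year."""
    if kind == "zero_flooding":
        return None
    if kind == "early_fill":
        early = True
    elif kind == "late_fill":
        if rng.random() < hp.p_nofill_late:
            return None
        early = False
    elif kind == "long_term":
        if rng.random() < hp.p_nofill_long:
            return None
        early = rng.random() < hp.p_early_given_fill_long
    else:
        raise WaterError(f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}")
    if early:
        return _draw_fill_doy(rng, hp.fill_mu_early, hp.fill_sd_early, hp.fill_min_early, EARLY_FILL_DOY)
    return _draw_fill_doy(rng, hp.fill_mu_late, hp.fill_sd_late, EARLY_FILL_DOY + 1, hp.fill_max_late)


def synth_water_year(
    kind: str,
    rng: np.random.Generator,
    hydro_params: HydroParams = DEFAULT_HYDRO,
    year_id: str | None = None,
) -> WaterYear:
    """Generate one synthetic season of daily water levels for a scenario.

    The trajectory is piecewise linear: a schematic base, a rise crossing
    435 m exactly on the sampled fill date, a continued rise at the sampled
    rate to the peak day, a short hold, then a decline.  No-fill years rise
    to a sub-435 peak instead.
    """
    hp = hydro_params
    fill = _sample_fill_doy(kind, rng, hp)
    base = float(rng.uniform(*hp.base_level_range))
    peak_doy = int(rng.integers(hp.peak_doy_range[0], hp.peak_doy_range[1] + 1))

    if fill is None:
        peak_level = float(rng.uniform(*hp.nofill_peak_range))
        points = [(hp.doy_start, base), (peak_doy, peak_level)]
    else:
        peak_doy = max(peak_doy, fill + hp.min_rise_days)
        rate = truncnorm_draw(rng, hp.rise_rate_mu, hp.rise_rate_sd, *hp.rise_rate_range)
        peak_level = min(FILL_THRESHOLD + rate * (peak_doy - fill), LEVEL_MAX)
        points = [(hp.doy_start, base), (fill, FILL_THRESHOLD), (peak_doy, peak_level)]

    hold_end = min(peak_doy + hp.hold_days, hp.doy_end - 1)
    if hold_end > peak_doy:
        points.append((hold_end, peak_level))
    points.append((hp.doy_end, max(LEVEL_MIN, peak_level - hp.fall_drop)))

    xs, ys = zip(*points)
    doys = np.arange(hp.doy_start, hp.doy_end + 1)
    levels = np.interp(doys, xs, ys).clip(LEVEL_MIN, LEVEL_MAX)
    if fill is None:
        # schematic base can only approach, never touch, the threshold
        levels = np.minimum(levels, FILL_THRESHOLD - 0.1)
    if year_id is None:
        year_id = f"synthetic-{kind}"
    return WaterYear(year_id=year_id, levels=levels, doy_start=hp.doy_start, source="synthetic")


# ---------------------------------------------------------------------------
# scenario pools and sampling


@dataclass(frozen=True)
class HydroScenario:
    """A management scenario: a kind plus an optional observed-year pool.

    With a pool, years are drawn from it with replacement; without one,
    fresh synthetic years are generated.  The pool must satisfy the
    scenario definition (early years fill by DOY 163, late years after or
    never, zero-flooding years stay below 435 m).
    """

    kind: str
    year_pool: Optional[tuple[WaterYear, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise WaterError(f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}")
        if self.year_pool is not None:
            object.__setattr__(self, "year_pool", tuple(self.year_pool))
            for wy in self.year_pool:
                if self.kind == "zero_flooding" and wy.levels.max() >= FILL_THRESHOLD:
                    raise WaterError(f"year {wy.year_id} exceeds 435 m in a zero_flooding pool")
                if self.kind == "early_fill" and classify_year(wy) != "early_fill":
                    raise WaterError(f"year {wy.year_id} is not an early-fill year")
                if self.kind == "late_fill" and classify_year(wy) != "late_fill":
                    raise WaterError(f"year {wy.year_id} is not a late-fill year")


def sample_scenario_years(
    scenario: HydroScenario,
    n_years: int,
    rng: np.random.Generator,
    hydro_params: HydroParams = DEFAULT_HYDRO,
) -> list[WaterYear]:
    """Draw ``n_years`` water years for a scenario (with replacement)."""
    if scenario.year_pool is not None:
        if len(scenario.year_pool) == 0:
            raise WaterError(f"empty year pool for scenario {scenario.kind}")
        idx = rng.integers(0, len(scenario.year_pool), size=n_years)
        return [scenario.year_pool[i] for i in idx]
    return [
        synth_water_year(scenario.kind, rng, hydro_params, year_id=f"{scenario.kind}-{i:03d}")
        for i in range(n_years)
    ]


# ---------------------------------------------------------------------------
# observed-record I/O


def read_water_csv(path: str | Path) -> list[WaterYear]:
    """Read a tidy daily water-level CSV (``year,doy,level_m``) into WaterYears.

    Gaps of at most 2 days are linearly interpolated (and logged); larger
    gaps, duplicate days, and levels outside [400, 450] m are errors that
    name the offending row.
    """
    df = pd.read_csv(path)
    missing = {"year", "doy", "level_m"} - set(df.columns)
    if missing:
        raise WaterError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df.index[(df["level_m"] < 400) | (df["level_m"] > 450) | df["level_m"].isna()]
    if len(bad):
        row = int(bad[0]) + 2  # 1-based, counting the header line
        raise WaterError(f"{path}: level_m={df.loc[bad[0], 'level_m']!r} out of [400, 450] at row {row}")

    years: list[WaterYear] = []
    for year, grp in df.groupby("year", sort=True):
        grp = grp.sort_values("doy")
        if grp["doy"].duplicated().any():
            dup = int(grp.loc[grp["doy"].duplicated(), "doy"].iloc[0])
            raise WaterError(f"{path}: duplicate DOY {dup} in year {year}")
        doys = grp["doy"].to_numpy(dtype=int)
        gaps = np.diff(doys)
        if (gaps > 3).any():
            at = int(doys[np.argmax(gaps > 3)])
            raise WaterError(f"{path}: gap longer than 2 days after DOY {at} in year {year}")
        full = np.arange(doys[0], doys[-1] + 1)
        levels = np.interp(full, doys, grp["level_m"].to_numpy(dtype=float))
        n_filled = full.size - doys.size
        if n_filled:
            log.info("year %s: interpolated %d missing day(s)", year, n_filled)
        years.append(WaterYear(year_id=str(year), levels=levels, doy_start=int(full[0]), source="observed"))
    return years


def write_water_csv(years: Sequence[WaterYear], path: str | Path) -> None:
    """Write WaterYears back to the tidy ``year,doy,level_m`` format."""
    frames = [
        pd.DataFrame(
            {
                "year": wy.year_id,
                "doy": np.arange(wy.doy_start, wy.doy_end + 1),
                "level_m": np.round(wy.levels, 3),
            }
        )
        for wy in years
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def convert_wide_export(frame: pd.DataFrame, date_column: str, level_column: str) -> pd.DataFrame:
    """Convert an agency-style export with a calendar-date column to tidy form.

    Maps dates to the non-leap DOY convention (Feb 29 rows are dropped).
    Format-specific quirks of particular agency files are out of scope;
    callers are expected to hand in an already-parsed DataFrame.
    """
    dates = pd.to_datetime(frame[date_column])
    keep = ~((dates.dt.month == 2) & (dates.dt.day == 29))
    dates = dates[keep]
    nonleap = pd.to_datetime(
        {"year": 2001, "month": dates.dt.month, "day": dates.dt.day}
    )
    return pd.DataFrame(
        {
            "year": dates.dt.year.to_numpy(),
            "doy": nonleap.dt.dayofyear.to_numpy(),
            "level_m": frame.loc[keep.index[keep], level_column].to_numpy(dtype=float),
        }
    )
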