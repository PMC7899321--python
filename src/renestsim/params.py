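"""Model parameters: demographic rates, nest-site statistics, sensitivity modifiers.

All defaults describe a yellow warbler (*Setophaga petechia*) population
breeding in the drawdown zone of a storage reservoir: breeding phenology,
a seasonally declining clutch-size model, brown-headed cowbird parasitism,
stage-specific daily nest survival, post-fledging survival that depends on
whether the territory is inundated, and date-dependent re-nesting
probabilities.  Parameters are plain frozen dataclasses; a flat key/value
YAML (or JSON) document can override any field by name.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

log = logging.getLogger(__name__)

_PROB_FIELDS = frozenset(
    {
        "parasitism_prob",
        "abandon_prob_if_parasitized",
        "dsr_egg",
        "dsr_nestling",
        "egg_to_fledgling_prob",
        "postfledge_survival_dry",
        "postfledge_survival_wet",
    }
)


class ParamError(ValueError):
    """Raised for malformed or out-of-range parameter configuration."""


@dataclass(frozen=True)
class SpeciesParams:
    """Demographic parameters of the simulated population.

    Dates are non-leap day-of-year (DOY, Jan 1 = 1); elevations are metres
    above sea level.  Ranges are hard truncation bounds for the
    truncated-normal draws.
    """

    # annual breeding phenology: mean first-egg date of the population
    season_mean_first_egg_mu: float = 158.0
    season_mean_first_egg_sd: float = 2.3
    season_mean_first_egg_range: tuple[float, float] = (155.0, 163.0)
    # individual females lay relative to the annual mean
    female_offset_sd: float = 7.0
    female_offset_range: tuple[float, float] = (-19.0, 26.0)
    # clutch size declines with date: CS = intercept + slope * DOY
    clutch_intercept: float = 9.60
    clutch_slope: float = -0.033
    clutch_range: tuple[int, int] = (2, 6)
    # nest cycle: fledge DOY = first-egg DOY + clutch size + offset
    days_to_fledge_offset: int = 18
    incubation_days: int = 11
    nestling_days: int = 9
    # brood parasitism (single check, the day before the last egg)
    parasitism_prob: float = 0.19
    abandon_prob_if_parasitized: float = 0.19
    parasitism_clutch_reduction: int = 1
    # stage-specific daily nest survival
    dsr_egg: float = 0.9712
    dsr_nestling: float = 0.9577
    # per-egg probability a laid egg becomes a fledgling given the nest
    # survives (combined hatching failure + nestling death); calibration
    # constant, not a field estimate
    egg_to_fledgling_prob: float = 0.83
    # post-fledging survival to independence (21 d), by territory state
    postfledge_survival_dry: float = 0.729
    postfledge_survival_wet: float = 0.214
    independence_days: int = 21
    # re-nesting probability, logit-linear in the date the attempt ended
    renest_fail_intercept: float = 35.534
    renest_fail_slope: float = -0.208
    renest_success_intercept: float = 34.324
    renest_success_slope: float = -0.211
    renest_delay_fail: int = 6
    renest_delay_success: int = 7
    max_attempts: int = 3
    n_females: int = 35
    n_years: int = 50

    def __post_init__(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParamError(f"{name}={v!r} is not a probability in [0, 1]")
        for name in ("season_mean_first_egg_sd", "female_offset_sd"):
            if getattr(self, name) < 0:
                raise ParamError(f"{name} must be >= 0")
        for name in (
            "season_mean_first_egg_range",
            "female_offset_range",
            "clutch_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParamError(f"{name}={lo, hi} is not an ordered pair")
        if not (
            self.season_mean_first_egg_range[0]
            <= self.season_mean_first_egg_mu
            <= self.season_mean_first_egg_range[1]
        ):
            raise ParamError("season_mean_first_egg_mu outside its range")
        if not self.female_offset_range[0] <= 0.0 <= self.female_offset_range[1]:
            raise ParamError("female_offset_range must contain 0")
        if self.clutch_slope >= 0:
            raise ParamError("clutch_slope must be negative (clutches shrink with date)")
        if self.renest_fail_slope >= 0 or self.renest_success_slope >= 0:
            raise ParamError("re-nesting slopes must be negative")
        if self.max_attempts < 1:
            raise ParamError("max_attempts must be >= 1")
        for name in ("incubation_days", "nestling_days", "independence_days"):
            if getattr(self, name) < 1:
                raise ParamError(f"{name} must be >= 1")
        if self.n_females < 1 or self.n_years < 1:
            raise ParamError("n_females and n_years must be >= 1")


@dataclass(frozen=True)
class SiteParams:
    """Nest-site statistics of the study plots (metres a.s.l. / metres)."""

    ground_elev_mu: float = 438.5
    ground_elev_sd: float = 0.9
    ground_elev_range: tuple[float, float] = (435.6, 441.7)
    nest_height_mu: float = 2.1
    nest_height_sd: float = 1.1
    nest_height_range: tuple[float, float] = (0.3, 6.0)
    # lowest elevation at which willow shrubs (hence nests) occur
    habitat_floor_elev: float = 435.0

    def __post_init__(self) -> None:
        for name in ("ground_elev_range", "nest_height_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParamError(f"{name}={lo, hi} is not an ordered pair")
        if not self.ground_elev_range[0] <= self.ground_elev_mu <= self.ground_elev_range[1]:
            raise ParamError("ground_elev_mu outside its range")
        if not self.nest_height_range[0] <= self.nest_height_mu <= self.nest_height_range[1]:
            raise ParamError("nest_height_mu outside its range")
        if self.habitat_floor_elev >= self.ground_elev_range[0]:
            raise ParamError("habitat_floor_elev must lie below the lowest nest ground elevation")


#: modifier targets -> SpeciesParams fields they act on
MODIFIER_TARGETS: dict[str, tuple[str, ...]] = {
    "parasitism_and_abandonment": ("parasitism_prob", "abandon_prob_if_parasitized"),
    "dsr": ("dsr_egg", "dsr_nestling"),
    "postfledge_wet": ("postfledge_survival_wet",),
}

_ACTIONS = ("multiply", "add", "set")


@dataclass(frozen=True)
class SensitivityModifier:
    """One perturbation of the sensitivity analysis.

    ``target`` names a group of jointly perturbed probabilities (parasitism
    and abandonment move together, as do the two stage-specific daily
    survival rates).  ``action`` is ``multiply``, ``add`` or ``set``;
    resulting probabilities are clamped to [0, 1].
    """

    target: str
    action: str
    value: float

    def __post_init__(self) -> None:
        if self.target not in MODIFIER_TARGETS:
            raise ParamError(
                f"unknown modifier target {self.target!r}; expected one of {sorted(MODIFIER_TARGETS)}"
            )
        if self.action not in _ACTIONS:
            raise ParamError(f"unknown modifier action {self.action!r}; expected one of {_ACTIONS}")

    def label(self) -> str:
        if self.action == "add":
            return f"{self.target}{self.value:+g}"
        sym = "x" if self.action == "multiply" else "="
        return f"{self.target}{sym}{self.value:g}"


def apply_modifier(params: SpeciesParams, mod: SensitivityModifier) -> SpeciesParams:
    """Return a new parameter set with ``mod`` applied; ``params`` is unchanged.

    A modifier that pushes a probability outside [0, 1] is clamped and
    logged, not fatal.
    """
    changes: dict[str, float] = {}
    for name in MODIFIER_TARGETS[mod.target]:
        old = getattr(params, name)
        if mod.action == "multiply":
            new = old * mod.value
        elif mod.action == "add":
            new = old + mod.value
        else:
            new = mod.value
        if name in _PROB_FIELDS and not 0.0 <= new <= 1.0:
            clamped = min(1.0, max(0.0, new))
            log.warning("modifier %s drives %s to %.4f; clamped to %.4f", mod.label(), name, new, clamped)
            new = clamped
        changes[name] = new
    return dataclasses.replace(params, **changes)


# ---------------------------------------------------------------------------
# configuration I/O

_SPECIES_FIELDS = {f.name: f for f in dataclasses.fields(SpeciesParams)}
_SITE_FIELDS = {f.name: f for f in dataclasses.fields(SiteParams)}

ConfigSource = Union[str, Path, dict, None]


def _coerce(name: str, fld: dataclasses.Field, value):
    if "range" in name:
        if not isinstance(value, (list, tuple)) or len(value) != 2:
            raise ParamError(f"{name} must be a 2-element [low, high] pair")
        return tuple(type(fld.default[0])(v) for v in value)
    if isinstance(fld.default, int) and not isinstance(fld.default, bool):
        return int(value)
    return float(value)


def load_params(config_source: ConfigSource = None) -> tuple[SpeciesParams, SiteParams]:
    """Load parameters, applying overrides from a flat key/value document.

    ``config_source`` may be None (pure defaults), a dict, a path to a
    YAML/JSON file, or a YAML string.  Keys are the field names of
    :class:`SpeciesParams` and :class:`SiteParams`; unknown keys are an
    error, as are values violating the invariants.
    """
    if config_source is None:
        overrides: dict = {}
    elif isinstance(config_source, dict):
        overrides = dict(config_source)
    else:
        text = Path(config_source).read_text() if _looks_like_path(config_source) else str(config_source)
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ParamError(f"malformed configuration document: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParamError("configuration document must be a key/value mapping")
        overrides = loaded

    sp_kw: dict = {}
    site_kw: dict = {}
    for key, value in overrides.items():
        if key in _SPECIES_FIELDS:
            sp_kw[key] = _coerce(key, _SPECIES_FIELDS[key], value)
        elif key in _SITE_FIELDS:
            site_kw[key] = _coerce(key, _SITE_FIELDS[key], value)
        else:
            raise ParamError(f"unknown configuration key {key!r}")
    try:
        return SpeciesParams(**sp_kw), SiteParams(**site_kw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ParamError(str(exc)) from exc


def _looks_like_path(source) -> bool:
    if isinstance(source, Path):
        return True
    if isinstance(source, str) and "\n" not in source and ":" not in source:
        return Path(source).exists() or source.endswith((".yml", ".yaml", ".json"))
    return False


def serialize(species: SpeciesParams, site: SiteParams) -> str:
    """Dump both parameter sets to a flat YAML document (load_params inverse)."""
    doc: dict = {}
    for obj in (species, site):
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            doc[f.name] = list(v) if isinstance(v, tuple) else v
    return yaml.safe_dump(doc, sort_keys=False)
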