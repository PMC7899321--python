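"""Scenario runs, validation summaries, effect sizes, and sensitivity analysis.

A scenario run simulates ``n_years`` (default 50) breeding years, each
against a water year drawn per the scenario rules, and collects annual
summaries.  Contrasts between scenarios report the change in fledging
success and productivity together with Cohen's d computed across the
annual values.  Single 50-year runs are intentionally noisy — annual
productivity varies roughly two-fold — so headline comparisons average
over replicate runs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .breeding import AnnualSummary, simulate_year
from .params import SensitivityModifier, SiteParams, SpeciesParams, apply_modifier
from .water import DEFAULT_HYDRO, HydroParams, HydroScenario, sample_scenario_years

METRICS = ("nest_success", "breeding_success", "fledging_success", "productivity")


@dataclass(frozen=True)
class ScenarioResult:
    """Annual summaries of one multi-year scenario run."""

    kind: str
    annual: tuple[AnnualSummary, ...]

    def metric(self, name: str) -> np.ndarray:
        if name not in METRICS:
            raise ValueError(f"unknown metric {name!r}; expected one of {METRICS}")
        return np.array([getattr(a, name) for a in self.annual], dtype=float)

    def mean_sd_ci(self, name: str) -> dict[str, float]:
        """Across-year mean, SD (n-1), and 2.5/97.5 percentile interval."""
        x = self.metric(name)
        return {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "ci_low": float(np.percentile(x, 2.5)),
            "ci_high": float(np.percentile(x, 97.5)),
        }

    def summary(self) -> dict[str, dict[str, float]]:
        return {m: self.mean_sd_ci(m) for m in METRICS}

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per year x metric (boxplot-ready)."""
        rows = [
            {"scenario": self.kind, "year": i + 1, "metric": m, "value": getattr(a, m)}
            for i, a in enumerate(self.annual)
            for m in METRICS
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectSize:
    """Standardized mean difference (Cohen's d) with a 95% CI."""

    d: float
    ci_low: float
    ci_high: float
    metric: str = ""
    from_scenario: str = ""
    to_scenario: str = ""


def run_scenario(
    kind: str,
    params: SpeciesParams,
    site: SiteParams,
    rng: np.random.Generator,
    hydro_params: HydroParams = DEFAULT_HYDRO,
    year_pool=None,
    n_years: Optional[int] = None,
) -> ScenarioResult:
    """Run one scenario: sample water years, simulate each breeding year."""
    scenario = HydroScenario(kind=kind, year_pool=year_pool)
    n = n_years if n_years is not None else params.n_years
    years = sample_scenario_years(scenario, n, rng, hydro_params)
    annual = tuple(simulate_year(wy, site, params, rng) for wy in years)
    return ScenarioResult(kind=kind, annual=annual)


def run_replicates(
    kind: str,
    params: SpeciesParams,
    site: SiteParams,
    n_replicates: int,
    seed_seq: np.random.SeedSequence,
    hydro_params: HydroParams = DEFAULT_HYDRO,
    year_pool=None,
) -> list[ScenarioResult]:
    """Replicate multi-year runs, each on its own child random stream.

    Spawning child streams from one seed sequence keeps every replicate
    reproducible and independent of how many replicates are requested.
    """
    children = seed_seq.spawn(n_replicates)
    return [
        run_scenario(kind, params, site, np.random.default_rng(c), hydro_params, year_pool)
        for c in children
    ]


# ---------------------------------------------------------------------------
# effect sizes and contrasts


def cohens_d(a: Sequence[float], b: Sequence[float], metric: str = "", from_scenario: str = "", to_scenario: str = "") -> EffectSize:
    """Cohen's d for the change from sample ``a`` to sample ``b``.

    d = (mean(b) - mean(a)) / s_pooled with the n-1 pooled SD; the 95% CI
    uses the large-sample variance of d,
    se² = (n1+n2)/(n1·n2) + d²/(2(n1+n2−2)).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("cohens_d needs at least 2 values per sample")
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        if x.mean() == y.mean():
            return EffectSize(0.0, 0.0, 0.0, metric, from_scenario, to_scenario)
        raise ValueError("Cohen's d undefined: zero pooled variance with unequal means")
    d = (y.mean() - x.mean()) / math.sqrt(pooled_var)
    se = math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2 - 2)))
    return EffectSize(float(d), float(d - 1.96 * se), float(d + 1.96 * se), metric, from_scenario, to_scenario)


def scenario_contrast(from_result: ScenarioResult, to_result: ScenarioResult) -> pd.DataFrame:
    """Per-metric mean change, percent change and Cohen's d between two runs."""
    if len(from_result.annual) != len(to_result.annual):
        raise ValueError("scenario runs must have equal numbers of years")
    rows = []
    for metric in ("fledging_success", "productivity"):
        a = from_result.metric(metric)
        b = to_result.metric(metric)
        es = cohens_d(a, b, metric, from_result.kind, to_result.kind)
        rows.append(
            {
                "metric": metric,
                "from_scenario": from_result.kind,
                "to_scenario": to_result.kind,
                "mean_from": a.mean(),
                "mean_to": b.mean(),
                "mean_change": b.mean() - a.mean(),
                "pct_change": 100.0 * (b.mean() - a.mean()) / a.mean() if a.mean() else math.nan,
                "d": es.d,
                "d_ci_low": es.ci_low,
                "d_ci_high": es.ci_high,
            }
        )
    return pd.DataFrame(rows)


def replicate_contrast(
    from_runs: Sequence[ScenarioResult],
    to_runs: Sequence[ScenarioResult],
    metric: str = "productivity",
) -> dict[str, float]:
    """Average a contrast over paired replicate runs.

    Returns the mean Cohen's d across pairs plus grand means and the grand
    percent change — the stable quantities single 50-year runs cannot give.
    """
    if len(from_runs) != len(to_runs):
        raise ValueError("need equal numbers of paired replicate runs")
    ds = [cohens_d(f.metric(metric), t.metric(metric)).d for f, t in zip(from_runs, to_runs)]
    mean_from = float(np.mean([f.metric(metric).mean() for f in from_runs]))
    mean_to = float(np.mean([t.metric(metric).mean() for t in to_runs]))
    return {
        "metric": metric,
        "mean_d": float(np.mean(ds)),
        "sd_d": float(np.std(ds, ddof=1)) if len(ds) > 1 else 0.0,
        "grand_mean_from": mean_from,
        "grand_mean_to": mean_to,
        "pct_change": 100.0 * (mean_to - mean_from) / mean_from if mean_from else math.nan,
        "n_pairs": len(ds),
    }


# ---------------------------------------------------------------------------
# sensitivity and validation


def sensitivity_table(
    params: SpeciesParams,
    site: SiteParams,
    modifiers: Iterable[SensitivityModifier],
    scenarios: Sequence[str],
    seed_seq: np.random.SeedSequence,
    hydro_params: HydroParams = DEFAULT_HYDRO,
    n_replicates: int = 1,
    common_random_numbers: bool = True,
) -> pd.DataFrame:
    """Mean +/- SD of fledging success and productivity per modifier x scenario.

    Each row also carries Cohen's d of annual productivity versus the
    unmodified (baseline) run of the same scenario.  With common random
    numbers (the default) every parameterization reuses the same child
    seeds, so contrasts are paired and Monte-Carlo noise largely cancels.
    """
    mods: list[Optional[SensitivityModifier]] = [None, *modifiers]
    base_children = seed_seq.spawn(len(scenarios))
    rows = []
    baseline_runs: dict[str, list[ScenarioResult]] = {}
    for mod in mods:
        p = apply_modifier(params, mod) if mod is not None else params
        for scen, child in zip(scenarios, base_children):
            if common_random_numbers or mod is None:
                seq = child
            else:
                salt = zlib.crc32(mod.label().encode()) % 2**31
                seq = np.random.SeedSequence(entropy=child.entropy, spawn_key=(*child.spawn_key, salt))
            runs = run_replicates(scen, p, site, n_replicates, seq, hydro_params)
            if mod is None:
                baseline_runs[scen] = runs
            fled = np.concatenate([r.metric("fledging_success") for r in runs])
            prod = np.concatenate([r.metric("productivity") for r in runs])
            row = {
                "modifier": mod.label() if mod is not None else "baseline",
                "scenario": scen,
                "fledging_mean": fled.mean(),
                "fledging_sd": fled.std(ddof=1),
                "productivity_mean": prod.mean(),
                "productivity_sd": prod.std(ddof=1),
            }
            if mod is not None:
                pairs = [
                    cohens_d(b.metric("productivity"), r.metric("productivity")).d
                    for b, r in zip(baseline_runs[scen], runs)
                ]
                row["d_vs_baseline"] = float(np.mean(pairs))
            else:
                row["d_vs_baseline"] = 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def validate_against_field(
    result: ScenarioResult,
    observed: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Side-by-side table of model summaries and observed field values.

    ``observed`` maps metric names (any of nest_success, breeding_success,
    fledging_success, productivity) to field estimates; a metric is flagged
    when the observed value falls outside the model's 95% interval across
    years.  With no observations, only the model columns are returned.
    """
    rows = []
    observed = dict(observed or {})
    unknown = set(observed) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown observed metric(s) {sorted(unknown)}")
    for m in METRICS:
        stats = result.mean_sd_ci(m)
        row = {"metric": m, "model_mean": stats["mean"], "model_sd": stats["sd"],
               "model_ci_low": stats["ci_low"], "model_ci_high": stats["ci_high"]}
        if m in observed:
            row["observed"] = observed[m]
            row["difference"] = observed[m] - stats["mean"]
            row["outside_model_ci"] = not (stats["ci_low"] <= observed[m] <= stats["ci_high"])
        rows.append(row)
    return pd.DataFrame(rows)
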