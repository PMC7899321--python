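# renestsim

A stochastic individual-based model (IBM) of the annual reproductive
output of yellow warblers (*Setophaga petechia*) breeding in the drawdown
zone of a hydroelectric storage reservoir, built to ask a management
question: **how does the timing and height of reservoir filling change the
number of independent young produced per female each year?**

Reservoirs flood riparian shrub habitat from below. For a multi-brooded
songbird the cost is not mainly drowned nests — those are rare — but
fledglings: young that leave the nest onto a territory inundated by the
rising reservoir survive the 21-day dependence period at 0.214 instead of
0.729. Whether that happens depends on the race between each female's
nesting schedule (first-egg date, clutch size, failures and re-nests) and
the hydrograph (when the water crosses the 435 m shrub line and how high
it peaks). `renestsim` simulates that race female by female, day by day,
and compares water-management scenarios on equal footing.

The model follows 35 females per year for 50-year runs. Each nesting
attempt faces daily flooding and stage-specific background mortality
(daily survival 0.9712 with eggs, 0.9577 with nestlings), a one-off
cowbird parasitism/abandonment check, binomial fledging, and
inundation-dependent post-fledging survival; females re-nest after failure
or success with probability logit⁻¹(35.534 − 0.208·DOY) or
logit⁻¹(34.324 − 0.211·DOY), up to three attempts. Water years come from a
tidy CSV of daily levels or from a built-in synthetic hydrograph generator
that reproduces the operating record's fill-date statistics. Four
scenarios are built in: `long_term`, `early_fill` (fill by June 12),
`late_fill` (after June 12 or never), and `zero_flooding`. Details and all
conventions are in [docs/methods.md](docs/methods.md).

## A worked example

```sh
python examples/run_scenarios.py
```

prints (20 replicate 50-year runs per scenario, seed 1):

```
scenario       nest_succ breed_succ fledglings independent
long_term          0.439      0.592       2.03        1.25
early_fill         0.436      0.588       2.01        1.06
late_fill          0.445      0.598       2.04        1.40
zero_flooding      0.453      0.605       2.06        1.49
```

Nest success, breeding success and fledglings per female barely differ
across scenarios — the reservoir rarely floods active nests. Independent
young per female differ a lot: under the current early-fill regime roughly
40% of broods fledge onto inundated territories, cutting productivity to
1.06; delaying the fill past mid-June recovers most of the loss (1.40),
and never flooding the habitat yields 1.49. `examples/effect_sizes.py`
expresses the same contrasts as Cohen's d on annual values (≈1.3 for
early→zero-flooding, ≈1.0 for early→late); `examples/validate_model.py`
checks the early-fill run against twelve years of field monitoring, and
`examples/sensitivity_analysis.py` shows the conclusions are insensitive
to parasitism rates but driven by the wet/dry post-fledging survival gap.

There is also a CLI for shell use — `renestsim run --scenario all --seed 1
--out results`, plus `sensitivity`, `validate`, and `fixtures` (writes a
small example water CSV and a defaults config). Every command is
bit-reproducible from `--seed`.

All Table-style defaults (phenology, clutch model, survival rates,
re-nesting logits, site geometry, hydrograph statistics) live in
`SpeciesParams`, `SiteParams` and `HydroParams`, and any field can be
overridden from a flat YAML config.

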