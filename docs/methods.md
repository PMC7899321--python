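# Methods

`renestsim` is a stochastic, spatially implicit individual-based model
(IBM) of the annual reproductive output of yellow warblers (*Setophaga
petechia*) breeding in riparian shrub habitat inside the drawdown zone of
a hydroelectric storage reservoir. The reservoir's water surface
fluctuates between 419.65 m a.s.l. and full pool at 440.1 m; willow
habitat, and hence nesting, begins at 435 m. Rising water affects
reproduction through two pathways: rarely, by flooding active nests
(water reaching ground elevation + nest height), and chiefly, by
inundating territories during the 21-day post-fledging dependence period,
when fledgling survival drops from 0.729 (dry) to 0.214 (inundated).

## The breeding model

Each simulated year runs 35 females (the average number breeding on the
study plots) against one water year. The year's mean first-egg date is a
truncated normal draw, N(158, 2.3) on [155, 163] (day-of-year, Jan 1 = 1);
each female offsets it by N(0, 7) on [−19, +26] days, and draws a nest
ground elevation N(438.5, 0.9) on [435.6, 441.7] m and nest height
N(2.1, 1.1) on [0.3, 6.0] m. All truncated normals are realized by
rejection sampling against the hard range bounds; because several ranges
are asymmetric, truncated means sit slightly above the location parameter
(e.g. 158.35 for the season start) — tests check the closed-form truncated
moments, not the location parameters.

Clutch size is the deterministic seasonal decline CS = 9.60 − 0.033·DOY,
rounded half-up and clamped to 2–6 eggs. Eggs are laid daily; incubation
(11 d) begins on the penultimate egg; nestlings fledge after 9 d. With the
first egg as day 1 this puts hatch on day CS + 10 and fledge on day
CS + 19 (day 23 for a 4-egg clutch), i.e. fledge DOY = first egg + CS + 18.

From the day after initiation through fledge day, a nest faces, in order
within each day:

1. **Flooding** — deterministic: the day's water level ≥ ground + height.
2. **Parasitism** — once, on the day before the last egg: Bernoulli(0.19)
   parasitism, then Bernoulli(0.19) abandonment. A parasitized clutch
   loses one host egg. (For 2-egg clutches the check day coincides with
   the first-egg day and is still evaluated.)
3. **Background daily survival** — Bernoulli at the stage-specific daily
   nest survival rate: 0.9712 through the hatch day, 0.9577 after. A
   4-egg nest therefore has 13 egg-days and 9 nestling-days at risk, so
   survival to fledging absent other hazards is 0.9712¹³ · 0.9577⁹ ≈ 0.463.

Rather than looping Bernoulli draws day by day, each stage's failure day
is drawn directly from the geometric distribution (one uniform per stage)
and the earliest event — flood day, abandonment day, survival-failure day
— decides the fate, with ties broken by the within-day order above. This
is identical in distribution to the daily loop and about an order of
magnitude cheaper; monotonicity under common random numbers is preserved
(raising a survival rate can only postpone the sampled failure day).

Surviving nests fledge Binomial(effective clutch, 0.83) young; 0.83 is the
combined hatch-and-nestling-survival probability per egg. It is a
calibration constant — the field estimate of ~3.45 fledglings per
successful nest divided by the effective eggs per successful nest — not a
direct field measurement, and it is an ordinary config key.

Fledged broods survive to independence as Binomial(n, p) with p = 0.214 if
the water surface reaches the nest's *ground* elevation (nest height no
longer protects a fledged brood) at any point in the 21 days after
fledging, else p = 0.729.

After an attempt ends on day E the female re-nests with probability
logit⁻¹(35.534 − 0.208·E) after failure (abandonment and flooding count as
failure) or logit⁻¹(34.324 − 0.211·E) after success, up to three attempts
per season. The next first egg follows 6 days after a failure or 7 days
after fledging, at a freshly drawn nest site. Brood independence is
evaluated regardless of whether the female re-nests. First-egg dates are
kept inside DOY 120–220 (rejection for the initial offset; re-nest chains
ending later than that simply stop), which keeps every schedule and
dependence window inside the water-year index (DOY 91–273).

Annual summaries: nest success (proportion of initiated nests fledging ≥1
young), breeding success (proportion of females fledging >0 young),
fledging success (fledglings per female) and productivity (independent
young per female).

## Water years and management scenarios

Observed records load from a tidy `year,doy,level_m` CSV (gaps ≤2 days are
interpolated; longer gaps and out-of-range levels are errors). Absent a
record, the synthetic generator emulates the statistics of the 50-year
operating history:

* **long_term** — 7/50 years never reach 435 m; pooled median fill date
  (first DOY at 435 m) DOY 163.
* **early_fill** — all years fill by June 12 (DOY 163, inclusive); median
  fill DOY 158.
* **late_fill** — fill after DOY 163 or never (7/28 never); median fill
  DOY 172 among filling years.
* **zero_flooding** — never exceeds 435 m.

Fill dates are integer draws from normals truncated to the early (≤163)
or late (≥164) window; the pre-truncation means (159.2 and 170.4) were
re-centred so the *truncated* medians land on 158 and 172. The long-term
scenario mixes no-fill years (p = 0.14) with early- and late-type fill
dates weighted 22:21, reproducing the pooled median of 163.

A trajectory is piecewise linear: a schematic base (the biology is blind
to levels below 435 m), a rise crossing 435 m exactly on the fill date and
continuing at a sampled rate to a peak day drawn uniformly in DOY 186–208
("peaks in July"), a 10-day hold, then a decline. The peak *level* is
derived, not sampled: 435 + rate · (peak day − fill date), capped at full
pool. Deriving the peak from a shared rise rate makes late-filling years
peak lower — physically sensible (late fills are low-water years) and
necessary to reproduce the observed scenario contrasts; an independent
peak-level distribution would give early and late years the same peaks
and erase most of the late-fill benefit.

The record gives no peak-level or rise-rate statistics, so the rate,
N(0.086, 0.022) m/day truncated to [0.03, 0.15], is the generator's one
calibrated constant: it was chosen (once, then frozen) so that under the
early-fill scenario ~40% of fledged broods sit on territories inundated
during their dependence window — the fraction implied by the population's
observed fledging success (2.06/female) and estimated productivity
(1.06/female) given the 0.729/0.214 survival split. All generator
parameters are exposed in `HydroParams`.

## Scenario analysis

Scenario runs default to 50 years of 35 females. Metrics are summarized
as across-year mean, SD, and 2.5–97.5 percentile interval. Contrasts
report the mean change, percent change, and Cohen's d across annual
values, d = (mean_to − mean_from)/s_pooled with n−1 pooled SD; its 95% CI
uses the normal approximation se(d)² = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂−2)).
Because a single 50-year run is dominated by environmental and demographic
stochasticity (annual productivity ranges roughly two-fold), headline
numbers average ≥80–200 replicate runs; paired replicates share seeds so
Monte-Carlo noise largely cancels. The sensitivity table reruns scenarios
under perturbed parameters — parasitism/abandonment ×0.5/×1.5, daily nest
survival ±0.01 (an absolute shift of the daily probability, the
conventional reading of "±1%"; a multiplicative action is also available),
and inundated post-fledging survival doubled or equalized — with common
random numbers by default.

All randomness flows through `numpy.random.Generator`; one root
`SeedSequence` spawns child streams per scenario and replicate, so runs
are bit-reproducible and adding replicates never perturbs earlier draws.

## What the synthetic generator does and does not capture

It reproduces the fill-date distributions, the no-fill frequencies, July
peaks, and (by calibration) the early-fill brood-inundation fraction. It
does **not** reproduce rare extreme-water years: observed records
occasionally approach full pool while nests are still active, and the
field study attributes ~4% of nest failures to flooding, whereas synthetic
early-fill years flood only ~1% of nests. Pushing the generator hard
enough to flood 4% of nests would overshoot the brood-inundation anchor
badly, and nest flooding is a minor pathway compared with post-fledging
survival, so the calibration favours the inundation anchor. Consequently
the zero-flooding scenario gains less fledging success over early fill
(~+2%) than the original study reports (~+11%), and simulated zero-flood
productivity (~1.49 independent young/female) sits just below the
published 1.62–1.68. Model validation against the early-fill field data is
unaffected (all validation metrics fall well inside one SD).

## Numerical conventions and edge cases

* Non-leap DOY calendar throughout; leap days in converted records are dropped.
* Clutch rounding is half-up; fill-date threshold crossing is first-day, ≥.
* "Filled by June 12" is inclusive (fill date ≤ 163 is early).
* The hatch day itself uses the egg-stage survival rate; days after it use
  the nestling rate.
* Probabilities pushed outside [0, 1] by a sensitivity modifier are
  clamped and logged, not fatal.
* Cohen's d with zero pooled variance raises unless the means are equal
  (then d = 0).

## Limitations

Spatially implicit: no territories, density dependence, or partial brood
flooding; no male behaviour; parasitism at most once per nest; empirical
regressions (clutch size, re-nesting, daily survival) are taken as fixed
inputs, not re-fitted. Productivity lacks a field validation value because
post-fledging survival was radio-tracked in only three field seasons.
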