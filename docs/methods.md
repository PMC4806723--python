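# Methods

## Diurnal water-loss integration and permutation inference

Porometry yields instantaneous stomatal conductance g_s (mmol·m⁻²·s⁻¹) at a
few clock times per individual. Because leaves transpire negligibly in the
dark, each individual's curve is closed with g_s = 0 at dawn and dusk and
integrated by the trapezoid rule over time-in-hours; with the standard four
sampling times each curve has six points. The daylight window defaults to
06:30–18:30 — a 12 h window bracketing the sampling times — and both
endpoints are parameters; the printed integral carries the unit
(mmol·m⁻²·s⁻¹)·h. No conversion to absolute transpiration or canopy-level
water use is attempted: the quantity is a leaf-level index whose species
*contrast* is the object of inference, under the assumption that leaf
conductance scales consistently to transpiration in both species.

The test statistic is the difference in species means of per-individual
daily integrals. Exchangeability holds at the level of whole individuals,
so each permutation reassigns species labels across individuals (all of an
individual's readings move together), preserving group sizes. We report
the permutation distribution, its 2.5th/97.5th percentiles (the decision
rule: the observed difference outside those limits), and an
add-one-corrected two-sided p-value, p = (1 + #{|Δ*| ≥ |Δ|})/(B + 1),
which can never be zero. A `species_mean` option integrates the
per-time-point species mean curve instead of averaging per-individual
integrals; for balanced data with common sampling times the two observed
statistics are identical (integration and averaging are both linear), and
the per-individual route is the default because it remains defined under
unbalanced sampling.

With ≤5 individuals per species the label universe is small (C(10,5) = 252
splits), so Monte-Carlo sampling with replacement is used at every size and
validated in the tests against exhaustive enumeration at 3+3 and 4+4.

## Growth analysis

The harvest design is cross-sectional: different plants are destroyed at
each age, so "growth through time" means an OLS fit across individuals, not
repeated measures. Per species × year:

* RGR: slope of ln W on age (W = total dry mass, g; day⁻¹);
* NAR slope: slope of ln(W/A) on age (A = leaf area, cm²) — an operational,
  log-scale net-assimilation measure, deliberately not the classical
  (1/A)(dW/dt);
* leaf-area rate: slope of ln A on age.

Since ln W = ln(W/A) + ln A, least-squares linearity makes
RGR = NAR_slope + leaf-area rate an exact identity on shared plants; the
tests assert it at machine precision, which guards against silent
row-filtering bugs anywhere in the pipeline.

Allocation components (SLA, LAR, LMR, RMR, root:shoot) are per-plant
ratios; LAR is defined as leaf area over total dry mass, which preserves
LAR = SLA × LMR identically. Zero denominators flag the record rather than
propagating silent NaNs. The mid-season ANOVAs analyse ln-transformed
component values at the 95-day anchor age (with 53 days as the early anchor
for the relative change in LAR, (LAR₉₅ − LAR₅₃)/LAR₅₃); both anchors are
parameters. The relative LAR change is computed from means at two ages, so
it carries no per-plant standard error.

Carbon isotope discrimination is Δ = (δ_air − δ_plant)/(1 + δ_plant/1000)
in per mil, strictly decreasing in δ_plant and exactly invertible; δ_air
defaults to −8.0‰ (standard tropospheric value) and is configurable.

## The ANOVA engine

All fixed-effects tables use OLS with Type-II sums of squares (marginal at
each order — appropriate for the mildly unbalanced layouts these
experiments produce; Type I/III are switches). p-values come from the F
distribution.

The single random blocking factor (field plot, or spatial block) is handled
classically rather than by REML, keeping every F deterministic:
fixed-term SS are computed in the fixed-effects projection; adding the
block dummies then splits the remaining variation into a block stratum and
a residual stratum. A fixed term constant within every block (e.g. year,
when plots are nested within years) is tested against the block mean
square; terms varying within blocks are tested against the residual mean
square; the block itself against the residual. This is exact for balanced
block layouts, which is what the generator produces; for strongly
unbalanced field data a REML fit would be the appropriate upgrade and the
engine's surface would not change. A consequence worth knowing: denominator
degrees of freedom are containment-based, so they will generally not match
software that uses Satterthwaite or Kenward–Roger approximations.

The engine refuses rank-deficient designs, constant responses, and models
with zero residual df rather than returning degenerate tables.

## The competition index

RII = (B_w − B̄₀)/(B_w + B̄₀) uses the *species-level* mean of alone-grown
plants as B̄₀, so all RII values within a species share one baseline and are
not strictly independent; the two-way ANOVA nevertheless treats them as
independent replicates, which matches standard practice for this index.
Seed-set RII is computed on raw counts. Focal plants with zero performance
are retained at RII = −1 (a dead plant is maximal competition, not missing
data); dropping them is an option. The ANOVA's competitor factor is the
neighbour's species identity (derived from focal species × neighbour class),
because the scientific question — "is the invader the stronger suppressor?"
— is a main effect in that coding and an interaction in the
conspecific/heterospecific coding.

## Enemy-release test

Responses are plot-level summaries (individuals per plot, mean fruits, mean
mass), analysed untransformed — including the count — to match the standard
treatment of such per-plot variables; a log option exists. Species rows
within a plot are treated as independent observations, and the design
requires both treatments within every block. The ERH verdict is
"interaction p < α for at least one response" by default (α and the
any/all rule are knobs); the package reports the verdict alongside the
extracted interaction rows rather than hiding the evidence behind the
boolean.

## The synthetic-data generator

The generator's defaults *are* the study conditions the analyses
interrogate; they are fixed once and the tests are written against them.

* **Porometry**: 5 individuals/species at the four standard times. The
  diurnal template is a half-sine over the daylight window, piecewise
  time-warped so its maximum sits at the configured peak time — any smooth
  unimodal shape would do, since downstream only ever sees the sampled
  points. Peaks of 252 (invasive) vs. 400 (native) mmol·m⁻²·s⁻¹ make the
  invader's expected daily integral 37% lower; noise is Gaussian (sd
  30 mmol·m⁻²·s⁻¹, a plausible porometer-plus-leaf variation) clipped at 0.
* **Harvests**: ages {33, 53, 95, 115} days (the two mid-season anchors
  plus flanking ages), 4 plots/year, 6 plants per species × year × plot ×
  age. ln-mass = ln M₀ + RGR·age + plot effect + noise, with M₀ = 0.01 g,
  mean-one lognormal mass noise (cv 0.2), plot sd 0.1 (log scale). True
  RGRs: invasive 0.12 (warm) / 0.155 (cool), native 0.08 / 0.15 day⁻¹ —
  a strong warm-season advantage for the invader, near-parity in the cool
  season. Allocation (leaf/root fractions, SLA per species × year, e.g.
  warm-season SLA 250 vs. 185 cm²·g⁻¹) gets mean-one lognormal jitter
  (cv 0.1), with fraction pairs rescaled if a draw would push
  leaf + root past 0.95.
* **Competition**: 20 alone pots per species plus 20 per neighbour
  treatment. Suppression factors {invasive: 0.449 vs. conspecific, 0.667
  vs. native; native: 0.587 vs. conspecific, 0.389 vs. invasive} are
  additive on the RII scale (expected RII −0.38/−0.20 and −0.26/−0.44), so
  both focals are hit harder by the invasive neighbour, the native is more
  suppressed overall, and the focal-by-competitor interaction is null in
  expectation. Seed counts are negative-binomial (dispersion k = 8;
  k = 0 switches to deterministic rounded means for exact-recovery tests);
  biomass is lognormal (cv 0.25) with independently jittered root
  allocation.
* **Exclusion**: 16 blocks × (control + exclusion) × 2 species = 64 rows.
  Species means (e.g. 14 vs. 10 individuals/plot, 6.5 vs. 4.0 fruits) with
  treatment and interaction effects defaulting to zero — the no-release
  scenario — plus block and residual Gaussian effects; counts are rounded
  and all responses clipped at non-negative values (means sit ≥4 sd from
  zero, so clipping is rare and the null calibration is unaffected).

Setting every sd/cv to zero collapses each value onto its closed-form
expectation, which the tests exploit for exact parameter recovery. Identical
configs produce byte-identical tables (all randomness flows through seeded
`numpy` Generators with a distinct stream per design).

What the generator does **not** emulate: weather-driven phenology,
spatially explicit competition, overdispersed or zero-inflated field
counts, measurement error in leaf-area scanning, or real unbalancedness
(missing plants, lost plots). Passing tests therefore demonstrate that the
estimators recover known effects under clean factorial designs at
desk-scale sample sizes — not that any particular field dataset satisfies
the models' assumptions.

## Numerical choices and scale

Simulation-heavy checks are sized to run on a laptop: the permutation null
calibration uses 1000 replicate datasets × 500 permutations; power checks
use 200 replicates; growth-bias checks 200 replicates at 25 plants per
species × year cell. The ERH power check injects a species-by-treatment
interaction of 1.5 residual sd (0.12 g on mean mass), chosen by a standard
noncentral-F power calculation to sit near 85% power for the 64-row design.
Percentiles are numpy linear-interpolation percentiles; permutation p-values
are add-one corrected; ties in the permutation statistic count as "as
extreme".

## Known limitations

* Containment denominator df will not reproduce software using
  approximate-df mixed models on unbalanced data.
* The fixed-term/stratum split is exact only for block-orthogonal (balanced)
  layouts; heavily unbalanced field data deserve REML.
* RII's shared-baseline dependence is ignored by the ANOVA (by design,
  matching field practice); a bootstrap over alone-grown plants would
  propagate that uncertainty.
* The permutation test assumes whole-curve exchangeability under the null;
  systematic species differences in *when* conductance peaks violate only
  power, not validity.
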