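# invasionphys

Trait-based comparison of an invasive desert winter annual with a native
congener: does the invader succeed by escaping its enemies, or by combining
high water-use efficiency with fast growth and strong competitive ability?

The package implements, as a tested and reusable pipeline, the four
analyses such a comparison rests on, plus a seed-reproducible synthetic-data
generator that emulates all four experimental designs so every estimator has
a parameter-recovery test surface.

## What it computes

**Diurnal water loss** (`water_flux`). Stomatal conductance g_s
(mmol·m⁻²·s⁻¹) is measured by porometer at four clock times (08:30, 10:30,
13:30, 16:30); each individual's curve is closed with zeros at dawn and dusk
(six points over a 12 h window) and integrated by the trapezoid rule. The
species contrast in mean daily integrated conductance,
Δ̄ = mean(invasive) − mean(native), is tested against a null built by
randomly permuting species labels across individuals (default 1000
permutations, 95% percentile limits plus an add-one-corrected two-sided p).

**Growth analysis** (`growth`). From sequential destructive harvests at
known ages in two contrasting growing seasons:

- RGR = slope of ln(total dry mass) on age (day⁻¹), by OLS per species × year;
- NAR slope = slope of ln(mass per leaf area) on age;
- leaf-area expansion rate = slope of ln(leaf area) on age, so that
  RGR = NAR_slope + leaf-area slope exactly;
- allocation components per plant: SLA = A/W_leaf, LAR = A/W_total,
  LMR = W_leaf/W_total, RMR = W_root/W_total, root:shoot — with the identity
  LAR = SLA × LMR;
- mixed ANCOVA of ln biomass (age covariate, species × year fixed, field
  plot random) and mixed ANOVAs of ln mid-season components;
- carbon isotope discrimination Δ = (δ_air − δ_plant)/(1 + δ_plant/1000)
  (per mil, δ_air default −8.0‰) as a proxy for integrated WUE, with a
  fixed-effects species × year ANOVA for leaf N and Δ.

**Competition** (`competition`). Relative interaction intensity per focal
plant and response (seed set, total, above-ground, root mass):

    RII = (B_w − B̄₀) / (B_w + B̄₀) ∈ [−1, 1]

with B̄₀ the conspecific alone-grown mean; negative = competition, positive
= facilitation. A two-way fixed-effects ANOVA crosses focal species with
the competitor's species identity.

**Enemy release** (`herbivory`). Paired control/herbivore-exclusion plots
in blocks; mixed ANOVA (species × treatment fixed, block random) per
plot-level response. The enemy release hypothesis predicts a
species-by-treatment interaction; `erh_test` extracts those rows and
applies a configurable α / any-vs-all decision rule.

All models funnel through a shared deterministic least-squares engine
(`linear_models`, statsmodels OLS with Type-II SS and classical
error-stratum F-ratios for the random blocking factor).

## Worked example

```
$ python analysis/01_simulate.py --seed 1
$ python analysis/02_water_flux.py --seed 1
mean daily integrated conductance: {'invasive': 1873.8, 'native': 3069.9}
observed difference (invasive - native) = -1196.1, permutation 95% limits [-769.0, 800.4], p = 0.0140
finding: the invader loses 39.0% less water over the day (significantly less at the 95% permutation limits)
```

The observed contrast lies far outside the permutation limits: the invader
moves ~39% less water through its leaves per day than the native. The growth
stage of the same run fits

```
$ python analysis/03_growth.py
 species year      rgr   rgr_se  nar_slope  leaf_area_rgr  n
invasive cool 0.154650 0.000619  -0.000075       0.154725 96
invasive warm 0.119840 0.000731  -0.000027       0.119867 96
  native cool 0.149954 0.000660   0.000118       0.149837 96
  native warm 0.080680 0.000686   0.000453       0.080228 96
RGR ANCOVA species-by-year interaction p = 1.27e-31
```

i.e. the invader grows ~50% faster than the native in the warm season
(0.120 vs. 0.081 day⁻¹) while the two converge in the cool season — a
species-by-year interaction the ANCOVA detects decisively. The competition
and herbivory stages (`04_competition.py`, `05_herbivory.py`) print the RII
table (all negative; strongest suppression by the invasive neighbour) and
the exclusion ANOVAs (no species-by-treatment interaction: no evidence of
enemy release).

The same surfaces are exposed as a CLI (`invasionphys simulate | waterloss |
growth | competition | herbivory | anova`); runs with a fixed seed are
byte-identical.

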