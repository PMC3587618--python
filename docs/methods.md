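# Methods

## Model

`envburden` estimates the annual deaths and health-care-facility visits
attributable to environmental exposures using the population-attributable-
fraction (PAF) framework of comparative risk assessment. For one
pollutant–endpoint pair,

    PAF = ( Σ_x P(x)·RR(x) − Σ_x P'(x)·RR(x) ) / Σ_x P(x)·RR(x)

where `P(x)` is the population distribution of exposure, `P'(x)` the
counterfactual distribution (all pollutants reduced to background: zero for
every route except outdoor air, where background is itself uncertain and
drawn from uniform distributions), and `RR(x)` the relative risk at
exposure level `x`. Categorical sums include the unexposed reference
category at RR = 1; continuous exposures replace the sums with expectations
over the exposure distribution. When several pollutants act on the same
endpoint within one route (e.g. second-hand smoke and incense on lung
cancer), fractions combine multiplicatively,

    PAF = 1 − Π_i (1 − PAF_i),

which assumes uncorrelated exposures and biologically independent effects.
Attributable cases are `D_attrib = PAF · D_total`, with `D_total` the
endpoint's baseline deaths or visits. Routes are always evaluated
separately — the same endpoint may appear under several routes, and those
fractions are never combined across routes.

Per-unit relative risks (per 10 µg/m³, per 100 Bq/m³, per log10
organisms/100 ml) extrapolate log-linearly:
`RR(x) = rr_unit^((t(x) − t(x0))/unit)` with `t` the identity or log10.
Extrapolation is floored at RR = 1: because the counterfactual is the
*elimination* of pollution to background, negative excess risk from
exposure below the counterfactual is out of model scope. The log10
transform floors concentrations at 1 organism/100 ml before taking logs, so
months with zero observed counts contribute no burden rather than −∞.

## Uncertainty propagation

Every uncertain input is a declarative distribution spec (point, uniform,
triangular, lognormal, normal, Bernoulli). Published summaries convert as
follows:

* **Central estimate with 95% CI** → lognormal anchored at the *median*
  (`mu = ln(central)`), with `sigma = ln(ucl/lcl) / (2·1.96)` from the CI
  ratio alone. Anchoring at the median preserves the printed point estimate
  under the log transform; whether the original implementation anchored the
  median or the arithmetic mean is not documented, and the median convention
  is adopted here. Using only the CI ratio is the standard single-parameter
  fit when printed CIs are asymmetric around the closed form.
* **Arithmetic mean and sd** → moment-matched lognormal
  (`sigma² = ln(1 + (sd/mean)²)`, `mu = ln(mean) − sigma²/2`).

Sampling is Latin hypercube: for each variable the n draws occupy the n
equiprobable CDF strata exactly once (one uniform sub-draw per stratum,
inverse-CDF transform), with stratum order permuted independently across
variables. The default is **1,000 iterations**, which the underlying study
found to yield stable results; our convergence test (doubling iterations on
the drinking-water pair) agrees. Each variable consumes a substream derived
from `SeedSequence([seed, crc32(variable_name)])`, so results are
bit-reproducible under a seed, independent of pair ordering, and adding a
variable never perturbs the draws of existing ones. Lower truncation is
implemented by inverse-CDF sampling on the truncated support, which
preserves stratification (rejection sampling would not). Inputs are assumed
independent; no copulas.

**Variability vs. uncertainty.** Within one Monte Carlo iteration, RR and
prevalence *parameters* are sampled (uncertainty), while continuous
exposure distributions describing across-person/home variability (radon,
formaldehyde) are integrated by deterministic quadrature on 512
equiprobable quantile midpoints. This follows the classic risk-analysis
separation of uncertainty from variability; the quadrature is exact for the
smooth RR curves used here to well below Monte Carlo noise (verified
against brute-force sampling oracles in the test suite).

Summaries are the **mean** of draws (the central estimates reproduce the
published values, which a median would not for skewed draws) with a 95%
interval from the 2.5th/97.5th percentiles (linear interpolation between
order statistics). Relative risks whose CI straddles 1 legitimately sample
protective draws; per-draw fractions may therefore be negative and interval
lower bounds can dip below zero. Display rounding follows the source's
precision pattern — counts ≥ 10,000 to 3 significant figures, 1,000–9,999
to the nearest 10, smaller counts to integers, fractions to 0.1% — with raw
values always retained.

## Exposure route models

* **Categorical** (second-hand smoke, mold, incense, occupational
  categories, climate change): survey prevalences with per-category RRs;
  sex-specific RRs are mixed by the endpoint's sex split (0.5/0.5 default —
  the source applies sex-specific RRs but prints no sex-split baselines).
  Climate change is a categorical pair with 100% prevalence, so
  PAF = (RR−1)/RR per draw. The second-hand-smoke endpoints use nonsmoker
  RRs applied to whole-endpoint baselines (no smoker stratum), which
  reproduces the published cardiovascular fraction.
* **Two-group drinking water**: population fraction with regulated supply
  `p1 ~ triangular(0.96, 0.98, 1.0)` at `RR1 ~ uniform(1, 4)`; the
  complement on unregulated water at `RR2 ~ uniform(7.2, 10.2)`;
  PAF = (p1(RR1−1) + p2(RR2−1)) / (1 + p1(RR1−1) + p2(RR2−1)).
* **Tap-water cancers**: exposed prevalence mixes citizenship —
  `0.19·0.105 + 0.81·uniform(0.84, 0.964)` per draw — with sex-mixed
  chlorination-by-product RRs.
* **Coastal water**: twelve monthly enterococci uniforms feed
  `RR = 1.34^log10(max(c, 1))` among swimmers; the monthly fraction among
  the whole population is `p_swim(RR−1)/(1 + p_swim(RR−1))`, averaged with
  equal month weights 1/12 (the monthly aggregation is not documented in
  the source; equal weighting of the annual gastroenteritis baseline is
  assumed). Swim prevalence is population-weighted: citizen age–sex strata
  (equal quarter weights, an assumption — the citizen age pyramid is not
  printed) and a 6.2% noncitizen prevalence at the 81% noncitizen share,
  giving p_swim ≈ 0.0531. Dubai beaches carry doubled concentrations
  (wastewater overflows) as the *same* monthly draw × 2 — perfectly
  correlated, since both derive from the same observed series — weighted by
  a 0.35 Dubai population share (approximate 2008 value; not printed).
* **Spatial outdoor air**: a 1,164-cell grid with per-cell concentration
  mean/sd and population by citizenship. Per iteration, each cell draws a
  concentration from a normal truncated at zero (independent across cells —
  only per-cell means/sds are specified; the synthetic generator can add
  autocorrelation to probe this), one national background draw is shared by
  all cells (the background is a counterfactual policy level, not local
  noise), and PAF = 1 − 1/(population-weighted mean RR). Cells below the
  background contribute RR = 1. The adult mortality baseline is applied
  nationally with cell weighting by total population, as no per-cell age
  structure exists.
* **Fixed fraction** (asbestosis, silicosis, mesothelioma): attributable
  cases are fixed sex-specific proportions of observed cases. Mesothelioma
  deaths use the 100% rule and visits the 90%/25% sex rule, matching how
  the two published tables report them.

## Synthetic data

The original inputs (monitor networks, a death registry, insurance claims,
household surveys) are not deposited. The synthetic module generates
stand-ins with known ground truth: concentration grids with log-uniform
population allocation (three decades of cell size, largest-remainder
integer rounding), stratified baseline tables in exact expected-count mode
by default (binomial noise optional, off so tests stay sharp), and whole
scenarios whose true PAF is solved analytically (categorical closed-form
inversion; continuous/spatial placement of all exposure at the
concentration solving `rr_unit^(x*/unit) = 1/(1−PAF)`). The synthetic
outdoor-air grid emulates the *size and structure* of the real grid, not
its values — desert-urban concentration ranges (PM2.5 35–90, PM10 80–250
µg/m³, O3 20–60 ppb cell means) were chosen once as plausible. Passing
tests on synthetic grids therefore demonstrate correctness of the spatial
machinery, not reproduction of published outdoor-air results, which require
the unpublished monitor-derived surfaces.

## Numerical choices and problem sizes

Quadrature: 512 equiprobable midpoints (configurable). LHS: 1,000
iterations for all headline runs; oracle comparisons in tests use up to
5·10⁵ brute-force draws and 3-standard-error bands. The bundled national
scenario (41 risk pairs, 1,164-cell grid) runs in about one second.
Percentile convention, rounding rules and the random-stream policy are
fixed as described above so that runs are exactly reproducible.

## Known limitations

* Exposed-workforce fractions for occupational leukemia/lung cancer and the
  radon subpopulation baseline shares are unpublished; bundled values are
  marked placeholders and excluded from reproduction checks.
* Published uncertainty intervals cannot be matched draw-for-draw without
  the original random streams; comparisons use means with tolerances and
  interval-containment checks.
* No disability-adjusted life years (repeat visits cannot be deduplicated
  in the source data), no dose–response shapes beyond log-linear/categorical,
  no exposure correlation, and no kriging of raw monitor series.
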