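# Methods

`cotslink` re-implements, as a tested pipeline over synthetic data, a
three-part Bayesian analysis of whether fish biomass removal by
fisheries predicts Crown-of-Thorns Starfish (CoTS, *Acanthaster* spp.)
densities on coral reefs, and whether no-take marine reserves carry more
predatory fish and fewer CoTS. The real monitoring (manta-tow and
belt-transect surveys) and fisheries logbook data are restricted, so a
first-class synthetic-data generator stands in for them; every model can
therefore be exercised against known ground truth.

## The three models

**1. Fisheries-lag models (hurdle-gamma).** Site-year CoTS density
`y` (individuals per minute of 2-minute manta tow, averaged over tows on
fished reefs within a 6×6-nautical-mile logbook grid-site) is zero for
many site-years and continuous otherwise:

    P(y = 0)        = logit⁻¹(γ₀ + γ₁·cover)
    y | y > 0       ~ Gamma(α, rate = α/μ)
    log μ           = a₀ + a₁·cover + b·log(1 + kg) + u_site
    u_site          ~ Normal(0, σ_site)

`kg` is retained catch (all four fisheries summed) for one fish group at
the same grid-site `x` years earlier. The slope `b` — the
biomass-removal scaling exponent — is the quantity of interest, fitted
independently for six fish groups × six lags (36 models). Gamma is
parameterized by (shape, mean) with `rate = shape/mean`, so the log link
acts on the mean and `b` is directly the scaling exponent. Because
site-years with zero aggregated catch are possible, the biomass
covariate enters as `log(1 + kg)`.

**2. Reserve-effect models (hurdle-gamma / gamma).** Site-level fish
density per 1000 m² and standing biomass (kg per 1000 m², via
length-weight `w = a·Lᵇ`) follow the same hurdle-gamma form with zoning
status as the fixed effect in both components; site-level mean total
length follows a plain gamma. Random intercepts: within-reef site, reef
pair, reef, and year. Fished reefs are the reference level, so the
effect of interest is the unfished log-fold; it is reported draw-wise as
`exp(effect)` (fold) and `(fold − 1)×100` (percent of the fished value).

**3. Zoning model for CoTS (negative binomial).** Tow-level CoTS counts:

    y_tow  ~ NB(μ, φ),  Var = μ + μ²/φ
    log μ  = β₀ + β₁·[open] + β₂·cover + ζ(reef-year)
    ζ      ~ Normal(0, σ_ζ)

Closed (no-take) zoning is the reference, so `β₀` is the unfished
intercept at zero cover, `β₁` tests whether open reefs carry more CoTS,
and `β₂` tests the coral-cover association. Derived draw-wise:
`exp(β₁)` (the open:closed fold ratio) and `exp(2σ_ζ)` (the fold range
between reef-years one SD above vs below average). Tow-level coral-cover
categories are converted to proportions by the fixed 16-category
midpoint table; the same table drives the site-year means used by the
lag models.

**Hypothesis summaries.** Every directional effect is summarized by the
percentage of posterior mass above zero, classified at strict
thresholds: `>95%`, `>80%`, otherwise `none`. Intervals are equal-tailed
quantile intervals (60% and 95%), never HPD. All derived quantities
(folds, percent differences, range factors) are transformed draw by draw
and only then summarized; percent and fold satisfy
`percent = (fold − 1)×100` exactly per draw.

## Priors and parameterization

The priors are weakly informative defaults, overridable via
`PriorConfig`:

| parameter | prior | default scale |
|---|---|---|
| intercepts (both components) | Student-t(3, 0, s) | s = 2.5 |
| slopes | Normal(0, s) | s = 2.5 |
| hierarchical SDs | half-Normal(0, s) | s = 2 |
| gamma shape / NB dispersion | half-Normal(0, s) | s = 5 |

Positive parameters are sampled on the log scale with the half-Normal
applied on the natural scale plus the log-Jacobian. Random intercepts
are non-centred (`effect = σ·z`, `z ~ N(0,1)`). A centred option exists
(`ModelSpec.centered`) and agrees with the non-centred form on
well-identified problems, but in worlds with many weakly informed group
levels (e.g. all-zero reef-years) it mixes into a funnel and is not used
by the built-in analyses.

## Sampling and diagnostics

Posteriors are sampled with an ensemble MCMC sampler (emcee; 90%
differential-evolution moves, 10% snooker moves) over fully vectorized
log-posteriors; the ensemble size is `max(2·ndim + 2, 8·chains)`
walkers. Walkers serve as diagnostic chains: rank-normalized split-R̂
and bulk/tail ESS are computed for every parameter (implemented in
`cotslink.diagnostics` with batched FFT autocovariances; cross-validated
against arviz). A fit whose worst split-R̂ exceeds 1.01 or whose
smallest ESS falls below 400 is returned with `converged=False` and an
explicit `ConvergenceWarning` — never silently. Because walkers within
an ensemble are cross-correlated, walker-chain R̂ is a conservative
flag: short desk-scale runs often carry the flag while their quantiles
are already stable (verified against 15 000-step reference runs). The
stored chain is thinned to roughly 250 draws per walker; with dozens of
walkers this leaves tens of thousands of draws. A mandatory integer seed
makes every fit bit-reproducible.

Posterior predictive checking for excess zeros: replicate datasets are
drawn at posterior parameter draws (conditional on the fitted random
intercepts) and the observed zero fraction is located within the
replicated distribution; a tiny upper-tail probability indicates zero
inflation the count model cannot produce.

## The synthetic-data generator

`WorldConfig` defaults mirror the study's sampling effort: 157 logbook
grid-sites, reporting years 1990–2018 (1 July–30 June, labelled by end
year), one third of reefs in no-take zones, 15 belt transects per reef
per survey year, ~47 manta tows per reef-year. `TruthParams` defaults
use the study's central estimates as generative truth: open-zoning log
ratio `log 2.8`, coral slope −0.45, reef-year SD 3.77, and per-group
reserve multipliers whose implied biomass folds (density × length³
under cubic length-weight scaling) span ≈1.4–2.1.

Mechanisms, and what was decided where the underlying study is silent:

- **Catch.** Site-year log-catch is multivariate normal across the six
  groups with a configurable correlation matrix (defaults: 0.95 for
  coral trout–Serranidae, 0.92 for the emperor species pair vs the
  family, 0.5 elsewhere; validated symmetric PSD with unit diagonal,
  errors name the failing eigenvalue). Fishery rows split site-year
  totals by fixed shares (line 70%, charter 15%, net 10%, trawl 5% —
  chosen once as a plausible reef-line-fishery profile), so aggregates
  preserve the correlation exactly. Catch tables extend 6 years before
  the first survey year so every lag is coverable.
- **Tow counts.** Negative binomial (dispersion 0.5, chosen once as
  strongly overdispersed) with the zoning model's exact structure; the
  lagged catch term enters with log-catch centred per group, so slopes
  act on catch variation and the intercept keeps its meaning. Zeros
  arise from the count process only — no inflation component — matching
  the finding of no zero inflation. The NB mean is capped at e¹²
  per tow to keep astronomically rare tails finite.
- **Coral cover.** A reef-year latent proportion is Beta-distributed
  (mean 0.30, concentration 8); tow-level cover is Beta around the
  latent (concentration 40) and snapped to the nearest category
  midpoint, which is the code recorded in the table.
- **Fish transects.** Counts per 250 m² belt are negative binomial
  (mean 5, dispersion 1.5); individual total lengths are lognormal
  (median 35 cm, log-SD 0.25). No-take reefs multiply the count mean and
  lengths by per-group factors; biomass folds *emerge* downstream
  through the length-weight computation rather than being injected.
- **Direct model-family generators.** For parameter-recovery studies,
  `simulate_paired_site_years` draws site-year densities from the
  hurdle-gamma process itself, and `simulate_reserve_site_values` draws
  site-level responses from the reserve model structure. Recovery of a
  model family is assessed on data from that family; the tow-level NB →
  site-year hurdle pathway (a deliberate structural mismatch mirroring
  the two real data streams) is assessed by classification behaviour
  instead.

Seeding is hierarchical: one world seed spawns independent child
generators per table, so regenerating one table never perturbs another,
and identical (config, truth, seed) triples give byte-identical CSVs.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no spatial autocorrelation or outbreak-wave
propagation between reefs; no observer error or under-sampling of small
CoTS; no temporal autocorrelation in catches beyond the cross-group
correlation; no unbalanced survey effort (every reef-year is sampled);
length-weight coefficients are synthetic fixtures, not literature
values. Passing recovery tests demonstrate the estimators are correct
and calibrated for the assumed processes, not that those processes
describe the Great Barrier Reef.

## Data preparation rules

- Reporting years run 1 July–30 June, labelled by end year; all joins
  use this label.
- Tow counts are per 2 minutes; density is `mean(count/2)` per minute.
- Duplicate grid-site-years: if both zonings present, closed-zone reefs
  are dropped; remaining multiple reefs are averaged with an unweighted
  arithmetic mean (tow-count weighting is deliberately not applied, and
  the choice is recorded in the audit log). The fisheries-lag stream
  additionally drops site-years observed only in closed zones.
- Catch aggregation sums the four fisheries; duplicate fishery rows are
  summed with a logged warning; negative masses are errors.
- Belt counts scale by 4 to densities per 1000 m²; site mean length
  pools individual fish across transects (a flat pool, not a mean of
  transect means).
- Every drop/average/sum decision is appended to a machine-readable
  audit log (JSON lines).
- Values are carried at full floating precision; rounding (3
  significant figures) happens only in reports.

## Problem sizes in the test suite

The test and acceptance runs use deliberately small worlds chosen to
make the statistical checks sharp at desk scale: zoning-model recovery
uses 5 grid-sites × 2 reefs × 4 years × 6 tows (40 reef-years) over 20
replicates; lag-model recovery uses 12 sites × 10 years over 20
replicates with truths b ∈ {0, 0.3}; reserve recovery uses 6 reef pairs
× 3 survey years with folds 1.4 and 2.1 over 20 replicates; null
calibration pools 2 replicates of the full 36-cell grid. Sampler runs
in tests use 1 000–2 500 ensemble steps after equal warmup.

## Known limitations

- Ensemble MCMC trades gradient information for simplicity; very high
  dimensional crossed-random-effect models (hundreds of levels) mix
  slowly, and walker-chain R̂ flags are conservative. For
  production-scale refits a gradient-based sampler would be preferable.
- The hurdle-gamma lag model is an approximation when data arise from
  tow-level counts (conditioning on positivity attenuates slopes); this
  mirrors the original two-stream design rather than a defect, but
  effect sizes from that pathway should be read qualitatively.
- No multiple-testing adjustment is applied across the 36-cell grid;
  with null effects, roughly 2–5% of cells are expected to reach the
  >95% class by chance, and the null-calibration test bounds this
  empirically.
- The catch generator is iid across years given the group correlation;
  real logbook series are temporally autocorrelated, which would widen
  lag-model uncertainty on real data.
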