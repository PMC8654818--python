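# cotslink

Bayesian analysis of the link between fisheries, no-take marine
reserves, and Crown-of-Thorns Starfish (CoTS, *Acanthaster* spp.)
outbreaks on coral reefs.

CoTS outbreaks are a leading cause of coral loss across the
Indo-Pacific, and whether harvesting of predatory fish drives them has
been debated for decades. This package implements, as a reusable and
fully tested pipeline, the statistical machinery needed to ask that
question with monitoring and fisheries-logbook data:

1. **Fisheries-lag models** — hurdle-gamma regressions of site-year CoTS
   density (individuals per minute of manta tow) on retained-catch
   biomass of a fish group `x` years earlier, one model per group × lag
   (six groups: Labridae, Lethrinidae, *Lethrinus miniatus/nebulosus*,
   Lutjanidae, Serranidae, *Plectropomus/Variola*; lags 1–6; 36 models).
   The slope `b(g, x)` of log density on log catch is the
   biomass-removal scaling exponent.
2. **Reserve-effect models** — hurdle-gamma (biomass, density) and gamma
   (length) hierarchical models comparing fish on paired fished/unfished
   reefs, with site, reef-pair, reef and year random intercepts; effects
   reported as unfished:fished fold changes and percent differences.
3. **Zoning model for CoTS** — a negative-binomial model of tow-level
   CoTS counts, `log μ = β₀ + β₁·[open] + β₂·cover + ζ(reef-year)` with
   `ζ ~ N(0, σ_ζ)`, yielding the open:closed density ratio `exp(β₁)` and
   the reef-year range factor `exp(2σ_ζ)`.

Directional hypotheses are assessed by the percentage of posterior mass
above zero (strict `>80%` / `>95%` evidence classes). The real
monitoring and logbook extracts are restricted-access, so the package
ships a first-class synthetic-data generator (`cotslink.simulate`) that
reproduces their statistical structure — zero-heavy overdispersed
counts, enormous reef-year variance, zoning multipliers on fish,
correlated cross-group catches — and makes every stage testable against
known ground truth.

## Worked example

Simulate a small tow-survey world whose generative truth is a 2.8-fold
open-zoning ratio, coral-cover slope −0.45 and reef-year SD 3.77, then
fit the zoning model (`examples/03_zoning_model.py`):

```python
from cotslink import TruthParams, WorldConfig, run_cots_zoning_model
from cotslink.simulate import simulate_catch_tables, simulate_cots_surveys

config = WorldConfig(n_grid_sites=6, reefs_per_site=2, years=(2000, 2004),
                     tows_per_reef_year=8, seed=3)
truth = TruthParams()
tows = simulate_cots_surveys(config, truth, simulate_catch_tables(config, truth))
result = run_cots_zoning_model(tows, warmup=2500, iterations=2500, seed=30)
print(result.summaries)
```

prints (medians with 60%/95% equal-tailed credible intervals):

```
     parameter  median  ci60_low  ci60_high  ci95_low  ci95_high  prob_above_zero evidence_class
         beta0  -3.327    -4.062     -2.645    -5.061     -1.757            0.000           none
         beta1   1.467     0.746      2.198    -0.235      3.196           95.539           >95%
         beta2   0.708    -0.347      1.765    -1.841      3.236           71.461           none
sigma_reefyear   3.504     3.179      3.877     2.780      4.406          100.000           >95%

open:closed fold ratio exp(beta1): 4.34 [0.79, 24.44]
reef-year range factor exp(2*sigma): 1105 [260, 6708]
```

Read: in this small world the open-zoning effect `β₁` is positive with
95.5% posterior probability (truth `log 2.8 ≈ 1.03` sits inside the 95%
interval), the reef-year SD is recovered near its truth of 3.77, and the
derived fold quantities are computed draw-wise from the same posterior.
At this desk scale the intervals are wide; they tighten with more reefs,
years and tows.

The other capabilities each have a narrative script under `examples/`:
world generation (`01`), the data-preparation chain with its audit log
(`02`), a miniature lag grid (`04`), and reserve effects from transects
to percent differences (`05`).

## Command line

A thin CLI drives the same library from a single YAML config:

```bash
cotslink simulate   -c run.yaml   # write catch / manta-tow / transect CSVs
cotslink validate   out/manta_tows.csv
cotslink prepare    -c run.yaml   # site-years, catch aggregates, lag pairs
cotslink fit-zoning -c run.yaml
cotslink fit-lag    -c run.yaml
cotslink fit-reserve -c run.yaml
cotslink report     -c run.yaml   # tables + figures
```

Every artifact gets a provenance sidecar (config hash + seed); schema
violations and convergence failures exit non-zero.

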