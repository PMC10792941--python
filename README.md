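# nestprospect

Movement-ecology analysis pipeline linking **pre-nesting prospecting** to
**incubation recess movements** and **nest fate** in GPS-tagged ground-nesting
birds (built around the biology of female wild turkeys, *Meleagris gallopavo*).

Ground-nesting birds leave the nest during incubation on short "recess"
excursions. If a female scouts foraging patches while she is still laying,
she can route those recesses to places she already knows. This package
quantifies that behavior from raw GPS fix tables and asks whether it predicts
nesting success:

1. **GPS cleaning** (`gps`) — fix tables with an hourly 05:00–20:00 +
   nightly 23:58:58 schedule; fixes with dilution of precision > 7 removed.
2. **Phenology** (`phenology`) — incubation onset = first night the nightly
   fix is on the nest (27.5 m, the transmitter's 90th-percentile error);
   laying onset = first hourly fix < 20 m from the nest in the preceding 20
   days; attempts incubated < 3 days are dropped.
3. **Prospecting** (`prospecting`) — laying-period fixes are merged into
   *clustered laying patches* (CLPs) by single-linkage clustering at 150 m;
   incubation fixes > 27.5 m from the nest are recesses; a recess within a
   45-m buffer of a CLP centroid is a revisit. Per attempt:
   `proportion_to_clp` and `n_clp_visited`.
4. **Incubation ranges** (`home_range`) — dynamic Brownian bridge movement
   model (dBBMM; 20-m error, 7-fix window, 3-fix margin), 95% utilization
   contour, 500 uniformly sampled available points per range.
5. **Landscape covariates** (`landscape`) — six-class landcover on a 30-m
   grid; exact Euclidean distance surfaces per class, to roads, and to the
   nest.
6. **Models** (`models`) —
   * used/available resource-selection GLMM (logit link, female random
     intercept, 2-SD covariate rescaling, Pearson collinearity screen at
     r > 0.6), fitted by adaptive Gauss–Hermite maximum likelihood:
     `used_i ~ Bernoulli(logit⁻¹(β₀ + βᵀz_i + b_f))`
   * Bayesian nest-fate model `fate_i ~ Bernoulli(logit⁻¹(α + β₁z₁ᵢ +
     β₂z₂ᵢ + b_f))`, `b_f ~ N(0, σ_b²)`, sampled with 4 MCMC chains ×
     8000 iterations (1000 burn-in); reported with 95% credible intervals,
     probability of direction (pd), split R-hat, and the average marginal
     effect of one extra CLP visited.

Because real telemetry is not bundled, `synthetic` simulates populations
with the same fix schedule and known ground truth (nest, onsets, per-fix
behavior labels, revisit targets, generative fate coefficients), so every
stage is scored by recovery tests.

## Worked example

The numbered scripts under `analysis/` run the pipeline step by step:

```sh
python analysis/01_simulate.py --seed 7 --n-females 20
python analysis/02_segment.py
python analysis/03_prospect.py
python analysis/04_home_range.py --seed 7
python analysis/05_rsf.py
python analysis/06_nest_fate.py --seed 7
```

`02_segment.py` prints, for the default seed:

```
DOP filter kept 13499/13600 fixes; 20 attempts kept, 0 removed (< 3 incubation days)
incubation onset exact for 100% of attempts; laying onset within 1 day for 95%; median nest error 2.5 m
```

i.e. the overnight rule recovers every simulated incubation onset and
locates nests to a few meters despite 10-m GPS noise. `03_prospect.py`
then prints

```
1344 recesses across 20 attempts; mean proportion to CLPs 0.527 (generative rate 0.576); mean CLPs visited 4.4 of 5.4
```

— the recovered revisit proportion tracks the generative rate (0.57) to
within classification noise. `06_nest_fate.py` reports the posterior table
(mean, 95% CI, pd, R-hat per coefficient) and the marginal effect in
percentage points of success per additional CLP visited; at 20 attempts
the credible intervals are wide, as they should be — the calibration and
power properties of the model are scored at n = 500 in the test suite.

The library surface is importable directly; `nestprospect.pipeline.run_pipeline`
executes everything end-to-end and writes deterministic, config-hashed
summary tables.

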