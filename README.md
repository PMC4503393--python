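# pvasim

**How reliable are projected population declines when the census data are
short, noisy, and the model may be too simple — or too complicated?**

`pvasim` is a simulation laboratory for population viability analysis
(PVA) aimed at conservation modellers and quantitative ecologists.  It
measures how the choice between a *scalar* (count-based) and a *matrix*
(age-structured Leslie) PVA model interacts with environmental
variability (process error), census noise (measurement error), and
census length when projecting the percent decline of a population over a
10-year horizon — the window used by IUCN Red List criterion A.3 for
short-generation species.  Two life histories ship as presets: a
10-age-class hypothetical short-lived organism (all annual survivals
0.5, like many passerines and small mammals) and the threatened
Tasmanian land snail *Tasmaphena lamproides* (5 classes, survivals
0.4, 0.5, 0.8, 0.75 with a 0.7 composite-class self-loop).

## The experiment

1. **Truth.** A stochastic Leslie matrix model
   `n_{t+1} = A_t n_t` generates 60 years of age-structured abundances.
   Every year draws fresh, mutually independent vital rates: survivals
   from moment-matched beta distributions on [0, 1], the single shared
   fecundity from a stretched beta on [0, 1000], each with standard
   deviation `PE_CV × mean`.  Fecundity `f` is back-calculated so the
   dominant eigenvalue of the mean matrix equals a chosen growth rate
   `λ ∈ {0.9, 0.95, 1.0, 1.025}`.  The run starts at the stable age
   distribution with 10⁹ individuals; years 1–50 are "history" and years
   51–60 the projection target.
2. **Observation.** Each age-specific abundance is perturbed with
   `Normal(n, ME_CV × n)` noise, truncated at zero; the estimators see
   only the last `M ∈ {5, 10, 15, 20, 30, 40, 50}` years.
3. **Estimation.** From one window, both model types are built: the
   scalar model pools the `M − 1` observed total-population growth
   ratios `λ_t = n_{t+1}/n_t`; the matrix model pools cohort-ratio
   survivals `n_{i+1,t+1}/n_{i,t}`, a composite-class survival
   `n_{K,t+1}/(n_{K−1,t} + n_{K,t})`, and fecundities
   `n_{1,t+1}/Σᵢ n_{i,t}`.  Survival ratios above 1 are biologically
   impossible and are **censored** — excluded from the pools but
   counted; this censoring is the engine of the matrix model's bias.
4. **Projection & scoring.** Each estimated model is projected 10 years,
   1000 trajectories, resampling each rate pool with replacement every
   time step.  Per replicate the score is
   `diff = true % decline − median estimated % decline`; per scenario,
   *precision* is the inverse IQR width of the diffs and *bias* their
   median.  The full factorial is 4 λ × 4 PE_CV × 3 ME_CV × 7 M = 336
   scenarios per life history.

## Worked example

```sh
$ pvasim fecundity -l t_lamproides --lam 0.95
t_lamproides lambda=0.95: fecundity = 0.397635
```

The snail matrix with shared fecundity 0.3976 has dominant eigenvalue
0.95: a population declining 5% per year on average.

```sh
$ pvasim simulate --lam 0.9 --pe-cv 0.3 --me-cv 0.1 -m 10 \
      --reps 100 --traj 200 --seed 42 --out demo
scalar: bias=-2.727  iqr_width=35.941  precision=0.02782
matrix: bias=-0.501  iqr_width=36.862  precision=0.02713
records -> demo/records.csv
```

One hypothetical-life-history scenario (λ = 0.9, PE_CV = 0.3,
ME_CV = 0.1, 10-year census, 100 replicates): both models are nearly
unbiased here (median diffs of −2.7 and −0.5 percentage points — the
negative sign means declines are slightly over-estimated) with an IQR
spread of ≈36 points in the replicate-to-replicate decline differences.
At higher measurement error or shorter windows the matrix model's
censoring pushes its bias strongly toward over-estimated declines while
the scalar model stays centred.

The same machinery is available as a library:

```python
from pvasim import ScenarioConfig, run_scenario

res = run_scenario(ScenarioConfig(life_history="t_lamproides", lam=1.025,
                                  pe_cv=0.3, me_cv=0.3, m=5,
                                  n_true_reps=200, n_traj=200, seed=0))
print(res.summaries["matrix"]["iqr_width"], res.summaries["matrix"]["bias"])
```

`pvasim grid` runs full or partial scenario grids from a YAML config and
writes a per-scenario summary CSV; `pvasim report` draws faceted
box-plot summaries of the decline differences from stored records.
Real census tables (year column + age-class columns, CSV) can be loaded
with `pvasim.io.read_census_table` and fed to the estimators.

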