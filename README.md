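# stockhab

Length-based stock assessment and overwintering habitat-suitability
modelling for data-limited fisheries.

`stockhab` is aimed at fisheries scientists working on stocks for which the
only population data are length measurements from surveys and spatially
gridded catch records: no ageing structures, no tagging, no stock-specific
acoustic surveys. It bundles two modelling engines plus synthetic-data
generators that make both fully testable by parameter recovery.

## What it computes

**1. ELEFAN growth and mortality.** Growth follows the seasonalized von
Bertalanffy growth function (VBGF)

    L(t) = L∞ (1 − exp(−(K(t − t0) + S(t) − S(t0)))),
    S(t) = (CK / 2π) sin 2π(t − ts),

with asymptotic length L∞, growth coefficient K, age-at-zero-length t0,
seasonal amplitude C and summer point ts. ELEFAN (electronic length
frequency analysis) fits these parameters without ages: binned length
frequencies are *restructured* into signed peak scores by a moving-average
ratio, and candidate growth curves are scored by the fraction of peak score
their cohort trajectories explain, Rn = 10^(ESP/ASP)/10 ∈ (0, 1]. Four
workflows are provided: K-scan (K at fixed L∞), response-surface analysis
(exhaustive L∞ × K grid), simulated annealing and a genetic algorithm (all
parameters at once), plus a sweep over bin widths × moving-average windows
× workflows.

Downstream of an accepted growth curve the package computes the
length-converted catch curve (total mortality Z = −slope of ln(N/Δt) on
relative age over the descending limb), natural mortality M (empirical
estimators or user-supplied), fishing mortality F = Z − M, exploitation
rate E = F/Z, the logistic capture-probability ogive (t50, t95) from the
ascending limb, and the length–weight allometry w = aL^b.

**2. Habitat suitability (HSI).** Standardized abundance (catch scaled to
[0, 1]) is related to depth, winter sea-surface temperature and salinity
through per-variable suitability-index curves SI(x) ∈ [0, 1] — either a
fitted Gaussian ("fitting-based") or a clipped polynomial
("regression-based") — combined across variables by an arithmetic or
geometric mean into HSI ∈ [0, 1]. All 28 candidate models (7 variable
subsets × 2 SI families × 2 combiners) are trained on one period and
validated on a held-out period by R² and small-sample AICc of the
observed-on-predicted regression; the winner is refit on the full period.
Predicted winter HSI fields are classed as optimal (≥ 0.7), average
(≥ 0.3) or poor habitat, with cosine-latitude-weighted area percentages,
decadal one-way ANOVA with Scheffé contrasts, and an OLS winter SST trend.

## Worked example

```python
import stockhab as sh

# a synthetic stock with known truth: Linf=434 mm, K=0.43/yr, Z=1.87/yr
scen = sh.PopulationScenario(n_per_sample=346, seed=7)
samples = sh.simulate_length_frequencies(scen)

model = sh.ElefanModel(samples.samples, bin_mm=10, ma_window=11)
fit = model.fit("SA", seed=7)
print(fit.summary())
```

```
ELEFAN SA fit (bin = 10 mm, MA = 11)
----------------------------------------------------
  Linf          477.72 mm
  K              0.402 /yr
  t_anchor       0.960 yr
  C              0.000
  ts             0.000 yr
  Rn            0.2919
  seed               7
```

With 8% individual length variation the fit lands near the generating
parameters (L∞ high by ~10%, K low by ~7% — the usual correlated L∞–K
uncertainty of length-based methods; at zero noise both are recovered to a
few percent). Mortality then follows from the catch curve:

```python
lfq = samples.to_lfq(10)
growth = sh.VBGFParams(fit.params.linf_mm, fit.params.k_per_yr, t0_yr=0.0)
cc = sh.length_converted_catch_curve(lfq, growth)
est = sh.exploitation(cc.z_per_yr, 0.30, z_se=cc.z_se)
print(est.summary())
```

```
Mortality and exploitation
--------------------------------
  Z  total mortality      2.200 /yr (SE 0.118)
  M  natural mortality    0.300 /yr  [user]
  F  fishing mortality    1.900 /yr
  E  exploitation rate    0.864
```

An exploitation rate of 0.86 — far above the ~0.5 rule-of-thumb for full
exploitation — flags a heavily overfished stock (the generator's truth is
E = (1.87 − 0.30)/1.87 = 0.84). The habitat engine runs the same way:

```python
grid = sh.simulate_environment_and_catch(sh.HabitatScenario(seed=7))
res = sh.HabitatSuitabilityModel(grid, range(1971, 1981), [1981, 1982]).fit()
print(res.summary())
```

```
Habitat suitability model selection
--------------------------------------------
  best model    fitting_based / AM / depth+sst
  test R^2        0.5389   (train 1971-1980, test 1981-1982, n=288)
  test AICc     -1445.57
  SI curves (refit on full period):
    depth  Gaussian mu=52.376 sigma=28.890 optimal [33.08, 71.68]
    sst    Gaussian mu=19.307 sigma=1.644 optimal [18.21, 20.41]
```

The selection recovers the generating model family (fitting-based,
arithmetic mean, depth + SST) and its optimal ranges (truth: 36–72 m and
18.2–20.5 °C) despite 30% lognormal catch noise.

A command-line interface wraps the same machinery:

```bash
stockhab simulate lfq  --seed 1 --out lfq.csv
stockhab assess growth --lfq lfq.csv --workflow SA --seed 1
stockhab simulate grid --seed 1 --out grid.csv
stockhab habitat --grid grid.csv --train-years 1971-1980 --test-years 1981-1982
stockhab run --config pipeline.yaml       # full growth -> mortality -> habitat run
```

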