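# Methods

This note documents the models implemented in `stockhab`, their
assumptions, the tunable parameters that matter, and the design choices
made where the methodology is genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Growth: seasonal VBGF and ELEFAN scoring

Growth follows the seasonalized von Bertalanffy function with parameters
L∞ (mm), K (1/yr), t0 (yr), C ∈ [0, 1] and ts ∈ [0, 1). For C ≤ 1 the
curve is non-decreasing in age; C > 1 (mid-winter shrinkage) is rejected.
Time is a decimal-year axis; calendar dates convert as
`year + (day_of_year − 0.5)/365.25`.

**Restructuring.** Each sample column of the binned length frequency is
transformed into signed peak scores in five documented steps: (1) centred
moving average over `ma_window` bins (edges use the neighbours that
exist); (2) ratio `count/MA − 1`, zero where MA = 0; (3) positive scores
divided by the column mean of positive scores (mean peak height 1; makes
the transform invariant to scaling a column's counts); (4) positive scores
divided by `2^nz`, nz = number of immediate neighbours with zero counts
(an isolated spike is weak evidence of a cohort mode); (5) bins with zero
counts assigned −0.01 × (position within their zero run) instead of the
raw −1 (long empty stretches accumulate a mild, not overwhelming,
penalty). The same sequence is transcribed independently, loops-and-lists,
in the test suite and the two implementations are compared elementwise on
random inputs.

**Scoring.** A candidate (L∞, K, t_anchor, C, ts) generates one cohort
trajectory per birth year, anchored at the year fraction `t_anchor`. At
every sample date each trajectory's length is mapped to a bin
(membership is half-open `[lower, upper)`); ESP accumulates the
restructured scores of the cells hit, ASP is the total positive score, and
Rn = 10^(ESP/ASP)/10. **Each (bin, sample) cell is credited at most once
in total, across all cohorts.** Crediting per cohort instead would let two
trajectories claim the same peak, allowing ESP > ASP and Rn > 1; the
global-crediting rule is what guarantees the invariant 0 < Rn ≤ 1 that the
rest of the package (and its tests) rely on.

**Workflows.** K-scan profiles Rn over a K grid at fixed L∞;
response-surface analysis evaluates the full L∞ × K grid (ties broken
toward smaller parameter values for reproducibility). Simulated annealing
(geometric cooling 0.95, 200 temperature levels × 50 proposals, Gaussian
steps of 2% of each bound range) and a generational genetic algorithm
(population 50, 100 generations, tournament selection of size 3, BLX-0.5
blend crossover, Gaussian mutation of 2% of range) search (L∞, K, C, ts)
jointly. Two design choices matter for reliability:

* *Anchor profiling.* The recruitment anchor is a phase parameter with
  many near-equivalent local modes; treating it as a free SA/GA coordinate
  makes the objective a needle in 3+ dimensions on sharply-peaked data. All
  workflows therefore profile the anchor over a grid (default 50 points)
  at every objective evaluation, vectorized so the profiled evaluation
  costs little more than a single one.
* *Warm start.* SA starts from (and the GA seeds one individual with) the
  best point of a coarse L∞ × K grid scan. Cold-started chains can settle
  on the L∞–K alias ridge (smaller L∞ compensated by larger K); the cheap
  global probe places the search inside the main basin while leaving the
  annealing/evolution budgets unchanged.

Both stochastic workflows require an explicit seed and are exactly
reproducible given one. With discrete per-parameter grids supplied, SA
proposals step between neighbouring grid points, which makes the search
space finite and lets tests compare against exhaustive enumeration.

The scenario sweep enumerates bin widths {10, 20} mm × MA windows
{5, 7, 9, 11} × the four workflows (32 fits) and ranks by Rn; arbitrary
user grids are accepted.

## Mortality, selectivity, length–weight

The length-converted catch curve pools all samples, converts bin edges to
relative ages with the **non-seasonal** inverse VBGF
t(L) = t0 − (1/K) ln(1 − L/L∞) (the seasonal inverse has no closed form;
using it for C > 0 is a documented approximation), and regresses ln(N/Δt)
on the age midpoint of each bin. The descending limb is auto-selected as
the bins strictly after the pooled peak through the last bin with at least
`min_count` (default 5) fish — the log of a small count is unstable — and
bins crossing L∞ are excluded with a warning. Z = −slope with its OLS
standard error; at least three points are required.

Natural mortality options: Pauly's temperature formula
(log10 M = −0.0066 − 0.279 log10 L∞[cm] + 0.6543 log10 K + 0.4634 log10 T),
the growth-based estimator M = 4.118 K^0.73 L∞[cm]^−0.33, or a
user-supplied value (the default for reproducing published parameter sets,
since the estimator behind a published M is often unstated). F = Z − M and
E = F/Z are computed at full precision; rounding happens only in
reporting. M > Z is rejected as implausible rather than silently producing
negative F.

The capture-probability ogive back-extrapolates expected fully-selected
counts over all bins up to the last regression point as
exp(intercept + slope·t)·Δt, forms observed/expected clipped to [0, 1],
and least-squares fits a logistic parameterised directly by (t50, t95), so
P(t50) = 0.5 and P(t95) = 0.95 hold by construction and t95 > t50 is
enforced. Lengths at 50%/95% capture come through the growth curve. The
length–weight fit is OLS on log w = log a + b log L.

## Habitat suitability

Catch standardized by its maximum serves as observed suitability in
[0, 1] (standardization by the global maximum over the modelling period;
per-year standardization is available but not default, since the choice is
not identifiable from the data itself).

**SI curves.** The fitting-based form is a Gaussian
SI(x) = exp(−(x − μ)²/2σ²), fitted to the binned upper envelope of the
abundance scatter (10 equal-width bins, the maximum observation per bin at
its actual x value); the envelope isolates the suitability signal from
cells that are unsuitable in *other* variables. The regression-based form
is a polynomial (default cubic) OLS fit, renormalized over the observed
domain and clipped to [0, 1], with the overall F-test p-value recorded.
The "optimal range" of a curve is {x : SI(x) ≥ 0.8}; the 0.8 cut is a
configurable convention, since published optimal ranges rarely state one.

**Joint calibration.** For a multi-variable fitting-based candidate the
per-variable envelope fits are only initial values: all Gaussian (μ, σ)
plus one scale factor are then refined together against the standardized
abundance by nonlinear least squares for the candidate's combiner. The
envelope of a combined surface is not itself a Gaussian (for an arithmetic
mean of two variables it is (SI_v + 1)/2), so envelope-only fits are
systematically too wide; the joint refinement removes that bias, and on
noise-free data generated from Gaussian SIs it recovers the generating
parameters exactly (zero-residual optimum). The scale factor absorbs
abundance standardization and is dropped afterwards — returned curves peak
at 1.

**Combination and selection.** HSI is the arithmetic (AM) or geometric
(GM) mean of the included SI values; GM ≤ AM everywhere and GM is
annihilated by any zero SI. Candidates — every non-empty subset of
{depth, SST, SSS} × 2 SI families × 2 combiners = 28 — are fitted on the
training winters and scored on held-out winters by OLS of observed on
predicted suitability: R² (higher better), then AICc
n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k = 3 (intercept, slope, residual
variance). At fixed n and k, AICc is a monotone transform of RSS, so it
cannot overturn an R² ranking; genuine ties are resolved by parsimony
(fewer variables, then fitting-based before regression-based, then AM
before GM), which matters on noise-free data where nested candidates fit
equally perfectly. The winner is refit on training + test years.

**Classification and change.** Winter means average December of the
labelled year with January/February of the next (a winter belongs to its
December year). Cells class as optimal (HSI ≥ 0.7), average (≥ 0.3) or
poor — the closed-upper boundary rule is a documented convention where
strict published inequalities leave the boundary undefined — and areas are
weighted by cos(latitude) because fixed-degree cells shrink poleward.
Decadal differences in yearly class areas are tested by standard one-way
fixed-effects ANOVA with Scheffé simultaneous pairwise contrasts
((mean_i − mean_j)² / (MSW(1/n_i + 1/n_j)(g−1)) against F(g−1, N−g);
conservative for all contrasts). The winter SST trend is OLS of area-mean
winter SST on year; a constant series returns slope 0 with the fit flagged
degenerate rather than an undefined R².

## Synthetic data: what it emulates and what it does not

**Population generator.** An equilibrium age structure (constant
recruitment and constant total mortality Z, truncated where survival
exp(−Z·age) < 1e-4), 1 or 2 recruitment pulses per year, mean length at
age from the seasonal VBGF phased to the calendar, Gaussian individual
variation (sd = cv_length × mean length, redrawn while non-positive), and
logistic gear selectivity applied by rejection sampling with resampling
until exactly `n_per_sample` fish are retained per date (fixed sample
sizes keep the tests simple). Defaults describe a heavily exploited,
fast-growing sciaenid-like stock: L∞ = 434 mm, K = 0.43/yr, t0 = −0.06 yr,
Z = 1.87/yr, selectivity L50/L95 at the lengths reached at ages 0.37/0.49
yr, six quasi-seasonal survey dates with 346 fish each (≈ 2074 total), and
cv_length = 0.08 (a typical within-cohort length CV for fast-growing
marine fish). The generator records each fish's cohort age, so tests can
verify lengths against the growth curve directly.

Not emulated: density-dependent or time-varying recruitment, growth
variability between individuals' K, size-dependent natural mortality,
gear saturation, and measurement error. Passing recovery tests therefore
demonstrates correctness of the estimators under their own assumptions,
not robustness to violations of them.

**Habitat generator.** A 0.5° grid over a shelf-sea domain
(120–126° E × 24–30° N by default). Depth is static, deepening offshore;
SST carries a meridional gradient, fixed per-cell spatial structure,
small month effects and a linear trend (−0.028 °C/yr by default — a
multi-decadal winter cooling; the spatial structure is held fixed across
years precisely so the area-mean trend is exactly linear and estimable);
SSS is a saddle-shaped field, deliberately orthogonal to the depth and SST
gradients so the three predictors are separable, plus per-winter
interannual anomalies. Expected winter catch is proportional to the true
HSI — the arithmetic mean of Gaussian SIs whose modes/widths put SI = 0.8
at 36/72 m (depth) and 18.2/20.5 °C (SST) — times mean-one lognormal noise
with CV `catch_noise_cv` (default 0.3). The true per-cell HSI is stored in
the output grid for recovery tests; with zero noise, catch is exactly
proportional to it.

Not emulated: land/coast masks (every cell is water), fishing effort
distribution (catch is abundance times noise, with no effort confounding —
the central caveat of using commercial catch as an abundance proxy),
species movement, and covariance between environmental variables beyond
the fixed spatial fields.

## Numerical choices and degenerate inputs

* Bin membership is half-open; a length on an edge belongs to the upper
  bin. Bins span the observed range starting at
  `floor(min/bin_mm)·bin_mm`.
* Grid-search ties break toward smaller parameter values; SA/GA require
  seeds; all randomness flows through one `numpy` generator per call, no
  global state.
* The joint SI calibration bounds σ away from 0 and ∞ (10⁻⁴–10× the
  variable span) and optimises log σ and log scale for conditioning.
* AICc guards RSS = 0 (perfect fit) by flooring RSS at 1e-300; n ≤ k+1 is
  rejected.
* An all-zero restructured column is returned as zeros, not an error;
  scoring a data set with no positive scores at all (ASP = 0) raises.
* Class percentages are closed to exactly 100 by assigning the float
  rounding drift to the poor class (≤ 1e-9 in practice).
* Problem sizes in the tests and the acceptance script (quarterly samples
  of 500 fish over two years; a 12 × 12-cell grid over 12 winters; 50
  selection replicates) were chosen as the smallest sizes at which the
  estimators' sampling noise is clearly below the tolerances being
  checked.

## Known limitations

* The seasonal inverse VBGF approximation biases catch-curve ages when
  C is large; the bias is zero at C = 0 and small for moderate C.
* ELEFAN's L∞–K ridge means single-workflow point estimates should be read
  together with the sweep's spread, not alone; no bootstrap confidence
  intervals are provided.
* HSI model selection with k fixed at 3 has no complexity penalty across
  candidates; on small test sets, over-selection of irrelevant variables
  is resolved only by the out-of-sample comparison and the parsimony
  tie-break.
* Catch-based suitability inherits effort confounding that the synthetic
  world does not simulate.
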