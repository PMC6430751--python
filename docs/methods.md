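# Methods

This note records the models and procedures implemented in `biogapfill`,
the defaults chosen where the design was genuinely open, and what the
synthetic benchmark does and does not establish about real manufacturing
data.

## Trend models and the robust F test

Each time-series parameter is modelled, pooling all cultures' (day, value)
points, by three candidates:

| kind        | form                    | free parameters |
|-------------|-------------------------|-----------------|
| cubic       | Y = ax³ + bx² + cx + d  | 4               |
| logarithmic | Y = a·ln(bx + c) + d    | 4               |
| constant    | Y = d                   | 1               |
| zero        | Y = 0                   | 0 (null only)   |

The objective is the RMS residual over observed points. The cubic fit is
ordinary polynomial least squares. The logarithmic fit is nonlinear least
squares started from (a, b, c, d) = (10, 10, 10, 10), with the feasibility
constraint b·x + c ≥ 10⁻⁶ on the observed day range enforced by a penalty
residual; if that run fails, lands infeasibly, or is beaten by the
constant fit (the constant model is in the family via a = 0), a coarse
multi-start over signed log-spaced coefficients is tried and the best
feasible solution kept. The (b, c) pair is identified only up to a common
scaling absorbed by d, so fits are always assessed at curve level
(predictions), never at coefficient level. Cost tolerances are 10⁻¹².

Model comparison uses F = MST/MSE, where

* MST = mean over observed points of the squared difference between the
  two models' fitted values (a per-point between-model mean square), and
* MSE = unbiased residual variance of the richer model, SSE/(n − p).

Degrees of freedom follow the nested-model convention: numerator = the
difference in parameter counts (3 for cubic-or-log vs constant, 4 vs
zero), denominator = n − p of the richer model. The candidate is accepted
when F exceeds the upper-α F quantile at those degrees of freedom;
α defaults to 10⁻⁴, whose critical value at (3, large) rounds to 7.
Degenerate cases are snapped relative to the data scale: a perfect richer
fit reports F = +∞ (significant); identical fits report F = 0 (not
significant).

This statistic is deliberately conservative. Under the null its numerator
is the mean (not the per-degree-of-freedom mean) of the projection of the
noise onto the extra model directions, so F is roughly (df_num/n) times a
classical F ratio; measured false-positive rates on constant-trend
Gaussian series are far below α (0 of 10,000 replicates in the acceptance
run). Power against genuine trends is nevertheless enormous because MST
grows with the trend amplitude while MSE estimates only the noise — the
regime the selection is designed for.

Selection policy: if neither cubic nor logarithmic is significant against
the constant baseline, the parameter is treated as constant. Otherwise
`policy="log"` (default) imputes every such parameter with the logarithmic
model — one uniform, monotone, extrapolation-safe family — while
`policy="best-rms"` takes the lower RMS residual. Candidates whose fits
fail are demoted, never fatal.

## Imputation

All methods compute statistics from observed cells only, never modify an
observed cell, and record per-cell provenance. Non-finite observed values
are treated as missing.

* **Mean substitution** preserves each column's mean exactly and can only
  shrink its SD — appropriate for the non-dynamical harvest layout.
* **Random substitution** draws uniformly from the observed [min, max] of
  each column; it is the deliberately uninformative control.
* **Regression imputation** (time-series layout only) fills each missing
  (culture, parameter, day) cell with the selected trend model's
  prediction at that day. `per_culture_offset=True` adds the culture's
  mean observed residual, centring the pooled curve on that culture;
  the pooled curve is the default since the dominant signal is the shared
  temporal trend.

## The synthetic benchmark

The generator emulates the structure of a proprietary CHO-bioprocess
database at its published scale; defaults are frozen as the study
conditions.

* **Harvest table**: 90 cultures × 15 anonymised parameters (A–O).
  The parameter block is a rank-2 factor model — loadings uniform in
  ±[0.5, 1.5], unit-variance factors, isotropic noise SD 0.05, baselines
  uniform in [5, 50] — so the first two principal components carry > 99%
  of its variance, matching the PCA behaviour reported for the real data.
  Harvest days are uniform integers in [4, 19]. Product titre is a fixed
  weighted sum of five driver parameters (D, G, L, M, N) plus Gaussian
  noise with SD 0.8, calibrated so a titre model on complete data attains
  R² ≈ 0.95, the explanatory power reported for the study's regression
  models. Mini-studies use the 36-culture complete subset.
* **Time series**: 75 cultures × 14 parameters × days 0–13. Each
  parameter follows a fixed trend (twelve logarithmic — rising and
  falling — and two constant, H and O, mirroring the constant-only
  parameters of the study) plus a Gaussian culture-level offset
  (inter-batch variability) and Gaussian measurement noise, both a few
  percent of the curve's range.
* **MCAR amputation**: exactly round(fraction × maskable cells) cells
  deleted uniformly without replacement, ground truth retained.
  Identifier, day and (by default) product columns are never maskable —
  the workflow imputes predictors and models the product. The deletion
  mechanism is MCAR only; MAR/MNAR mechanisms are out of scope because
  the benchmark experiments delete at random.

What the generator does **not** emulate: mechanistic culture kinetics,
realistic units for the anonymised parameters, heteroscedastic or
drifting noise, structured (instrument-outage-like) missingness, and any
departure from the low-rank parameter covariance. Passing tests show the
workflow behaves correctly under the stated statistical structure, not
that real databases share that structure.

## Multigene symbolic regression

The titre model is w₀ + Σᵢ wᵢ·gᵢ(x): each gene gᵢ is an expression tree
over parameter terminals, ephemeral constants in [−10, 10] and the
function set {+, −, ×, protected ÷} (÷ returns 1 when |denominator| <
10⁻¹²); the weights are re-fitted by ordinary least squares at every
evaluation (tiny-ridge fallback for singular systems), so evolution
searches only the nonlinear feature space. A bare terminal has depth 1,
which makes a maximum depth of 1 meaningful (bare-parameter genes).
Evolution is generational: tournament selection (size 4), subtree or
whole-gene crossover (rate 0.85, offspring exceeding the depth limit
revert to the first parent), subtree/constant/gene-add/gene-delete
mutation (rate 0.1), elitism on. Fitness is the training RMSE (TRE);
fitness values are memoised on tree structure within a run. Individuals
whose gene outputs overflow to non-finite values receive infinite
fitness. Everything is driven by a single seeded generator, so runs are
bit-reproducible.

Metrics: TEE is the test-set RMSE; TEE − TRE measures overfitting;
|Δ(TEE − TRE)| against the complete-data run with the same setting, split
and seed measures how much an imputation method perturbs downstream
modelling. A parameter counts as *used* by a model when it appears in a
gene with non-negligible (> 10⁻¹⁰) weight; recurrence over 50 reseeded
runs tallies these sets. The hyper-parameter grid is population
{5, 50, 500, 5000} × generations {5, 50, 500, 5000} × genes
{1, 2, 3, 4, 10} × depth {1, 2, 3, 4, 5, 10} (480 points); settings
studies sample grid points uniformly without replacement, 38 by default.
PRESS-style cross-validation accumulates squared held-out residuals over
ten resampled splits; adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with
p = mean gene count + 1, reported as undefined when n − p − 1 ≤ 0.

## The deletion mini-study and its direction

One MCAR mask per gap fraction is shared by all imputers; every SR setting
runs on the complete table and each imputed variant with identical splits
and run seeds, so arm differences are attributable to imputation alone.
Directional claims average ten harness seeds because single SR runs are
stochastic; the repeated studies use a reduced 10-setting grid drawn from
the fast corner of the full grid (population {5, 50} × generations
{5, 50} × genes {1, 2, 3} × depth {1, 2}).

Two aggregate comparisons are computed and they genuinely differ:

* **Error-magnitude similarity** — grid-average |TRE − TRE_complete| +
  |TEE − TEE_complete|. Mean substitution tracks the complete-data
  baseline substantially better than random substitution (the headline
  direction; ~90% of harness seeds at 20.2% gaps).
* **Overfit-gap delta** — grid-average |Δ(TEE − TRE)|. This metric is
  ambiguous and, with well-converged SR runs, tends to *favour* random
  filling: random fills inflate the training error (the subtrahend) along
  with the test error, so their difference can sit closer to the
  complete-data gap even while both error magnitudes are far worse. The
  harness reports it but does not treat it as evidence for an imputer.

On this generator's strongly collinear parameter block, mean substitution
— which pins imputed cells at column means, off the factor plane — can
hurt converged titre models more than random noise does; the PRESS
adjusted-R² ordering between mean- and random-filled variants is
accordingly unstable here and is reported as computed rather than
asserted. This is a known limitation of the low-rank benchmark, not a
property claimed for real data.

The training-fraction study repeats runs at training fractions
{0.67, 0.85, 0.90} (24/12, 31/5 and 32/4 of 36 cultures) and reports each
variant's mean overfit and its change relative to the smallest fraction.

## PCA bias diagnostics

Variants are pooled, columns centred and scaled by pooled statistics (the
anonymised parameters have incommensurate units), and principal axes are
fitted once on the pooled matrix; each variant is then projected on those
shared axes. "No evident clustering" is operationalised as the largest
pairwise distance between variant centroids in the PC1–PC2 plane, in
units of the pooled PC-score SD, with 0.5 as the default threshold of
concern. Note that pooling an imputed variant legitimately dilutes the
top-2 variance share below the generator's > 99% (imputed cells lie off
the rank-2 plane); the > 99% property applies to the complete table.

## Temporal segmentation clustering

A from-scratch implementation honouring the conventional merge/extension
threshold interface (m = e = 0.5 defaults). Day-mean parameter profiles
are standardised; day-to-day profile changes (RMS over parameters) are
normalised by their maximum; a greedy left-to-right scan starts a new
segment where the normalised change exceeds threshold × e. Boundary sets
are therefore nested in the threshold and segment counts weakly decrease.
Parameters are represented by per-segment means of their standardised
profiles and merged agglomeratively (average linkage, Pearson-correlation
similarity, lexicographic tie-breaks) while the best inter-cluster
similarity is ≥ m. Sweeping the segmentation threshold and classifying
each parameter pair as always/sometimes/never co-clustered identifies
groups that share a trend throughout the culture — candidates for
monitoring a single representative. The default sweep (0.05–1.0) stops
short of the degenerate single-segment regime, where one-point profiles
make every pair trivially similar. The stage refuses input with gaps by
design: it is the gap-intolerant downstream consumer that motivates
imputation in the first place.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full workflow at the
study's published scale for data generation (90/36 cultures × 15
parameters; 75 × 14 × 14 time series) and use 10-setting reduced SR grids,
10 harness seeds, 10,000 F-test replicates, 50 recurrence runs and
10-split PRESS resampling for the repeated studies — sizes chosen so each
claim is measured with comfortable statistical margin. Tolerances:
exact-arithmetic claims at 10⁻¹²–10⁻⁹, least-squares oracle agreement at
10⁻⁶ relative, noiseless recovery at 10⁻⁶–10⁻⁵, directional claims at
≥ 8 of 10 seeds. Tiny-magnitude round-off in the F statistic is snapped
to the exact-zero cases relative to the data scale (10⁻¹⁸ × mean square).
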