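# biogapfill

Heuristic missing-data handling for biologics manufacturing databases.

Historical bioprocess databases — daily readings and harvest-day records
from years of monoclonal-antibody production in CHO cell cultures — are
riddled with gaps from instrument changes, inconsistent sampling and
operator error. Downstream mining (predictive titre models, clustering of
parameter time courses) either cannot run on incomplete tables or is
silently biased by how the gaps were filled. `biogapfill` implements a
complete workflow for choosing and validating simple single-imputation
strategies on such data:

* **Mean substitution** for smooth, non-dynamical harvest-day tables: each
  missing cell gets its variable's observed mean.
* **Bounded random substitution** as the uninformative control: uniform
  draws between each variable's observed minimum and maximum.
* **Trend-regression imputation** for dynamical time series: per parameter,
  a cubic trend Y = ax³ + bx² + cx + d and a logarithmic trend
  Y = a·ln(bx + c) + d are fitted by least squares (RMS-residual
  objective, nonlinear search started from coefficients of 10) and each is
  compared against the constant baseline Y = d by a robust F statistic
  F = MST/MSE at α = 10⁻⁴, whose critical value at (3, large) degrees of
  freedom rounds to 7. Gaps are filled with the selected model's
  prediction at the missing day.

The package also ships the full evaluation harness used to judge these
choices on data with known ground truth:

* a synthetic CHO-bioprocess generator (90-culture × 15-parameter
  harvest tables with a rank-2 parameter block; 75-culture × 14-parameter
  × 14-day time series with logarithmic/cubic/constant trends) plus MCAR
  amputation at any gap fraction;
* multigene evolutionary symbolic regression (genes combined by
  least-squares weights) predicting product titre, with the TEE − TRE
  train/test error gap as the overfitting measure, a 480-point
  hyper-parameter grid, 50-run parameter-recurrence tallies and
  PRESS-style cross-validation with adjusted R²;
* controlled deletion mini-studies (delete → impute → model → compare
  against the complete-data baseline with shared masks, splits and seeds),
  PCA bias diagnostics on shared axes, and a training-fraction study;
* temporal segmentation clustering of the imputed time series (merge and
  extension thresholds m = e = 0.5 by default) that classifies parameter
  pairs by how robustly they co-cluster across a threshold sweep.

## Worked example

```python
import biogapfill as bg
from biogapfill.harness import SMALL_GRID_DOMAIN

# a complete 36-culture harvest table, then 20.2% MCAR amputation
table = bg.generate_harvest_table(bg.GeneratorConfig(seed=1, n_cultures=36))
masked = bg.inject_gaps(table, 0.202, seed=7)
print(f"masked {masked.n_masked} of {masked.mask.size} cells ({masked.gap_fraction:.1%})")

# delete -> impute -> model: same masks, splits and seeds for every arm
study = bg.deletion_experiment(table, 0.202, n_settings=10,
                               grid_domain=SMALL_GRID_DOMAIN, seed=0)
print(study.summary())
print("error similarity:", study.error_similarity().round(3).to_dict())
```

```
masked 109 of 540 cells (20.2%)
Deletion mini-study at 20.2% MCAR gaps
  complete: mean TRE=0.9718  TEE=1.19  overfit=0.2183  |delta vs complete|=0
      mean: mean TRE=1.24  TEE=1.283  overfit=0.04332  |delta vs complete|=0.2751
    random: mean TRE=1.63  TEE=2.115  overfit=0.4846  |delta vs complete|=0.525
error similarity: {'mean': 0.408, 'random': 1.583}
```

109 cells is exactly round(0.202 × 540). The mini-study trains the same
ten symbolic-regression settings on the complete table and on both imputed
variants; the grid-average training/testing errors of the mean-imputed
table stay much closer to the complete-data baseline (error similarity
0.41) than the random-filled table's (1.58) — random filling also shows
the largest overfitting gap (0.48).

Trend selection on a time series works through the model front end:

```python
ts = bg.generate_time_series(bg.GeneratorConfig(n_cultures=75, seed=2))
days, values, _ = ts.parameter_series("D")
sel = bg.TrendModel(days, values).fit_select()
print("selected:", sel.selected.kind, "|", sel.selected.equation())
```

```
selected: logarithmic | Y = 20.09 ln(9.551 x + 18.23) + 19.92
```

`bg.model_selection_report(ts)` produces the per-parameter table (RMS
residuals and F statistics against the constant and zero baselines for
both candidates, plus the selection); constant-only parameters such as the
generator's H and O are reported as `constant`.

A thin CLI mirrors the stages: `biogapfill generate | impute |
trend-report | sr | evaluate | cluster` (see `--help` of each).

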