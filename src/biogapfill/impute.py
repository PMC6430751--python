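"""Single-imputation methods: mean, bounded-random and trend-regression.

All three methods share the same contract: observed cells are never
modified, every missing cell in a maskable column is filled, and the
result records which cells were imputed and from what.  Column statistics
(mean, min, max) are always computed from observed cells only; non-finite
observed values are treated as missing.

* ``mean_substitute`` fills each gap with its column's observed mean —
  adequate for smooth, non-dynamical tables such as harvest-day records.
* ``random_substitute`` draws uniformly between the column's observed
  minimum and maximum — the deliberately uninformative control used to
  benchmark the other methods.
* ``regression_impute`` fits a temporal trend per parameter (constant /
  cubic / logarithmic, selected by robust F test) and fills each gap with
  the model's prediction at that day — appropriate for dynamical
  time-series tables, where mean substitution would flatten the trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DAY_COL, ID_COL, CultureTable, MaskedDataset, TimeSeriesTable
from .trends import InfeasibleFitError, TrendFit, fit_constant, select_trend_model


class FullyMissingColumnError(ValueError):
    """A maskable column has no observed values to estimate from."""


@dataclass
class ImputationResult:
    """A filled table plus full provenance of every imputed cell."""

    filled: object  # CultureTable or TimeSeriesTable, gap-free
    mask: pd.DataFrame  # True where a cell was imputed
    method: str
    per_parameter_models: dict = field(default_factory=dict)
    seed: int | None = None
    sources: dict = field(default_factory=dict)  # column -> description string

    def provenance(self) -> pd.DataFrame:
        """One row per imputed cell: location, method and source."""
        rows = []
        for col in self.mask.columns:
            where = self.mask.index[self.mask[col]]
            src = self.sources.get(col, self.method)
            for idx in where:
                rows.append({"row": idx, "column": col, "method": self.method, "source": src})
        return pd.DataFrame(rows, columns=["row", "column", "method", "source"])


def _unwrap(table):
    return table.table if isinstance(table, MaskedDataset) else table


def _block_and_mask(table):
    """Maskable block with non-finite entries demoted to missing."""
    block = table.data[table.param_columns].copy()
    finite = block.apply(lambda s: np.isfinite(s.astype(float)), axis=0)
    block = block.where(finite)
    mask = table.mask | ~finite
    return block, mask


def mean_substitute(table) -> ImputationResult:
    """Fill every gap with its column's observed arithmetic mean."""
    table = _unwrap(table)
    block, mask = _block_and_mask(table)
    sources = {}
    for col in block.columns:
        obs = block[col][~mask[col]]
        if obs.empty:
            raise FullyMissingColumnError(f"column {col!r} has no observed values")
        mean = float(obs.mean())
        block.loc[mask[col], col] = mean
        sources[col] = f"column mean {mean:.6g}"
    filled = table.copy()
    filled.data[table.param_columns] = block
    filled.mask = mask & False
    return ImputationResult(filled, mask, "mean", sources=sources)


def random_substitute(table, seed: int) -> ImputationResult:
    """Fill every gap with a uniform draw from [observed min, observed max]."""
    table = _unwrap(table)
    rng = np.random.default_rng(seed)
    block, mask = _block_and_mask(table)
    sources = {}
    for col in block.columns:
        obs = block[col][~mask[col]]
        if obs.empty:
            raise FullyMissingColumnError(f"column {col!r} has no observed values")
        lo, hi = float(obs.min()), float(obs.max())
        n_gap = int(mask[col].sum())
        if n_gap:
            block.loc[mask[col], col] = rng.uniform(lo, hi, size=n_gap)
        sources[col] = f"uniform[{lo:.6g}, {hi:.6g}]"
    filled = table.copy()
    filled.data[table.param_columns] = block
    filled.mask = mask & False
    return ImputationResult(filled, mask, "random", seed=seed, sources=sources)


def regression_impute(
    ts,
    policy: str = "log",
    alpha: float = 1e-4,
    per_culture_offset: bool = False,
) -> ImputationResult:
    """Fill time-series gaps with per-parameter trend-model predictions.

    For each parameter a trend model is selected on the pooled observed
    (day, value) points; each missing cell is filled with the model's
    prediction at its day.  With ``per_culture_offset`` the culture's mean
    observed residual is added to the prediction, centring the pooled curve
    on that culture; the default uses the pooled curve directly.
    Parameters whose nonlinear fits fail fall back to the constant model.
    """
    ts = _unwrap(ts)
    if not isinstance(ts, TimeSeriesTable):
        raise TypeError("regression imputation operates on the time-series layout")
    block, mask = _block_and_mask(ts)
    days_all = block.index.get_level_values(DAY_COL).to_numpy(dtype=float)
    ids_all = block.index.get_level_values(ID_COL).to_numpy()

    models: dict[str, TrendFit] = {}
    sources = {}
    for col in block.columns:
        obs_mask = ~mask[col].to_numpy()
        if not obs_mask.any():
            raise FullyMissingColumnError(f"column {col!r} has no observed values")
        obs_days = days_all[obs_mask]
        obs_vals = block[col].to_numpy(dtype=float)[obs_mask]
        try:
            fit = select_trend_model(obs_days, obs_vals, alpha=alpha, policy=policy).selected
        except InfeasibleFitError:
            fit = fit_constant(obs_days, obs_vals)
        models[col] = fit
        sources[col] = fit.equation()

        gap_mask = mask[col].to_numpy()
        if gap_mask.any():
            pred = fit.predict(days_all[gap_mask])
            if per_culture_offset:
                resid = obs_vals - fit.predict(obs_days)
                offsets = pd.Series(resid).groupby(ids_all[obs_mask]).mean()
                pred = pred + np.array(
                    [offsets.get(cid, 0.0) for cid in ids_all[gap_mask]]
                )
            vals = block[col].to_numpy(dtype=float)
            vals[gap_mask] = pred
            block[col] = vals

    filled = ts.copy()
    filled.data[ts.param_columns] = block
    filled.mask = mask & False
    return ImputationResult(filled, mask, "regression", per_parameter_models=models, sources=sources)
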