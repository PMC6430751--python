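"""Per-parameter temporal trend models with robust F-test model selection.

Daily bioprocess parameter readings tend to follow either a third-degree
polynomial trend

    Y = a x^3 + b x^2 + c x + d

or a logarithmic trend

    Y = a ln(b x + c) + d,

with x the day of sampling.  Both candidates are fitted by least squares
(minimising the RMS residual), and each is compared against the
constant-only baseline Y = d (and optionally the null Y = 0) with a robust
F statistic

    F = MST / MSE,

where MST is the mean over observed points of the squared difference
between the two models' fitted values and MSE is the unbiased residual
variance of the richer model.  A candidate is retained only when F exceeds
the upper-``alpha`` F quantile (alpha defaults to 1e-4, whose critical
value at 3 numerator and large denominator degrees of freedom rounds to 7).
When neither candidate beats the constant baseline the parameter is treated
as constant over time; otherwise the selection policy is either the
lowest-RMS candidate or — the convention adopted for the study this
mirrors — always the logarithmic model.

Usage follows the Model/Results convention::

    fit = TrendModel(days, values).fit("cubic")        # -> TrendFit
    sel = TrendModel(days, values).fit_select()        # -> TrendSelection
    sel.selected.predict([0, 5, 13])
    print(sel.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import TimeSeriesTable

#: free parameters per model kind (constant estimates d only; zero estimates nothing)
N_PARAMS = {"cubic": 4, "logarithmic": 4, "constant": 1, "zero": 0}

_LOG_EPS = 1e-6  # feasibility floor for b*x + c on the day range


class DegenerateDesignError(ValueError):
    """Too few distinct design points to fit the requested model."""


class InfeasibleFitError(RuntimeError):
    """No feasible (b, c) region found for the logarithmic model."""


@dataclass
class TrendFit:
    """A fitted trend model: coefficients, RMS residual and the data it saw."""

    kind: str
    a: float
    b: float
    c: float
    d: float
    rms_residual: float
    n_points: int
    days: np.ndarray = field(repr=False, default=None)
    values: np.ndarray = field(repr=False, default=None)

    @property
    def n_model_params(self) -> int:
        return N_PARAMS[self.kind]

    @property
    def coefficients(self) -> tuple:
        return (self.a, self.b, self.c, self.d)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "cubic":
            return self.a * x**3 + self.b * x**2 + self.c * x + self.d
        if self.kind == "logarithmic":
            return self.a * np.log(np.maximum(self.b * x + self.c, _LOG_EPS)) + self.d
        if self.kind == "constant":
            return np.full_like(x, self.d, dtype=float)
        return np.zeros_like(x, dtype=float)

    @property
    def fitted_values(self) -> np.ndarray:
        return self.predict(self.days)

    @property
    def sse(self) -> float:
        return float(self.n_points * self.rms_residual**2)

    def equation(self) -> str:
        if self.kind == "cubic":
            return f"Y = {self.a:.4g} x^3 + {self.b:.4g} x^2 + {self.c:.4g} x + {self.d:.4g}"
        if self.kind == "logarithmic":
            return f"Y = {self.a:.4g} ln({self.b:.4g} x + {self.c:.4g}) + {self.d:.4g}"
        if self.kind == "constant":
            return f"Y = {self.d:.4g}"
        return "Y = 0"


@dataclass
class FTestResult:
    """One robust F comparison of a richer model against a baseline."""

    f_stat: float
    critical_value: float
    alpha: float
    df_num: int
    df_den: int
    significant: bool


def _as_clean_arrays(days, values):
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(days) & np.isfinite(values)
    return days[keep], values[keep]


def fit_constant(days, values) -> TrendFit:
    """Least-squares constant fit: d equals the mean of observed values."""
    days, values = _as_clean_arrays(days, values)
    if values.size == 0:
        raise ValueError("need at least one observed point")
    d = float(values.mean())
    rms = float(np.sqrt(np.mean((values - d) ** 2)))
    return TrendFit("constant", 0.0, 0.0, 0.0, d, rms, values.size, days, values)


def fit_zero(days, values) -> TrendFit:
    """The null model Y = 0 (no estimated parameters)."""
    days, values = _as_clean_arrays(days, values)
    rms = float(np.sqrt(np.mean(values**2))) if values.size else 0.0
    return TrendFit("zero", 0.0, 0.0, 0.0, 0.0, rms, values.size, days, values)


def fit_cubic(days, values) -> TrendFit:
    days, values = _as_clean_arrays(days, values)
    if np.unique(days).size < 4:
        raise DegenerateDesignError("cubic fit needs >= 4 distinct days")
    a, b, c, d = np.polyfit(days, values, 3)
    pred = np.polyval([a, b, c, d], days)
    rms = float(np.sqrt(np.mean((values - pred) ** 2)))
    return TrendFit("cubic", float(a), float(b), float(c), float(d), rms, values.size, days, values)


def _log_residuals(theta, days, values):
    a, b, c, d = theta
    arg = b * days + c
    feasible = np.maximum(arg, _LOG_EPS)
    res = a * np.log(feasible) + d - values
    # one appended residual penalising constraint violation keeps the
    # optimiser inside b*x + c > 0 without hard bounds
    penalty = 1e3 * np.sum(np.maximum(_LOG_EPS - arg, 0.0))
    return np.concatenate([res, [penalty]])


def _log_fit_from(x0, days, values):
    sol = optimize.least_squares(
        _log_residuals, x0, args=(days, values), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
    )
    a, b, c, d = sol.x
    if np.any(b * days + c <= 0):
        return None
    pred = a * np.log(b * days + c) + d
    rms = float(np.sqrt(np.mean((values - pred) ** 2)))
    return (float(a), float(b), float(c), float(d)), rms


def fit_logarithmic(days, values) -> TrendFit:
    """Nonlinear least squares for Y = a ln(b x + c) + d.

    Starts at (10, 10, 10, 10); if that run fails, degrades to worse than
    the constant fit, or lands infeasibly, a coarse multi-start over signed
    log-spaced coefficients is tried and the best feasible solution kept.
    The (b, c) pair is only identified up to a common scaling absorbed by
    d, so fits are judged at curve level.
    """
    days, values = _as_clean_arrays(days, values)
    if values.size < 4:
        raise DegenerateDesignError("logarithmic fit needs >= 4 observed points")

    best = _log_fit_from(np.array([10.0, 10.0, 10.0, 10.0]), days, values)
    const_rms = fit_constant(days, values).rms_residual
    if best is None or best[1] > const_rms + 1e-12:
        starts = [np.array([0.0, 1.0, 1.0, float(values.mean())])]
        for a0 in (-10.0, -1.0, 1.0, 10.0):
            for b0 in (0.1, 1.0, 10.0):
                for c0 in (0.5, 1.0, 10.0):
                    starts.append(np.array([a0, b0, c0, float(values.mean())]))
        for x0 in starts:
            cand = _log_fit_from(x0, days, values)
            if cand is not None and (best is None or cand[1] < best[1]):
                best = cand
    if best is None:
        raise InfeasibleFitError("no feasible logarithmic fit found")
    (a, b, c, d), rms = best
    return TrendFit("logarithmic", a, b, c, d, rms, values.size, days, values)


def robust_f_test(model_fit: TrendFit, baseline_fit: TrendFit, alpha: float = 1e-4) -> FTestResult:
    """Robust F = MST/MSE comparison of a richer model against a baseline.

    MST is the mean squared difference between the two fitted-value sets;
    MSE is the richer model's unbiased residual variance, SSE/(n - p).
    Degrees of freedom follow the nested-model convention: numerator = the
    difference in parameter counts, denominator = n - p of the richer model.
    """
    if model_fit.n_points != baseline_fit.n_points:
        raise ValueError("fits must be computed on the same observed points")
    n = model_fit.n_points
    p_rich = model_fit.n_model_params
    df_num = p_rich - baseline_fit.n_model_params
    df_den = n - p_rich
    if df_num <= 0 or df_den <= 0:
        raise ValueError("baseline must be nested in a richer model with n > p")

    mst = float(np.mean((model_fit.fitted_values - baseline_fit.fitted_values) ** 2))
    mse = model_fit.sse / df_den
    # snap round-off to the exact-zero cases: a perfect fit reports F = inf,
    # identical fits report F = 0
    tol = 1e-18 * max(float(np.mean(model_fit.values**2)), 1.0)
    if mse <= tol:
        f_stat = 0.0 if mst <= tol else np.inf
    else:
        f_stat = mst / mse
    crit = float(stats.f.isf(alpha, df_num, df_den))
    return FTestResult(float(f_stat), crit, alpha, df_num, df_den, bool(f_stat > crit))


@dataclass
class TrendSelection:
    """Result of fitting all candidate trends and selecting one."""

    selected: TrendFit
    fits: dict
    f_vs_constant: dict
    f_vs_zero: dict
    policy: str
    alpha: float

    def summary(self) -> pd.DataFrame:
        rows = []
        for kind in ("cubic", "logarithmic"):
            fit = self.fits.get(kind)
            if fit is None:
                continue
            fc = self.f_vs_constant.get(kind)
            fz = self.f_vs_zero.get(kind)
            rows.append(
                {
                    "model": kind,
                    "rms_residual": fit.rms_residual,
                    "f_vs_constant": fc.f_stat if fc else np.nan,
                    "f_vs_zero": fz.f_stat if fz else np.nan,
                    "significant_vs_constant": fc.significant if fc else False,
                    "selected": kind == self.selected.kind,
                }
            )
        if self.selected.kind == "constant":
            rows.append(
                {
                    "model": "constant",
                    "rms_residual": self.fits["constant"].rms_residual,
                    "f_vs_constant": np.nan,
                    "f_vs_zero": np.nan,
                    "significant_vs_constant": False,
                    "selected": True,
                }
            )
        return pd.DataFrame(rows)


def select_trend_model(days, values, alpha: float = 1e-4, policy: str = "log") -> TrendSelection:
    """Fit constant, cubic and logarithmic trends and pick one.

    Candidates failing to fit are demoted rather than aborting.  If neither
    cubic nor logarithmic is significant against the constant baseline, the
    constant model is selected.  Otherwise ``policy`` decides among the
    significant candidates: ``"log"`` prefers the logarithmic model
    whenever it is significant (the convenient uniform choice), and
    ``"best-rms"`` takes the lower RMS residual.
    """
    if policy not in ("log", "best-rms"):
        raise ValueError(f"unknown policy {policy!r}")
    days_c, values_c = _as_clean_arrays(days, values)
    const = fit_constant(days_c, values_c)
    zero = fit_zero(days_c, values_c)
    fits = {"constant": const}
    f_const, f_zero = {}, {}
    for kind, fitter in (("cubic", fit_cubic), ("logarithmic", fit_logarithmic)):
        try:
            fit = fitter(days_c, values_c)
        except (DegenerateDesignError, InfeasibleFitError, ValueError):
            continue
        fits[kind] = fit
        if fit.n_points > fit.n_model_params:
            f_const[kind] = robust_f_test(fit, const, alpha)
            f_zero[kind] = robust_f_test(fit, zero, alpha)

    significant = [k for k in ("cubic", "logarithmic") if f_const.get(k) and f_const[k].significant]
    if not significant:
        selected = const
    elif policy == "log" and "logarithmic" in significant:
        selected = fits["logarithmic"]
    elif policy == "log":
        selected = fits[significant[0]]
    else:
        selected = min((fits[k] for k in significant), key=lambda f: f.rms_residual)
    return TrendSelection(selected, fits, f_const, f_zero, policy, alpha)


class TrendModel:
    """Trend model for one parameter's pooled (day, value) observations.

    Pooling all cultures' points for a parameter is the default analysis
    unit; construct per-culture models from per-culture slices if needed.
    """

    def __init__(self, days, values):
        self.days, self.values = _as_clean_arrays(days, values)
        if self.values.size == 0:
            raise ValueError("need at least one observed point")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, day_col: str = "day", value_col: str = "value"):
        return cls(df[day_col].to_numpy(float), df[value_col].to_numpy(float))

    def fit(self, kind: str = "logarithmic") -> TrendFit:
        fitters = {
            "constant": fit_constant,
            "cubic": fit_cubic,
            "logarithmic": fit_logarithmic,
            "zero": fit_zero,
        }
        if kind not in fitters:
            raise ValueError(f"unknown trend kind {kind!r}")
        return fitters[kind](self.days, self.values)

    def fit_select(self, alpha: float = 1e-4, policy: str = "log") -> TrendSelection:
        return select_trend_model(self.days, self.values, alpha=alpha, policy=policy)


def model_selection_report(
    ts: TimeSeriesTable, alpha: float = 1e-4, policy: str = "log"
) -> pd.DataFrame:
    """Per-parameter model-selection table (one row per parameter).

    Columns mirror the classic report layout: RMS residual and F statistics
    against the constant and zero baselines for both the cubic and
    logarithmic candidates, plus the selected model kind.
    """
    rows = []
    for param in ts.param_columns:
        days, values, _ = ts.parameter_series(param)
        sel = select_trend_model(days, values, alpha=alpha, policy=policy)

        def _get(table, kind, attr):
            entry = table.get(kind)
            return getattr(entry, attr) if entry is not None else np.nan

        rows.append(
            {
                "parameter": param,
                "cubic_rms": _get(sel.fits, "cubic", "rms_residual"),
                "cubic_f_vs_constant": _get(sel.f_vs_constant, "cubic", "f_stat"),
                "cubic_f_vs_zero": _get(sel.f_vs_zero, "cubic", "f_stat"),
                "log_rms": _get(sel.fits, "logarithmic", "rms_residual"),
                "log_f_vs_constant": _get(sel.f_vs_constant, "logarithmic", "f_stat"),
                "log_f_vs_zero": _get(sel.f_vs_zero, "logarithmic", "f_stat"),
                "selected": sel.selected.kind,
            }
        )
    return pd.DataFrame(rows)
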