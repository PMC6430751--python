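"""Synthetic CHO-bioprocess data with known ground truth.

Real antibody-manufacturing databases are proprietary, so every downstream
stage of this package is exercised on generated data that reproduces the
structure such databases exhibit:

* a wide *harvest-day* table — one multivariate record per culture taken on
  its (uniformly drawn) harvest day, with a low-rank parameter block and a
  product titre driven by a designated subset of parameters;
* a long *time-series* table — daily readings per culture and parameter,
  each parameter following a logarithmic, cubic or constant temporal trend
  with a Gaussian culture-level offset and Gaussian measurement noise;
* MCAR amputation: uniform deletion of a prescribed fraction of cells,
  retaining the deleted values as ground truth.

Defaults mirror the study conditions: 90 cultures x 15 parameters (A-O)
for the harvest table; 75 cultures x 14 parameters x 14 days (days 0-13)
for the time series, with parameters H and O constant over time and the
rest logarithmic.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DAY_COL, HARVEST_COL, ID_COL, PRODUCT_COL, CultureTable, MaskedDataset, TimeSeriesTable

HARVEST_PARAMS = list(string.ascii_uppercase[:15])  # A..O
TIMESERIES_PARAMS = [p for p in HARVEST_PARAMS if p != "B"]  # 14 parameters


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass
class TrendSpec:
    """Temporal trend of one parameter.

    kind ``cubic``: Y = a x^3 + b x^2 + c x + d;
    kind ``logarithmic``: Y = a ln(b x + c) + d  (requires b x + c > 0 on the
    day axis, checked at day 0 and every other day);
    kind ``constant``: Y = d.

    ``noise_sd`` is the per-reading Gaussian measurement noise;
    ``offset_sd`` the standard deviation of the culture-level additive
    offset representing inter-batch variability.
    """

    kind: str
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    noise_sd: float = 0.0
    offset_sd: float = 0.0

    def __post_init__(self):
        if self.kind not in ("cubic", "logarithmic", "constant"):
            raise ConfigurationError(f"unknown trend kind {self.kind!r}")
        if self.noise_sd < 0 or self.offset_sd < 0:
            raise ConfigurationError("noise_sd and offset_sd must be >= 0")

    def validate_on(self, day_axis, name: str = "?") -> None:
        if self.kind == "logarithmic":
            x = np.asarray(day_axis, dtype=float)
            if np.any(self.b * x + self.c <= 0):
                raise ConfigurationError(
                    f"logarithmic spec for parameter {name!r} violates b*x + c > 0 on the day axis"
                )

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "cubic":
            return self.a * x**3 + self.b * x**2 + self.c * x + self.d
        if self.kind == "logarithmic":
            return self.a * np.log(self.b * x + self.c) + self.d
        return np.full_like(x, self.d, dtype=float)


def default_trend_specs() -> dict:
    """One spec per time-series parameter: H and O constant, the rest logarithmic.

    Coefficients are fixed arbitrary values spanning rising and falling
    log-like time courses at roughly unit-to-tens magnitudes; noise and
    offset SDs are a few percent of each curve's dynamic range.
    """
    specs = {}
    rising = [
        ("A", 12.0, 1.0, 1.0, 30.0, 1.2),
        ("C", 8.0, 2.0, 1.0, 60.0, 0.9),
        ("D", 20.0, 0.8, 1.5, 70.0, 1.5),
        ("E", 0.8, 1.0, 1.0, 5.0, 0.07),
        ("F", 15.0, 0.5, 2.0, 16.0, 1.1),
        ("G", 2.5, 1.5, 1.0, 7.0, 0.2),
        ("I", 0.15, 1.0, 1.0, 0.5, 0.012),
        ("K", 1.4, 1.2, 1.0, 4.0, 0.11),
    ]
    falling = [
        ("J", -1.1, 1.0, 1.0, 7.2, 0.09),
        ("L", -1.8, 0.7, 1.0, 14.0, 0.15),
        ("M", -45.0, 1.0, 1.0, 300.0, 4.0),
        ("N", -18.0, 1.3, 1.0, 110.0, 1.6),
    ]
    for name, a, b, c, d, sd in rising + falling:
        specs[name] = TrendSpec("logarithmic", a=a, b=b, c=c, d=d, noise_sd=sd, offset_sd=sd)
    specs["H"] = TrendSpec("constant", d=36.8, noise_sd=0.3, offset_sd=0.3)
    specs["O"] = TrendSpec("constant", d=330.0, noise_sd=3.0, offset_sd=3.0)
    return specs


def default_titre_drivers() -> dict:
    """Parameters driving product titre, with their weights."""
    return {"D": 1.5, "G": -1.0, "L": 0.8, "M": 1.2, "N": -0.6}


@dataclass
class GeneratorConfig:
    n_cultures: int = 90
    n_params: int = 15
    day_axis: tuple = tuple(range(14))
    harvest_day_range: tuple = (4, 19)
    trend_specs: dict = field(default_factory=default_trend_specs)
    titre_drivers: dict = field(default_factory=default_titre_drivers)
    titre_noise_sd: float = 0.8
    latent_rank: int = 2
    harvest_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_cultures <= 0 or self.n_params <= 0 or self.latent_rank <= 0:
            raise ConfigurationError("dimensions must be positive")
        if self.titre_noise_sd < 0 or self.harvest_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if not self.titre_drivers:
            raise ConfigurationError("titre_drivers must be non-empty")
        if not all(np.isfinite(list(self.titre_drivers.values()))):
            raise ConfigurationError("driver weights must be finite")
        lo, hi = self.harvest_day_range
        if hi < lo:
            raise ConfigurationError("harvest_day_range must be a non-empty interval")

    def harvest_param_names(self) -> list[str]:
        if self.n_params <= 26:
            return list(string.ascii_uppercase[: self.n_params])
        return [f"P{i:02d}" for i in range(self.n_params)]


def generate_harvest_table(config: GeneratorConfig) -> CultureTable:
    """Generate a fully observed harvest-day table.

    The parameter block follows a rank-``latent_rank`` factor model plus
    small isotropic noise (so its first two principal components carry
    essentially all variance at the default rank of 2); the product column
    is a weighted sum of the designated driver parameters plus Gaussian
    noise; harvest days are uniform on ``harvest_day_range``.
    """
    rng = np.random.default_rng(config.seed)
    n, p, r = config.n_cultures, config.n_params, config.latent_rank
    names = config.harvest_param_names()
    unknown = set(config.titre_drivers) - set(names)
    if unknown:
        raise ConfigurationError(f"titre_drivers not among parameters: {sorted(unknown)}")

    baselines = rng.uniform(5.0, 50.0, size=p)
    loadings = rng.uniform(0.5, 1.5, size=(r, p)) * rng.choice([-1.0, 1.0], size=(r, p))
    factors = rng.standard_normal((n, r))
    block = baselines + factors @ loadings + config.harvest_noise_sd * rng.standard_normal((n, p))

    lo, hi = config.harvest_day_range
    harvest_days = rng.integers(lo, hi + 1, size=n)

    df = pd.DataFrame(block, columns=names)
    product = np.zeros(n)
    for param, w in config.titre_drivers.items():
        product += w * df[param].to_numpy()
    product += config.titre_noise_sd * rng.standard_normal(n)

    df.insert(0, HARVEST_COL, harvest_days)
    df[PRODUCT_COL] = product
    df.index = pd.Index([f"CUL{i:03d}" for i in range(n)], name=ID_COL)
    return CultureTable(df, names)


def generate_time_series(config: GeneratorConfig) -> TimeSeriesTable:
    """Generate a fully observed time-series table.

    value(culture, param, day) = trend(day) + culture offset + noise,
    with the per-parameter trend, offset SD and noise SD taken from
    ``config.trend_specs``.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.day_axis, dtype=int)
    params = sorted(config.trend_specs)
    for name in params:
        config.trend_specs[name].validate_on(days, name)

    n, n_days = config.n_cultures, len(days)
    ids = [f"CUL{i:03d}" for i in range(n)]
    index = pd.MultiIndex.from_product([ids, days], names=[ID_COL, DAY_COL])
    data = {}
    for name in params:
        spec = config.trend_specs[name]
        trend = spec.evaluate(days)
        offsets = spec.offset_sd * rng.standard_normal(n)
        noise = spec.noise_sd * rng.standard_normal((n, n_days))
        data[name] = (trend[None, :] + offsets[:, None] + noise).ravel()
    return TimeSeriesTable(pd.DataFrame(data, index=index))


def inject_gaps(dataset, fraction: float, seed: int, include_product: bool = False) -> MaskedDataset:
    """Delete a fraction of maskable cells uniformly at random (MCAR).

    Exactly ``round(fraction * n_maskable_cells)`` cells are deleted,
    chosen without replacement; the deleted values are retained as ground
    truth.  Identifier and day columns are never maskable; the product
    column only when ``include_product`` is set.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    if isinstance(dataset, CultureTable):
        cols = list(dataset.param_columns) + ([PRODUCT_COL] if include_product else [])
        block = dataset.data[cols]
    elif isinstance(dataset, TimeSeriesTable):
        cols = dataset.param_columns
        block = dataset.data[cols]
    else:
        raise TypeError(f"cannot inject gaps into {type(dataset).__name__}")
    if block.isna().to_numpy().any():
        raise ValueError("dataset must be fully observed in the maskable region")

    n_cells = block.size
    n_mask = int(round(fraction * n_cells))
    flat = rng.choice(n_cells, size=n_mask, replace=False)
    mask_arr = np.zeros(n_cells, dtype=bool)
    mask_arr[flat] = True
    mask_arr = mask_arr.reshape(block.shape)

    mask = pd.DataFrame(mask_arr, index=block.index, columns=block.columns)
    ground_truth = block.where(mask)
    holed = dataset.copy()
    holed.data[cols] = block.mask(mask)
    if isinstance(holed, CultureTable):
        holed.mask = mask[dataset.param_columns].copy()
    else:
        holed.mask = mask.copy()
    return MaskedDataset(holed, mask, ground_truth, n_mask / n_cells)


def split_complete_subset(table: CultureTable) -> CultureTable:
    """Cultures with no missing values (the complete subset used for mini-studies)."""
    return table.complete_subset()
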