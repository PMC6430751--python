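"""Tabular containers for bioprocess culture data.

Two layouts are used throughout the package:

* :class:`CultureTable` — one row per culture, taken on its harvest day:
  an identifier, the harvest day, a block of anonymised process parameters
  and the final product titre.
* :class:`TimeSeriesTable` — daily readings of each parameter for each
  culture over a fixed day axis, stored wide (one row per culture-day,
  one column per parameter) and serialised long
  (``culture_id,day,parameter,value``).

Both carry an explicit boolean missingness mask over their parameter block
(``True`` = missing).  Identifier, day and (by default) product columns are
never maskable.  :class:`MaskedDataset` additionally retains the ground
truth of deliberately deleted cells so imputation error can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ID_COL = "culture_id"
DAY_COL = "day"
HARVEST_COL = "harvest_day"
PRODUCT_COL = "product"


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")


@dataclass
class CultureTable:
    """Wide harvest-day table: cultures x (harvest day, parameters, product).

    Parameters
    ----------
    data : DataFrame indexed by culture id with columns
        ``harvest_day``, the parameter columns, and ``product``.
    param_columns : names of the maskable parameter columns.
    mask : boolean DataFrame over ``param_columns`` (True = missing).
        Defaults to the NaN pattern of ``data``.
    """

    data: pd.DataFrame
    param_columns: list[str]
    mask: pd.DataFrame = None

    def __post_init__(self):
        _require_columns(self.data, [HARVEST_COL, PRODUCT_COL] + list(self.param_columns))
        if self.mask is None:
            self.mask = self.data[self.param_columns].isna()
        self.mask = self.mask.astype(bool)
        if list(self.mask.columns) != list(self.param_columns) or not self.mask.index.equals(
            self.data.index
        ):
            raise ValueError("mask must be congruent with the parameter block")

    @property
    def n_cultures(self) -> int:
        return len(self.data)

    @property
    def params(self) -> pd.DataFrame:
        """The parameter block (view)."""
        return self.data[self.param_columns]

    def complete_subset(self) -> "CultureTable":
        """Rows with zero masked cells, order preserved."""
        keep = ~self.mask.any(axis=1)
        return CultureTable(
            self.data.loc[keep].copy(),
            list(self.param_columns),
            self.mask.loc[keep].copy(),
        )

    def copy(self) -> "CultureTable":
        return CultureTable(self.data.copy(), list(self.param_columns), self.mask.copy())

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, ID_COL, out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CultureTable":
        df = pd.read_csv(path)
        _require_columns(df, [ID_COL, HARVEST_COL, PRODUCT_COL])
        df = df.set_index(ID_COL)
        params = [c for c in df.columns if c not in (HARVEST_COL, PRODUCT_COL)]
        return cls(df, params)


@dataclass
class TimeSeriesTable:
    """Per-culture daily parameter readings on a fixed day axis.

    Stored wide: ``data`` is indexed by ``(culture_id, day)`` with one
    column per parameter.  The long CSV layout
    ``culture_id,day,parameter,value`` is used for serialisation.
    """

    data: pd.DataFrame
    mask: pd.DataFrame = None

    def __post_init__(self):
        if self.data.index.nlevels != 2:
            raise ValueError("data must be indexed by (culture_id, day)")
        if self.mask is None:
            self.mask = self.data.isna()
        self.mask = self.mask.astype(bool)

    @property
    def param_columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def day_axis(self) -> np.ndarray:
        return np.asarray(sorted(self.data.index.get_level_values(DAY_COL).unique()))

    @property
    def culture_ids(self) -> list:
        return list(self.data.index.get_level_values(ID_COL).unique())

    def parameter_series(self, param: str, observed_only: bool = True):
        """(days, values, culture_ids) triples for one parameter, pooled over cultures."""
        col = self.data[param]
        obs = ~self.mask[param]
        if observed_only:
            col = col[obs.values]
        days = col.index.get_level_values(DAY_COL).to_numpy(dtype=float)
        ids = col.index.get_level_values(ID_COL).to_numpy()
        return days, col.to_numpy(dtype=float), ids

    def copy(self) -> "TimeSeriesTable":
        return TimeSeriesTable(self.data.copy(), self.mask.copy())

    def to_csv(self, path) -> None:
        long = self.data.stack(future_stack=True).rename("value").reset_index()
        long.columns = [ID_COL, DAY_COL, "parameter", "value"]
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeriesTable":
        long = pd.read_csv(path)
        _require_columns(long, [ID_COL, DAY_COL, "parameter", "value"])
        wide = long.pivot_table(
            index=[ID_COL, DAY_COL], columns="parameter", values="value", dropna=False
        )
        wide.columns.name = None
        return cls(wide)


@dataclass
class MaskedDataset:
    """A table with deliberately deleted cells and their retained ground truth.

    ``table`` holds NaN where ``mask`` is True; ``ground_truth`` holds the
    deleted values exactly there.  ``gap_fraction`` is the realised fraction
    of masked cells among maskable cells.
    """

    table: object  # CultureTable or TimeSeriesTable
    mask: pd.DataFrame = field(repr=False)
    ground_truth: pd.DataFrame = field(repr=False)
    gap_fraction: float = 0.0

    def __post_init__(self):
        if self.mask.shape != self.ground_truth.shape:
            raise ValueError("mask and ground_truth must be congruent")

    @property
    def n_masked(self) -> int:
        return int(self.mask.to_numpy().sum())

    def fill_errors(self, filled: pd.DataFrame) -> np.ndarray:
        """Absolute fill errors at the masked cells."""
        m = self.mask.to_numpy()
        return np.abs(filled.to_numpy()[m] - self.ground_truth.to_numpy()[m])
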