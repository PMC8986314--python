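"""Site- and event-level predictors: NDVI, buffer proportions, scaling.

The model's five predictors (available greenspace, impervious cover,
vegetation cover, human population density, daily mean temperature) are
group-mean centered by city and scaled by the covariate's global standard
deviation, so a coefficient measures the effect of a one-global-SD shift
within a city. Raster inputs are plain numeric grids supplied by the user
in a locally projected metric system; no reprojection is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RasterGrid",
    "ndvi",
    "proportion_in_buffer",
    "GroupMeanScaler",
    "center_and_scale",
    "NDVI_VEGETATION_THRESHOLD",
]

#: NDVI above this marks substantial vegetation cover
NDVI_VEGETATION_THRESHOLD = 0.2


@dataclass
class RasterGrid:
    """A rectangular grid of cell values.

    ``origin`` is the (x, y) of the grid's lower-left corner; row index
    increases northward, column index eastward; cell centers sit at
    origin + (j + 0.5, i + 0.5) * cell_size. ``nodata`` cells are ignored
    in all statistics.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell size must be positive")

    def valid_mask(self) -> np.ndarray:
        mask = np.isfinite(self.values)
        if self.nodata is not None:
            mask &= self.values != self.nodata
        return mask

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        n_rows, n_cols = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


def ndvi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """Normalized difference vegetation index, (NIR - Red)/(NIR + Red).

    Cells where either band is no-data or the band sum is zero become NaN.
    """
    if nir.values.shape != red.values.shape or nir.cell_size != red.cell_size or nir.origin != red.origin:
        raise ValueError("NIR and Red grids must share geometry")
    denom = nir.values + red.values
    valid = nir.valid_mask() & red.valid_mask() & (denom != 0)
    out = np.full_like(nir.values, np.nan)
    out[valid] = (nir.values[valid] - red.values[valid]) / denom[valid]
    return RasterGrid(out, nir.cell_size, nir.origin, nodata=None)


def proportion_in_buffer(grid: RasterGrid, center: tuple[float, float], radius_m: float, predicate) -> float:
    """Fraction of valid cells inside a circular buffer satisfying ``predicate``.

    Cell membership is by cell-center-in-circle. ``predicate`` maps an array
    of cell values to booleans (e.g. ``lambda v: v > 0.2``). Raises if the
    buffer contains no valid cell.
    """
    if not radius_m > 0:
        raise ValueError("radius must be positive")
    xs, ys = grid.cell_centers()
    cx, cy = center
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_m**2
    usable = inside & grid.valid_mask()
    n = usable.sum()
    if n == 0:
        raise ValueError("buffer contains no valid cells (outside grid or all no-data)")
    passing = np.zeros_like(usable)
    passing[usable] = np.asarray(predicate(grid.values[usable]), dtype=bool)
    return float(passing.sum() / n)


@dataclass
class GroupMeanScaler:
    """City-mean centering + global-SD scaling, with back-transformation.

    sklearn-style: ``fit`` learns per-city means and the global standard
    deviation of each covariate column, ``transform`` maps raw values to the
    model's scale, ``inverse_transform`` maps back. Fitted state lives in
    ``city_means_`` and ``global_sd_``.
    """

    columns: list[str] | None = None
    group_col: str = "city_id"
    ddof: int = 1
    city_means_: pd.DataFrame = field(default=None, init=False, repr=False)
    global_sd_: pd.Series = field(default=None, init=False, repr=False)

    def get_params(self, deep: bool = True) -> dict:
        return {"columns": self.columns, "group_col": self.group_col, "ddof": self.ddof}

    def set_params(self, **params) -> "GroupMeanScaler":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _cols(self, table: pd.DataFrame) -> list[str]:
        if self.columns is not None:
            return self.columns
        return [c for c in table.columns if c != self.group_col and pd.api.types.is_numeric_dtype(table[c])]

    def fit(self, table: pd.DataFrame) -> "GroupMeanScaler":
        cols = self._cols(table)
        for col in cols:
            if table[col].nunique() < 2:
                raise ValueError(f"covariate {col!r} has zero global variance")
        self.city_means_ = table.groupby(self.group_col)[cols].mean()
        self.global_sd_ = table[cols].std(ddof=self.ddof)
        zero = self.global_sd_[self.global_sd_ == 0]
        if len(zero):
            raise ValueError(f"zero global standard deviation for: {list(zero.index)}")
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        cols = list(self.city_means_.columns)
        out = table.copy()
        means = self.city_means_.reindex(table[self.group_col]).to_numpy()
        out[cols] = (table[cols].to_numpy() - means) / self.global_sd_.to_numpy()
        return out

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        cols = list(self.city_means_.columns)
        out = table.copy()
        means = self.city_means_.reindex(table[self.group_col]).to_numpy()
        out[cols] = table[cols].to_numpy() * self.global_sd_.to_numpy() + means
        return out

    def _check_fitted(self):
        if self.city_means_ is None:
            raise RuntimeError("GroupMeanScaler is not fitted")


def center_and_scale(table: pd.DataFrame, columns: list[str] | None = None, group_col: str = "city_id"):
    """Convenience wrapper: returns (scaled table, fitted GroupMeanScaler)."""
    scaler = GroupMeanScaler(columns=columns, group_col=group_col)
    return scaler.fit_transform(table), scaler
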