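"""Annual raster stack container.

An :class:`AnnualStack` holds one value grid per year on a common pixel
grid, together with a single nodata mask shared by every year.  The shared
mask matches the cloud-free annual-composite assumption: a pixel is either
observed in every year or in none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass
class AnnualStack:
    """Year x row x col raster time series with a constant nodata mask.

    Parameters
    ----------
    values : ndarray, shape (n_years, rows, cols)
        NDVI or FVC values. Masked pixels may hold any value; they are
        ignored by every downstream statistic.
    years : ndarray of int, shape (n_years,)
        Calendar-year labels, strictly increasing.
    nodata_mask : ndarray of bool, shape (rows, cols)
        True where the pixel is nodata (constant across years).
    """

    values: np.ndarray
    years: np.ndarray
    nodata_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D (year, row, col), got shape {self.values.shape}")
        self.years = np.asarray(self.years, dtype=int)
        if self.years.shape != (self.values.shape[0],):
            raise ValueError("years must have one label per layer")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape[1:], dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape[1:]:
            raise ValueError("nodata_mask shape must match the spatial grid")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (rows, cols)."""
        return self.values.shape[1:]

    @property
    def valid(self) -> np.ndarray:
        """Boolean grid of valid (non-nodata) pixels."""
        return ~self.nodata_mask

    def series_matrix(self) -> np.ndarray:
        """Valid-pixel series as an (n_years, n_valid) matrix."""
        return self.values[:, self.valid]
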