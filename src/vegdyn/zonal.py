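"""Zonal summaries over a categorical zone raster (e.g. microtopography).

Means are reported in percent FVC; class fractions are pixel-count
fractions within each zone.  A zone raster coarser than the value raster
is expected to be aligned upstream by nearest-neighbour resampling of the
categorical codes (no interpolation of codes).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _check_aligned(a: np.ndarray, b: np.ndarray):
    if a.shape != b.shape:
        raise ValueError(f"grids not aligned: {a.shape} vs {b.shape}")


def zonal_mean(
    values: np.ndarray,
    zones: np.ndarray,
    zone_names: dict[int, str] | None = None,
    percent: bool = True,
) -> pd.DataFrame:
    """Per-zone mean of a value grid or a (year, row, col) stack.

    For a stack the mean pools all years and pixels of the zone.  NaN
    values and zone code 0 (nodata) are excluded.
    """
    values = np.asarray(values, dtype=float)
    zones = np.asarray(zones)
    spatial = values.shape[-2:]
    _check_aligned(np.empty(spatial), zones)
    if values.ndim == 2:
        values = values[None]
    scale = 100.0 if percent else 1.0
    rows = []
    for code in np.unique(zones):
        if code == 0:
            continue
        sel = zones == code
        vals = values[:, sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"zone {code}: no valid pixels, omitted")
            continue
        rows.append(
            {
                "zone_code": int(code),
                "zone_name": (zone_names or {}).get(int(code), str(int(code))),
                "n_pixels": int(sel.sum()),
                "mean": vals.mean() * scale,
            }
        )
    df = pd.DataFrame(rows)
    if percent and not df.empty:
        df = df.rename(columns={"mean": "mean_fvc_percent"})
    return df


def zonal_class_fractions(
    class_grid: np.ndarray,
    zones: np.ndarray,
    class_names: dict[int, str] | None = None,
    zone_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Fraction of each class label within each zone (long format).

    Class code 0 (nodata) pixels are excluded from the denominators; the
    fractions within a zone sum to 1.
    """
    class_grid = np.asarray(class_grid)
    zones = np.asarray(zones)
    _check_aligned(class_grid, zones)
    codes = [c for c in np.unique(class_grid) if c != 0]
    rows = []
    for z in np.unique(zones):
        if z == 0:
            continue
        sel = (zones == z) & (class_grid != 0)
        n = int(sel.sum())
        for c in codes:
            rows.append(
                {
                    "zone_code": int(z),
                    "zone_name": (zone_names or {}).get(int(z), str(int(z))),
                    "class_code": int(c),
                    "class_name": (class_names or {}).get(int(c), str(int(c))),
                    "fraction": (class_grid[sel] == c).sum() / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)
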