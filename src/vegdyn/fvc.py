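"""Fractional vegetation cover from NDVI via the dichotomous pixel model.

Each pixel is assumed to mix exactly two endmembers, full vegetation and
bare ground, so FVC is the linear mixing fraction

    FVC = (NDVI - NDVI_n) / (NDVI_v - NDVI_n),

clamped to [0, 1].  The endmembers NDVI_n (bare ground) and NDVI_v (full
vegetation) are taken as low/high percentiles (default 5% and 95%) of the
cumulative frequency of valid NDVI values, so the model is invariant to
positive affine rescalings of the NDVI histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import AnnualStack


@dataclass(frozen=True)
class Endmembers:
    """Bare-ground and full-vegetation NDVI anchor values."""

    ndvi_n: float
    ndvi_v: float

    def __post_init__(self):
        if not (self.ndvi_n < self.ndvi_v):
            raise ValueError(f"require ndvi_n < ndvi_v, got ({self.ndvi_n}, {self.ndvi_v})")
        if not (-1.0 <= self.ndvi_n <= 1.0 and -1.0 <= self.ndvi_v <= 1.0):
            raise ValueError("endmembers must lie in [-1, 1]")


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """NDVI = (NIR - Red) / (NIR + Red), NaN where the denominator is zero.

    NaN in either band propagates to the output.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if red.shape != nir.shape:
        raise ValueError("red and nir grids must be aligned")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom != 0, (nir - red) / denom, np.nan)
    return ndvi


def estimate_endmembers(
    ndvi: np.ndarray,
    p_low: float = 5.0,
    p_high: float = 95.0,
    min_valid: int = 100,
) -> Endmembers:
    """Percentile endmembers from the valid-pixel cumulative frequency.

    ``ndvi`` may be a grid or a stack array; NaNs are ignored.  Percentiles
    use linear interpolation between order statistics.
    """
    if not (0 < p_low < p_high < 100):
        raise ValueError("require 0 < p_low < p_high < 100")
    x = np.asarray(ndvi, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < min_valid:
        raise ValueError(f"need at least {min_valid} valid pixels, got {x.size}")
    lo, hi = np.percentile(x, [p_low, p_high])
    if lo == hi:
        raise ValueError("degenerate NDVI histogram: identical low/high percentiles")
    return Endmembers(float(lo), float(hi))


def compute_fvc(ndvi: np.ndarray, em: Endmembers) -> np.ndarray:
    """Linear unmixing of NDVI into FVC, clamped to [0, 1].

    Pixels at or below the bare-ground endmember get FVC 0, at or above the
    vegetation endmember FVC 1.  NaN (nodata) propagates.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    fvc = (ndvi - em.ndvi_n) / (em.ndvi_v - em.ndvi_n)
    return np.clip(fvc, 0.0, 1.0)


def fvc_stack(
    ndvi_stack: AnnualStack,
    p_low: float = 5.0,
    p_high: float = 95.0,
    global_endmembers: bool = False,
) -> AnnualStack:
    """Convert an NDVI stack to an FVC stack.

    By default endmembers are estimated per annual image; with
    ``global_endmembers=True`` one pair is estimated from the whole stack.
    """
    valid = ndvi_stack.valid
    out = np.empty_like(ndvi_stack.values)
    if global_endmembers:
        em = estimate_endmembers(ndvi_stack.values[:, valid], p_low, p_high)
        ems = [em] * ndvi_stack.n_years
    else:
        ems = [
            estimate_endmembers(ndvi_stack.values[i][valid], p_low, p_high)
            for i in range(ndvi_stack.n_years)
        ]
    for i, em in enumerate(ems):
        out[i] = compute_fvc(ndvi_stack.values[i], em)
    return AnnualStack(out, ndvi_stack.years, ndvi_stack.nodata_mask)


def annual_mean_series(stack: AnnualStack) -> "pd.DataFrame":
    """Per-year mean FVC over valid pixels, in percent.

    Returns a DataFrame with columns ``year`` and ``mean_fvc_percent``.
    """
    import pandas as pd

    valid = stack.valid
    if not valid.any():
        raise ValueError("no valid pixels in any year")
    means = stack.values[:, valid].mean(axis=1) * 100.0
    if np.any(~np.isfinite(means)):
        raise ValueError("non-finite annual mean (fully masked or NaN year)")
    return pd.DataFrame({"year": stack.years, "mean_fvc_percent": means})
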