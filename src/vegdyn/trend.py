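"""Per-pixel linear trend of FVC and the five-way change classification.

The trend statistic is the ordinary-least-squares slope of FVC on the year
index, written in normal-equation form

    SLOPE = [ n * sum(i * FVC_i) - sum(i) * sum(FVC_i) ]
          / [ n * sum(i^2)      - (sum(i))^2 ],

with i = 1..n.  Significance is the two-sided t-test of the slope with
n - 2 degrees of freedom.  Pixels are classified as extremely significant
increase (slope > 0, p <= 0.01), significant increase (slope > 0,
0.01 < p <= 0.05), extremely significant decrease / significant decrease
(mirrored for slope < 0), and insignificant change (p > 0.05).  A boundary
p lands in the more significant bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stack import AnnualStack

# class codes (0 reserved for nodata)
TREND_CLASSES = {
    1: "extremely_significant_increase",
    2: "significant_increase",
    3: "insignificant",
    4: "significant_decrease",
    5: "extremely_significant_decrease",
}


@dataclass
class TrendGrid:
    """Per-pixel slope, its two-sided p-value, and the 5-way change class."""

    slope: np.ndarray
    p_value: np.ndarray = None
    change_class: np.ndarray = None
    valid: np.ndarray = field(default=None)


def _index_sums(n: int) -> tuple[np.ndarray, float]:
    i = np.arange(1, n + 1, dtype=float)
    sxx = n * (i**2).sum() - i.sum() ** 2  # = n^2 (n^2-1)/12
    return i, sxx


def pixel_slope(stack: AnnualStack) -> TrendGrid:
    """OLS slope of FVC on the year index for every valid pixel.

    Masked pixels get NaN.  Requires at least 4 years so the slope
    t-statistic has positive degrees of freedom.
    """
    n = stack.n_years
    if n < 4:
        raise ValueError(f"need >= 4 years for a testable trend, got {n}")
    i, sxx = _index_sums(n)
    v = stack.values
    num = n * np.tensordot(i, v, axes=(0, 0)) - i.sum() * v.sum(axis=0)
    slope = num / sxx
    slope[np.ptp(v, axis=0) == 0] = 0.0  # exactly flat: kill round-off slope
    slope[stack.nodata_mask] = np.nan
    return TrendGrid(slope=slope, valid=stack.valid.copy())


def slope_pvalue(stack: AnnualStack, trend: TrendGrid | None = None) -> TrendGrid:
    """Two-sided p-value of the per-pixel slope (t-test, n - 2 df).

    Zero residual variance is a degenerate (noiseless) series: p is 0 for a
    nonzero slope and 1 for a flat one.
    """
    if trend is None:
        trend = pixel_slope(stack)
    n = stack.n_years
    i, sxx_norm = _index_sums(n)
    ic = i - i.mean()
    sxx = (ic**2).sum()
    v = stack.values
    ybar = v.mean(axis=0)
    sst = ((v - ybar) ** 2).sum(axis=0)
    ssr = trend.slope**2 * sxx
    sse = np.maximum(sst - ssr, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sse / (n - 2) / sxx)
        t = trend.slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    degenerate = se == 0
    flat = np.ptp(v, axis=0) == 0
    p = np.where(degenerate & (trend.slope != 0), 0.0, p)
    p = np.where(flat | (degenerate & (trend.slope == 0)), 1.0, p)
    p[~trend.valid] = np.nan
    trend.p_value = p
    return trend


def classify_trend(trend: TrendGrid) -> tuple[TrendGrid, pd.DataFrame]:
    """Assign the 5-way change class and report class area fractions.

    Fractions are pixel-count fractions over valid pixels and sum to 1.
    """
    if trend.p_value is None:
        raise ValueError("p_value missing; run slope_pvalue first")
    s, p = trend.slope, trend.p_value
    cls = np.zeros(s.shape, dtype=np.int8)
    v = trend.valid
    cls[v & (s > 0) & (p <= 0.01)] = 1
    cls[v & (s > 0) & (p > 0.01) & (p <= 0.05)] = 2
    cls[v & (p > 0.05)] = 3
    cls[v & (s < 0) & (p > 0.01) & (p <= 0.05)] = 4
    cls[v & (s < 0) & (p <= 0.01)] = 5
    # slope exactly 0 with p <= 0.05 cannot occur (t = 0 => p = 1), but a
    # zero-slope pixel must still land somewhere: insignificant.
    cls[v & (s == 0)] = 3
    trend.change_class = cls
    nv = int(v.sum())
    frac = pd.DataFrame(
        {
            "class_code": list(TREND_CLASSES),
            "class_name": [TREND_CLASSES[c] for c in TREND_CLASSES],
            "fraction": [(cls[v] == c).sum() / nv for c in TREND_CLASSES],
        }
    )
    return trend, frac


def zonal_trend(series: pd.DataFrame, min_years: int = 4) -> pd.DataFrame:
    """Per-stratum OLS regression of zonal-mean FVC (%) on calendar year.

    ``series`` is long-format with columns ``zone``, ``year``,
    ``mean_fvc_percent``.  Returns one row per zone with slope
    (percent/year), intercept, and the two-sided slope p-value, mirroring a
    "regression equation / P-value" zonal table.
    """
    rows = []
    for zone, g in series.groupby("zone", sort=True):
        if len(g) < min_years:
            import warnings

            warnings.warn(f"zone {zone!r}: fewer than {min_years} years, omitted")
            continue
        res = stats.linregress(g["year"].to_numpy(float), g["mean_fvc_percent"].to_numpy(float))
        rows.append(
            {
                "zone": zone,
                "slope_percent_per_year": res.slope,
                "intercept_percent": res.intercept,
                "p_value": res.pvalue if np.isfinite(res.pvalue) else (0.0 if res.slope != 0 else 1.0),
            }
        )
    return pd.DataFrame(rows)
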