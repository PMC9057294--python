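"""Rescaled-range (R/S) Hurst exponent and the future-trend classifier.

For a window of length w with values x_1..x_w the rescaled range is

    m   = mean(x),            y_i = x_i - m,
    z_i = y_1 + ... + y_i     (cumulated deviations),
    R   = max(z) - min(z),    S = population standard deviation of x,

and R/S grows like w^H, where H is the Hurst exponent.  H is estimated as
the OLS slope of log(mean R/S over non-overlapping windows) against
log(window length).  H < 0.5 marks anti-persistence (future reverses the
past), H ~ 0.5 a memoryless series, H > 0.5 persistence.

The printed form of the range in some descriptions spans the raw
deviations y_1..y_i rather than their cumulative sum; that variant does
not produce the w^H scaling law but is available as ``literal_eq5=True``
for comparison.

Combining the Hurst class with the trend slope and its significance gives
a seven-way future-trend class (random fluctuation; continuous
increase/decrease, optionally significant; degradation-to-improvement and
improvement-to-degradation for anti-persistent pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

H_CLASSES = {1: "opposite", 2: "random", 3: "continuous"}

FUTURE_CLASSES = {
    1: "random_fluctuation",
    2: "continuous_decrease",
    3: "continuous_increase",
    4: "continuous_significant_decrease",
    5: "continuous_significant_increase",
    6: "degradation_to_improvement",
    7: "improvement_to_degradation",
}


@dataclass
class HurstGrid:
    """Per-pixel Hurst exponent with its 3-way and 7-way classifications."""

    H: np.ndarray
    h_class: np.ndarray = None
    future_class: np.ndarray = None
    valid: np.ndarray = None


def _as_matrix(series: np.ndarray) -> np.ndarray:
    """(n,) or (n, k) -> (k, n) row-per-series matrix."""
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        return x[None, :]
    if x.ndim == 2:
        return x.T
    raise ValueError("series must be 1-D or (n_steps, n_series)")


def _rs_matrix(x: np.ndarray, window: int, literal_eq5: bool) -> np.ndarray:
    """Mean R/S over non-overlapping windows for each row of x.

    Windows with zero standard deviation are skipped; a row where every
    window is degenerate yields NaN.
    """
    n = x.shape[1]
    nseg = n // window
    seg = x[:, : nseg * window].reshape(x.shape[0], nseg, window)
    dev = seg - seg.mean(axis=2, keepdims=True)
    spread = dev if literal_eq5 else np.cumsum(dev, axis=2)
    R = spread.max(axis=2) - spread.min(axis=2)
    S = seg.std(axis=2)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.where(S > 0, R / S, np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-degenerate rows -> NaN
        return np.nanmean(rs, axis=1)


def rescaled_range(series: np.ndarray, window: int, literal_eq5: bool = False) -> float | np.ndarray:
    """Mean R/S statistic at one window length.

    ``series`` is a single sequence or an (n_steps, n_series) matrix; the
    result is a scalar or one value per series.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    x = _as_matrix(series)
    if x.shape[1] < window:
        raise ValueError(f"series length {x.shape[1]} < window {window}")
    out = _rs_matrix(x, window, literal_eq5)
    if np.isnan(out).all():
        raise ValueError("all windows degenerate (zero variance)")
    return float(out[0]) if np.asarray(series).ndim == 1 else out


def default_windows(n: int, n_windows: int = 12, short_series_max: int = 64) -> list[int]:
    """Window lengths used for the log-log fit.

    Short series (n <= 64, e.g. 21 annual composites) use every length in
    {4, ..., n // 2} plus n itself — short records need every usable
    scale.  Long series use ~12 log-spaced lengths in [32, n // 2], which
    avoids the strong small-window bias of the R/S statistic.
    """
    if n < 8:
        raise ValueError("series too short for R/S analysis (need n >= 8)")
    if n <= short_series_max:
        return sorted(set(range(4, n // 2 + 1)) | {n})
    lo, hi = 32, n // 2
    w = np.unique(np.round(np.exp(np.linspace(np.log(lo), np.log(hi), n_windows))).astype(int))
    return [int(v) for v in w]


def estimate_hurst(
    series: np.ndarray,
    windows: list[int] | None = None,
    literal_eq5: bool = False,
) -> float | np.ndarray:
    """Hurst exponent: OLS slope of log(mean R/S) on log(window).

    ``series`` is one sequence or an (n_steps, n_series) matrix.  Series
    with fewer than 3 usable window scales yield NaN.
    """
    x = _as_matrix(series)
    n = x.shape[1]
    if windows is None:
        windows = default_windows(n)
    windows = sorted(set(int(w) for w in windows))
    if len(windows) < 3:
        raise ValueError("need >= 3 distinct window sizes")
    if windows[0] < 2 or windows[-1] > n:
        raise ValueError("windows must lie in [2, series length]")
    rs = np.stack([_rs_matrix(x, w, literal_eq5) for w in windows])  # (W, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        logrs = np.log(rs)
    lw = np.log(np.array(windows, dtype=float))
    usable = np.isfinite(logrs)
    H = np.full(x.shape[0], np.nan)
    ok = usable.sum(axis=0) >= 3
    if ok.any():
        # per-series OLS allowing different usable-window subsets
        w_ok = np.where(usable, 1.0, 0.0)
        y = np.where(usable, logrs, 0.0)
        sw = w_ok.sum(axis=0)
        mx = (w_ok * lw[:, None]).sum(axis=0) / sw
        my = y.sum(axis=0) / sw
        sxx = (w_ok * (lw[:, None] - mx) ** 2).sum(axis=0)
        sxy = (w_ok * (lw[:, None] - mx) * (y - my)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Hall = sxy / sxx
        H[ok] = Hall[ok]
    return float(H[0]) if np.asarray(series).ndim == 1 else H


def hurst_grid(stack, windows: list[int] | None = None, literal_eq5: bool = False) -> HurstGrid:
    """Per-pixel Hurst exponent of an :class:`~vegdyn.stack.AnnualStack`."""
    valid = stack.valid
    mat = stack.values[:, valid]  # (n_years, n_valid)
    H = estimate_hurst(mat, windows=windows, literal_eq5=literal_eq5)
    grid = np.full(stack.shape, np.nan)
    grid[valid] = H
    return HurstGrid(H=grid, valid=valid.copy())


def classify_hurst(hg: HurstGrid | np.ndarray, band: float = 0.05) -> HurstGrid:
    """3-way Hurst class: opposite (< 0.5 - band), random (within the band
    around 0.5), continuous (> 0.5 + band).

    The band replaces the measure-zero event "H exactly 0.5" for estimated
    exponents.
    """
    if not isinstance(hg, HurstGrid):
        hg = HurstGrid(H=np.asarray(hg, dtype=float), valid=np.isfinite(np.asarray(hg, dtype=float)))
    if hg.valid is None:
        hg.valid = np.isfinite(hg.H)
    H = hg.H
    cls = np.zeros(H.shape, dtype=np.int8)
    v = hg.valid & np.isfinite(H)
    cls[v & (H < 0.5 - band)] = 1
    cls[v & (np.abs(H - 0.5) <= band)] = 2
    cls[v & (H > 0.5 + band)] = 3
    hg.h_class = cls
    return hg


def classify_future(
    hg: HurstGrid,
    slope: np.ndarray,
    p_value: np.ndarray,
    alpha: float = 0.05,
) -> tuple[HurstGrid, pd.DataFrame]:
    """7-way future-trend class from (Hurst class, slope sign, p-value).

    Persistent pixels continue their historical direction (significant if
    p <= alpha); anti-persistent pixels reverse it; random pixels are
    unclassifiable fluctuation.  A slope of exactly zero is put on the
    decrease side of the non-significant classes (flagged in the returned
    fractions table footnote column).
    """
    if hg.h_class is None:
        raise ValueError("h_class missing; run classify_hurst first")
    hc = hg.h_class
    s = np.asarray(slope)
    p = np.asarray(p_value)
    fc = np.zeros(hc.shape, dtype=np.int8)
    v = hg.valid & (hc > 0) & np.isfinite(s) & np.isfinite(p)
    sig = p <= alpha
    fc[v & (hc == 2)] = 1
    fc[v & (hc == 3) & (s <= 0) & ~sig] = 2
    fc[v & (hc == 3) & (s > 0) & ~sig] = 3
    fc[v & (hc == 3) & (s < 0) & sig] = 4
    fc[v & (hc == 3) & (s > 0) & sig] = 5
    fc[v & (hc == 3) & (s == 0) & sig] = 2  # degenerate: flat but "significant"
    fc[v & (hc == 1) & (s <= 0)] = 6
    fc[v & (hc == 1) & (s > 0)] = 7
    hg.future_class = fc
    nv = int(v.sum())
    group = {1: "random", 2: "degradation", 3: "improvement", 4: "degradation",
             5: "improvement", 6: "improvement", 7: "degradation"}
    frac = pd.DataFrame(
        {
            "class_code": list(FUTURE_CLASSES),
            "class_name": [FUTURE_CLASSES[c] for c in FUTURE_CLASSES],
            "group": [group[c] for c in FUTURE_CLASSES],
            "fraction": [((fc == c) & v).sum() / nv if nv else np.nan for c in FUTURE_CLASSES],
        }
    )
    return hg, frac
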