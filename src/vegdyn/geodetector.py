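"""Geographical Detector statistics for driver attribution.

The factor detector measures how much a categorical stratification of
space explains the variance of a response y (here: the per-pixel FVC
trend) through the q-statistic

    q = 1 - sum_h N_h * sigma_h^2 / (N * sigma^2) = 1 - SSW / SST,

with population variances, q in [0, 1].  Significance comes from a seeded
permutation test by default, or from the noncentral-F distribution used by
the original Geodetector software.  The interaction detector computes q on
the cross-classification of two factors and labels the pair by comparing
q(x1 ∩ x2) with q(x1), q(x2) and their sum (weaken nonlinear / weaken
univariate / enhance bivariate / independent / enhance nonlinear).  The
risk detector compares stratum means of y pairwise with Welch t-tests and
flags the most favorable level.

Continuous drivers are discretized before detection; a VIF screen drops
collinear continuous drivers first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

INTERACTION_TYPES = (
    "weaken_nonlinear",
    "weaken_univariate",
    "enhance_bivariate",
    "independent",
    "enhance_nonlinear",
)


@dataclass
class StratifiedSample:
    """Response vector paired with one or more per-pixel stratifications.

    ``strata`` maps factor name -> integer code vector aligned with ``y``.
    Codes are arbitrary labels; statistics are invariant to relabeling.
    """

    y: np.ndarray
    strata: dict[str, np.ndarray]
    level_labels: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.strata = {k: np.asarray(v).ravel().astype(int) for k, v in self.strata.items()}
        for k, v in self.strata.items():
            if v.shape != self.y.shape:
                raise ValueError(f"factor {k!r}: strata length mismatch")

    def factor(self, name: str) -> np.ndarray:
        return self.strata[name]


def _q_from_codes(y: np.ndarray, codes: np.ndarray) -> float:
    """q = 1 - SSW/SST via group sums (population variances cancel N)."""
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("response has zero variance: nothing to explain")
    _, inv, counts = np.unique(codes, return_inverse=True, return_counts=True)
    gsum = np.bincount(inv, weights=y)
    gsum2 = np.bincount(inv, weights=y * y)
    ssw = (gsum2 - gsum**2 / counts).sum()
    return float(1.0 - ssw / sst)


def factor_q(
    sample: StratifiedSample,
    factor: str,
    permutations: int = 999,
    seed: int | None = 0,
    method: str = "permutation",
) -> tuple[float, float]:
    """Factor-detector q and its p-value for one stratification.

    ``method`` is ``"permutation"`` (seeded label permutation,
    p = (1 + #{q* >= q}) / (permutations + 1)) or ``"ncf"`` (the
    noncentral-F test of the original Geodetector software).
    Levels must number >= 2 and each needs >= 2 members.
    """
    y = sample.y
    codes = sample.factor(factor)
    levels, inv, counts = np.unique(codes, return_inverse=True, return_counts=True)
    if len(levels) == 1:
        # degenerate stratification explains nothing: sigma_h^2 == sigma^2
        return 0.0, 1.0
    if counts.min() < 2:
        raise ValueError("every stratum needs >= 2 members (within-variance undefined)")
    q = _q_from_codes(y, codes)
    N, L = y.size, len(levels)
    if method == "ncf":
        F = (N - L) / (L - 1) * q / max(1.0 - q, 1e-300)
        gmean = np.bincount(inv, weights=y) / counts
        sigma2 = y.var()
        lam = ((gmean**2 * counts).sum() - (np.sqrt(counts) * gmean).sum() ** 2 / N) / sigma2
        lam = max(lam, 0.0)
        p = float(stats.ncf.sf(F, L - 1, N - L, lam))
        return q, p
    rng = np.random.default_rng(seed)
    sst = ((y - y.mean()) ** 2).sum()
    onehot = np.zeros((N, L))
    onehot[np.arange(N), inv] = 1.0
    exceed = 0
    chunk = 200  # bound the (chunk, N) permutation matrix
    done = 0
    y2sum = (y * y).sum()
    while done < permutations:
        k = min(chunk, permutations - done)
        idx = np.argsort(rng.random((k, N)), axis=1)
        yp = y[idx]
        gsum = yp @ onehot
        # SSW = sum(y^2) - sum_h (group sum)^2 / N_h ; SST is permutation-invariant
        ssw = y2sum - (gsum**2 / counts).sum(axis=1)
        qperm = 1.0 - ssw / sst
        exceed += int((qperm >= q - 1e-12).sum())
        done += k
    p = (1 + exceed) / (permutations + 1)
    return q, float(p)


def _merge_small_cells(y: np.ndarray, codes: np.ndarray, min_size: int = 2) -> tuple[np.ndarray, int]:
    """Merge cells with < min_size members into the sibling whose mean y is
    nearest; returns the recoded vector and the number of merges."""
    codes = codes.copy()
    merges = 0
    while True:
        levels, inv, counts = np.unique(codes, return_inverse=True, return_counts=True)
        small = np.where(counts < min_size)[0]
        if small.size == 0 or len(levels) < 2:
            break
        means = np.bincount(inv, weights=y) / counts
        s = small[0]
        big = np.where(counts >= min_size)[0]
        candidates = big if big.size else np.array([i for i in range(len(levels)) if i != s])
        tgt = candidates[np.argmin(np.abs(means[candidates] - means[s]))]
        codes[codes == levels[s]] = levels[tgt]
        merges += 1
    return codes, merges


def interaction_q(
    sample: StratifiedSample,
    factor_a: str,
    factor_b: str,
    permutations: int = 0,
    seed: int | None = 0,
    independent_tol: float = 1e-9,
) -> dict:
    """Interaction detector: q of both factors, of their cross-classification,
    and the interaction type.

    Cross cells with < 2 members are merged into the nearest sibling by
    mean response (merge count reported).  Type rules, checked in order:
    independent if q_ab matches q_a + q_b within ``independent_tol``;
    enhance_nonlinear if q_ab exceeds the sum; enhance_bivariate if it
    exceeds both singles; weaken_nonlinear if below both; else
    weaken_univariate.
    """
    qa = _q_from_codes(sample.y, sample.factor(factor_a))
    qb = _q_from_codes(sample.y, sample.factor(factor_b))
    a = sample.factor(factor_a)
    b = sample.factor(factor_b)
    cross = np.unique(np.stack([a, b], axis=1), axis=0, return_inverse=True)[1].ravel()
    cross, merges = _merge_small_cells(sample.y, cross)
    if np.unique(cross).size < 2:
        raise ValueError("cross-classification degenerate after merging")
    qab = _q_from_codes(sample.y, cross)
    itype = classify_interaction(qa, qb, qab, independent_tol)
    return {
        "factor_a": factor_a,
        "factor_b": factor_b,
        "q_a": qa,
        "q_b": qb,
        "q_ab": qab,
        "type": itype,
        "merged_cells": merges,
    }


def classify_interaction(qa: float, qb: float, qab: float, tol: float = 1e-9) -> str:
    """Label a (q_a, q_b, q_ab) triple with its interaction type."""
    lo, hi = min(qa, qb), max(qa, qb)
    if abs(qab - (qa + qb)) <= tol:
        return "independent"
    if qab > qa + qb:
        return "enhance_nonlinear"
    if qab > hi:
        return "enhance_bivariate"
    if qab < lo:
        return "weaken_nonlinear"
    return "weaken_univariate"


def risk_detect(sample: StratifiedSample, factor: str, alpha: float = 0.05) -> dict:
    """Risk detector: per-level mean response, pairwise Welch t-tests, and
    the most favorable (maximum-mean) level.

    Singleton levels are excluded with a warning.  Returns a dict with a
    per-level table, the symmetric significance matrix, and the name/code
    of the most favorable level.
    """
    y = sample.y
    codes = sample.factor(factor)
    levels, counts = np.unique(codes, return_counts=True)
    keep = levels[counts >= 2]
    if keep.size < levels.size:
        warnings.warn(f"factor {factor!r}: {levels.size - keep.size} singleton level(s) excluded")
    if keep.size < 2:
        raise ValueError("need >= 2 usable levels")
    labels = sample.level_labels.get(factor, {})
    groups = {lv: y[codes == lv] for lv in keep}
    table = pd.DataFrame(
        {
            "level_code": keep,
            "level_name": [labels.get(int(lv), str(int(lv))) for lv in keep],
            "n": [groups[lv].size for lv in keep],
            "mean_y": [groups[lv].mean() for lv in keep],
        }
    )
    k = keep.size
    tmat = np.full((k, k), np.nan)
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[keep[i]], groups[keep[j]]
            if gi.var(ddof=1) == 0 and gj.var(ddof=1) == 0:
                t, p = (0.0, 1.0) if gi.mean() == gj.mean() else (np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(gi, gj, equal_var=False)
            tmat[i, j] = tmat[j, i] = t
            sig[i, j] = sig[j, i] = p <= alpha
    best = int(np.argmax(table["mean_y"].to_numpy()))
    return {
        "table": table,
        "t_matrix": tmat,
        "significant": sig,
        "most_favorable_code": int(keep[best]),
        "most_favorable_name": table["level_name"].iloc[best],
    }


# ---------------------------------------------------------------------------
# discretization of continuous drivers


def discretize(
    values: np.ndarray,
    scheme: str = "quantile",
    k: int = 5,
    breaks: np.ndarray | None = None,
) -> np.ndarray:
    """Discretize a continuous grid into integer stratum codes 1..k.

    Schemes: ``equal_interval`` (k equal-width bins over the observed
    range), ``quantile`` (k equal-count bins), ``custom_breaks`` (explicit
    bin edges), ``circular_aspect`` (eight 45-degree compass bins offset by
    22.5 degrees, so north wraps 337.5 -> 22.5).  NaN maps to code 0.
    """
    x = np.asarray(values, dtype=float)
    out = np.zeros(x.shape, dtype=int)
    ok = np.isfinite(x)
    if scheme == "circular_aspect":
        # bin 1 = north (337.5..22.5), then clockwise: NE, E, SE, S, SW, W, NW
        shifted = np.mod(x[ok] + 22.5, 360.0)
        out[ok] = np.minimum((shifted // 45.0).astype(int), 7) + 1
        return out
    if scheme == "custom_breaks":
        if breaks is None:
            raise ValueError("custom_breaks requires explicit breaks")
        edges = np.asarray(breaks, dtype=float)
    elif scheme == "equal_interval":
        if k < 2:
            raise ValueError("k must be >= 2")
        edges = np.linspace(x[ok].min(), x[ok].max(), k + 1)
    elif scheme == "quantile":
        if k < 2:
            raise ValueError("k must be >= 2")
        edges = np.unique(np.quantile(x[ok], np.linspace(0, 1, k + 1)))
        if edges.size < 3:
            raise ValueError("too few distinct values for quantile bins")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    codes = np.digitize(x[ok], edges[1:-1], right=False) + 1
    out[ok] = codes
    used = np.unique(codes)
    if used.size < edges.size - 1:
        warnings.warn(f"{edges.size - 1 - used.size} empty bin(s) under the given breaks")
    return out


# ---------------------------------------------------------------------------
# VIF screening


def vif_screen(factors: pd.DataFrame, threshold: float = 10.0) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop continuous factors with VIF above the threshold.

    VIF_j = 1 / (1 - R^2_j) from an intercept OLS of factor j on the
    remaining factors.  The worst offender (perfect collinearity reported
    as +inf) is removed first; repeats until all retained factors pass
    strict ``VIF > threshold``.  Returns the retained names and a report
    with each factor's initial VIF, final VIF (NaN if dropped), and
    retention flag.
    """
    import statsmodels.api as sm

    if factors.shape[1] < 2:
        raise ValueError("need >= 2 factors")
    if factors.shape[0] <= factors.shape[1]:
        raise ValueError("need more samples than factors")

    def vifs(cols: list[str]) -> pd.Series:
        out = {}
        X = factors[cols].to_numpy(float)
        for j, name in enumerate(cols):
            others = np.delete(X, j, axis=1)
            r2 = sm.OLS(X[:, j], sm.add_constant(others)).fit().rsquared
            out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    cols = list(factors.columns)
    initial = vifs(cols) if len(cols) > 1 else pd.Series(1.0, index=cols)
    current = initial.copy()
    dropped = []
    while len(cols) > 1:
        worst = current.idxmax()
        if current[worst] > threshold:
            cols.remove(worst)
            dropped.append(worst)
            current = vifs(cols) if len(cols) > 1 else pd.Series(1.0, index=cols)
        else:
            break
    report = pd.DataFrame(
        {
            "factor": list(factors.columns),
            "vif_initial": [initial[c] for c in factors.columns],
            "vif_final": [current.get(c, np.nan) for c in factors.columns],
            "retained": [c in cols for c in factors.columns],
        }
    )
    return cols, report
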