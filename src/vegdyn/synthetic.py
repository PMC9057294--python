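"""Synthetic basin generator with planted, recoverable ground truth.

Every downstream stage of the pipeline has a counterpart here that plants
the quantity the stage estimates:

* linear-trend stacks with a known per-pixel slope and Gaussian noise,
  for the trend estimator;
* fractional Gaussian noise (fGn) stacks with a known Hurst exponent,
  synthesised exactly by the Davies-Harte circulant-embedding method,
  for the R/S estimator;
* stratified value fields with a known between-/within-stratum variance
  split, hence a known q-statistic, for the Geographical Detector;
* a toy 13-type microtopography map with planted zone means, for the
  zonal summaries.

``build_basin`` composes all of these into one basin: the northern half
carries the trend/driver experiment (additive stratum effects on the
slope plus white noise), the southern half carries zero-trend fGn bands
with contrasting Hurst regimes.  The returned ground-truth dictionary
holds every planted map and closed-form expected value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .stack import AnnualStack

#: the 13 landform classes of a continuous heat-insolation / topographic
#: position landform product, used as the toy microtopography legend
MICROTOPO_NAMES = {
    1: "lower_slope_cool",
    2: "lower_slope",
    3: "lower_slope_warm",
    4: "valley",
    5: "upper_slope_warm",
    6: "upper_slope",
    7: "valley_narrow",
    8: "upper_slope_cool",
    9: "cliff",
    10: "mountain_divide",
    11: "peak_ridge_warm",
    12: "peak_ridge",
    13: "peak_ridge_cool",
}


@dataclass(frozen=True)
class StratumSpec:
    """One categorical driver: level means and within-level noise sd.

    Equal assignment probability per level; the planted q-statistic is
    Vb / (Vb + Vw) with Vb the population variance of the level means and
    Vw the mean within-level variance.
    """

    name: str
    level_means: tuple
    within_sd: float

    @property
    def n_levels(self) -> int:
        return len(self.level_means)

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("need >= 2 levels")
        if self.within_sd < 0:
            raise ValueError("within_sd must be >= 0")


def planned_q(spec: StratumSpec, weights: np.ndarray | None = None) -> float:
    """Closed-form q = Vb / (Vb + Vw) planted by a stratum specification."""
    mu = np.asarray(spec.level_means, dtype=float)
    w = np.full(mu.size, 1.0 / mu.size) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    vb = float((w * (mu - (w * mu).sum()) ** 2).sum())
    vw = float(spec.within_sd**2)
    if vb + vw == 0:
        raise ValueError("degenerate spec: zero total variance")
    return vb / (vb + vw)


def means_for_q(q: float, within_sd: float, n_levels: int) -> tuple:
    """Equally spaced, zero-mean level means whose planted q equals ``q``."""
    if not (0 <= q < 1):
        raise ValueError("q must lie in [0, 1)")
    vb = q / (1.0 - q) * within_sd**2
    base = np.arange(n_levels, dtype=float) - (n_levels - 1) / 2.0
    base_var = (n_levels**2 - 1) / 12.0
    return tuple(base * np.sqrt(vb / base_var))


@dataclass
class BasinConfig:
    """Configuration of the synthetic basin.

    ``trend_map`` is a per-pixel slope in FVC-units/year (scalar allowed);
    ``hurst_target`` the H planted in the fGn half; ``strata_spec`` the
    categorical drivers whose planted q is known in closed form.
    """

    n_years: int = 21
    grid_shape: tuple = (200, 200)
    seed: int = 0
    trend_map: float | np.ndarray = 0.003
    noise_sd: float = 0.05
    intercept: float | np.ndarray = 0.4
    hurst_target: tuple = (0.25, 0.5, 0.85)
    strata_spec: list = dc_field(default_factory=list)
    nodata_fraction: float = 0.02
    start_year: int = 2000
    clip_warn_fraction: float = 0.05

    def __post_init__(self):
        if self.n_years < 4:
            raise ValueError("n_years must be >= 4 (slope p-value needs n - 2 >= 2 df)")
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be two positive ints")
        if not (0 <= self.nodata_fraction < 1):
            raise ValueError("nodata_fraction must be in [0, 1)")
        for h in np.atleast_1d(np.asarray(self.hurst_target, float)).ravel():
            if not (0 < h < 1):
                raise ValueError("hurst_target values must lie in (0, 1)")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


def _warn_clip(values: np.ndarray, threshold: float):
    frac = float(((values < 0) | (values > 1)).mean())
    if frac > threshold:
        warnings.warn(f"{frac:.1%} of values clipped into [0, 1] (threshold {threshold:.0%})")


def _nodata_mask(shape: tuple, fraction: float, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    n_bad = int(round(fraction * mask.size))
    if n_bad:
        idx = rng.choice(mask.size, size=n_bad, replace=False)
        mask.ravel()[idx] = True
    return mask


def generate_trend_stack(config: BasinConfig) -> AnnualStack:
    """Linear-trend FVC stack: intercept + slope * year_index + N(0, sd).

    The year index runs 0..n-1; values are clipped to [0, 1] with a
    warning if more than ``clip_warn_fraction`` of them move.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    slope = np.broadcast_to(np.asarray(config.trend_map, float), (rows, cols))
    intercept = np.broadcast_to(np.asarray(config.intercept, float), (rows, cols))
    i = np.arange(config.n_years, dtype=float)[:, None, None]
    values = intercept[None] + slope[None] * i
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=(config.n_years, rows, cols))
    _warn_clip(values, config.clip_warn_fraction)
    values = np.clip(values, 0.0, 1.0)
    mask = _nodata_mask((rows, cols), config.nodata_fraction, rng)
    return AnnualStack(values, config.years, mask)


def fgn(H: float, n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise, unit variance, shape (size, n).

    Davies-Harte circulant embedding: the autocovariance
    gamma(k) = 0.5 (|k+1|^(2H) - 2|k|^(2H) + |k-1|^(2H)) is embedded in a
    circulant of order 2n whose eigenvalues (nonnegative for fGn) scale
    complex Gaussian spectral weights.
    """
    if not (0 < H < 1):
        raise ValueError("H must lie in (0, 1)")
    k = np.arange(n, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([gamma, [0.0], gamma[1:][::-1]])
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # tiny negatives are FFT round-off
    m = 2 * n
    z = rng.standard_normal((size, m)) + 1j * rng.standard_normal((size, m))
    w = np.fft.fft(z * np.sqrt(lam / (2 * m)), axis=1)
    return np.ascontiguousarray(w.real[:, :n])


def generate_fgn_stack(
    hurst_target: float,
    n_steps: int,
    shape: tuple,
    seed: int = 0,
    mean: float = 0.5,
    sd: float = 0.1,
    nodata_fraction: float = 0.0,
    start_year: int = 2000,
    clip_warn_fraction: float = 0.05,
) -> AnnualStack:
    """FVC stack whose pixel series are fGn with Hurst ``hurst_target``.

    The unit-variance noise is mapped affinely to mean ``mean`` and sd
    ``sd`` (affine maps preserve the R/S slope), then clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    x = fgn(hurst_target, n_steps, rows * cols, rng)
    values = mean + sd * x.T.reshape(n_steps, rows, cols)
    _warn_clip(values, clip_warn_fraction)
    values = np.clip(values, 0.0, 1.0)
    mask = _nodata_mask((rows, cols), nodata_fraction, rng)
    years = np.arange(start_year, start_year + n_steps)
    return AnnualStack(values, years, mask)


def generate_stratified_field(
    spec: StratumSpec,
    shape: tuple,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Value grid and stratum-code grid with a planted q-statistic.

    Pixels are assigned to levels uniformly at random; values are the
    level mean plus N(0, within_sd).  Raises if any level receives fewer
    than 2 pixels (its within-variance would be undefined).
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    codes = rng.integers(1, spec.n_levels + 1, size=(rows, cols))
    counts = np.bincount(codes.ravel(), minlength=spec.n_levels + 1)[1:]
    if counts.min() < 2:
        raise ValueError("a level received < 2 pixels; enlarge the grid")
    mu = np.asarray(spec.level_means, dtype=float)
    values = mu[codes - 1] + rng.normal(0.0, spec.within_sd, size=(rows, cols))
    return values, codes


def microtopography_map(shape: tuple, seed: int = 0, n_types: int = 13) -> np.ndarray:
    """Toy categorical landform map: a smoothed random surface cut into
    ``n_types`` contiguous-ish classes coded 1..n_types."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    rough = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(rough, sigma=min(shape) / 12.0)
    qs = np.quantile(smooth, np.linspace(0, 1, n_types + 1)[1:-1])
    return np.digitize(smooth, qs) + 1


def build_basin(config: BasinConfig | None = None) -> dict:
    """Compose the full synthetic basin and its ground truth.

    Northern half (rows < rows/2): FVC = zone intercept + slope * i +
    white noise, with the slope driven additively by the categorical
    drivers in ``config.strata_spec`` (planted q known in closed form,
    including the slope-estimation noise variance).  Southern half:
    zero-trend fGn bands, one per ``hurst_target`` entry, planted H known.

    Returns a dict with the FVC ``stack``, the ``zones`` map, per-factor
    stratum grids, and a ``truth`` dict of planted maps and expected
    values.
    """
    if config is None:
        config = default_basin_config()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    n = config.n_years
    half = rows // 2
    north = np.zeros((rows, cols), dtype=bool)
    north[:half] = True

    # --- zones and intercepts: planted zone means span high (lower slope,
    # cool) to near-bare (peak/ridge, cool)
    zones = microtopography_map((rows, cols), seed=config.seed + 1)
    zone_codes = np.arange(1, 14)
    zone_intercepts = np.linspace(0.55, 0.25, 13)
    intercept = zone_intercepts[zones - 1]

    # --- slope field on the north half, driven by the categorical drivers
    base_slope = float(np.mean(config.trend_map))
    slope = np.zeros((rows, cols))
    slope[north] = base_slope
    factor_grids: dict[str, np.ndarray] = {}
    truth_q: dict[str, float] = {}
    n_north = int(north.sum())
    # variance of the OLS slope estimate under iid noise: sigma^2 / Sxx
    i1 = np.arange(1, n + 1, dtype=float)
    sxx = ((i1 - i1.mean()) ** 2).sum()
    est_var = config.noise_sd**2 / sxx
    total_effect_var = sum(
        planned_q_var(spec) for spec in config.strata_spec
    )
    for k, spec in enumerate(config.strata_spec):
        codes = np.zeros((rows, cols), dtype=int)
        codes_n = np.random.default_rng(config.seed + 10 + k).integers(
            1, spec.n_levels + 1, size=n_north
        )
        codes[north] = codes_n
        mu = np.asarray(spec.level_means, dtype=float)
        slope[north] += mu[codes_n - 1]
        factor_grids[spec.name] = codes
    # slope jitter: independent pixel-level slope variation
    jitter_sd = float(np.mean([s.within_sd for s in config.strata_spec])) if config.strata_spec else 0.0
    if jitter_sd > 0:
        slope[north] += rng.normal(0.0, jitter_sd, size=n_north)
    # planted q of each factor on the *estimated* slope response:
    # Vb = var of its level means; Vw = everything else incl. estimation noise
    for spec in config.strata_spec:
        vb = planned_q_var(spec)
        # everything the factor does not explain: the other factors' effects,
        # the pixel jitter (applied once), and the slope-estimation noise
        vw = total_effect_var - vb + jitter_sd**2 + est_var
        truth_q[spec.name] = vb / (vb + vw)

    # --- assemble the stack
    i = np.arange(n, dtype=float)[:, None, None]
    values = intercept[None] + slope[None] * i
    values[:, north] += rng.normal(0.0, config.noise_sd, size=(n, n_north))

    # southern fGn bands, one per Hurst regime
    hursts = np.atleast_1d(np.asarray(config.hurst_target, float)).ravel()
    # H is planted only in the southern fGn bands; the trended north half
    # has no planted H (a deterministic trend is persistent by construction)
    hurst_map = np.full((rows, cols), np.nan)
    band_edges = np.linspace(half, rows, hursts.size + 1).astype(int)
    for b, H in enumerate(hursts):
        r0, r1 = band_edges[b], band_edges[b + 1]
        npix = (r1 - r0) * cols
        noise = fgn(H, n, npix, np.random.default_rng(config.seed + 100 + b))
        values[:, r0:r1, :] += config.noise_sd * 2.0 * noise.T.reshape(n, r1 - r0, cols)
        hurst_map[r0:r1, :] = H

    _warn_clip(values, config.clip_warn_fraction)
    values = np.clip(values, 0.0, 1.0)
    mask = _nodata_mask((rows, cols), config.nodata_fraction, rng)
    stack = AnnualStack(values, config.years, mask)

    # expected zone means (percent), from the planted noiseless surface
    expected = intercept + slope * i.mean()
    zone_truth = {
        int(z): float(expected[zones == z].mean() * 100.0) for z in zone_codes
    }

    return {
        "stack": stack,
        "zones": zones,
        "zone_names": dict(MICROTOPO_NAMES),
        "factors": factor_grids,
        "north_mask": north,
        "truth": {
            "slope_map": slope,
            "intercept_map": intercept,
            "hurst_map": hurst_map,
            "planned_q": truth_q,
            "zone_mean_percent": zone_truth,
            "base_slope": base_slope,
            "noise_sd": config.noise_sd,
        },
        "config": config,
    }


def planned_q_var(spec: StratumSpec) -> float:
    """Population variance of a factor's level means under equal weights."""
    mu = np.asarray(spec.level_means, dtype=float)
    return float(((mu - mu.mean()) ** 2).mean())


def default_basin_config(seed: int = 0, grid_shape: tuple = (200, 200)) -> BasinConfig:
    """Study-condition defaults: 21 annual composites, 2000 onward, two
    drivers with planted q of about 0.5 and 0.2, and anti-persistent /
    random / persistent fGn regimes (H = 0.25, 0.5, 0.85) in the south."""
    noise_sd = 0.05
    i1 = np.arange(1, 22, dtype=float)
    sxx = ((i1 - i1.mean()) ** 2).sum()
    est_var = noise_sd**2 / sxx  # variance the slope estimator adds
    # choose a total slope variance able to host q_A=0.5, q_B=0.2 with the
    # remainder split between pixel jitter and estimation noise
    total = max(4.0 * est_var / 0.3, 2.0e-5)
    var_a, var_b = 0.5 * total, 0.2 * total
    jitter_var = 0.3 * total - est_var
    jitter_sd = float(np.sqrt(max(jitter_var, 0.0)))

    def spaced(var: float, L: int) -> tuple:
        base = np.arange(L, dtype=float) - (L - 1) / 2.0
        return tuple(base * np.sqrt(var / ((L**2 - 1) / 12.0)))

    strata = [
        StratumSpec("aspect_class", spaced(var_a, 4), jitter_sd),
        StratumSpec("soil_group", spaced(var_b, 5), jitter_sd),
    ]
    return BasinConfig(
        n_years=21,
        grid_shape=grid_shape,
        seed=seed,
        trend_map=0.003,
        noise_sd=noise_sd,
        hurst_target=(0.25, 0.5, 0.85),
        strata_spec=strata,
        nodata_fraction=0.02,
    )


def truth_sidecar(basin: dict) -> str:
    """JSON-serializable ground-truth summary (for the sidecar file)."""
    t = basin["truth"]
    payload = {
        "planned_q": t["planned_q"],
        "zone_mean_percent": t["zone_mean_percent"],
        "base_slope": t["base_slope"],
        "noise_sd": t["noise_sd"],
        "hurst_regimes": sorted({v for v in np.asarray(t["hurst_map"]).ravel().tolist()
                                 if np.isfinite(v)}),
        "years": basin["stack"].years.tolist(),
    }
    return json.dumps(payload, indent=2, sort_keys=True)
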