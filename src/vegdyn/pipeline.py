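"""Pipeline orchestration: fvc -> trend -> hurst -> zonal -> geodetector.

``run_all`` executes the whole analysis on either a simulated basin or a
directory of annual rasters, writing every tabular product as CSV (with
the run seed in a leading metadata comment) and the per-pixel products as
float32 TIFFs.  Identical configuration and seed reproduce identical
bytes.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fvc import annual_mean_series, fvc_stack
from .geodetector import StratifiedSample, factor_q, interaction_q, risk_detect
from .hurst import FUTURE_CLASSES, classify_future, classify_hurst, hurst_grid
from .raster import write_grid, write_stack
from .synthetic import build_basin, default_basin_config, truth_sidecar
from .trend import TREND_CLASSES, classify_trend, pixel_slope, slope_pvalue, zonal_trend
from .zonal import zonal_class_fractions, zonal_mean

log = logging.getLogger("vegdyn")


@dataclass
class PipelineConfig:
    """Everything `run_all` needs; loadable from a YAML file."""

    out_dir: str = "vegdyn_out"
    seed: int = 0
    simulate: bool = True
    grid_shape: tuple = (200, 200)
    n_years: int = 21
    stack_dir: str | None = None  # used when simulate is False
    stack_kind: str = "fvc"  # "fvc" or "ndvi"
    zones_path: str | None = None
    p_low: float = 5.0
    p_high: float = 95.0
    global_endmembers: bool = False
    hurst_band: float = 0.05
    hurst_windows: list | None = None
    literal_eq5: bool = False
    alpha: float = 0.05
    permutations: int = 199
    write_rasters: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.grid_shape, list):
            cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg


def _write_csv(df: pd.DataFrame, path: Path, seed: int):
    with open(path, "w") as fh:
        fh.write(f"# vegdyn {__version__} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write all products under ``config.out_dir``.

    Returns a dict of the in-memory results (stack, trend, hurst grids,
    tables) plus ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_log(out)
    log.info("vegdyn %s on python %s", __version__, platform.python_version())
    log.info("config: %s", config)

    basin = None
    if config.simulate:
        log.info("stage simulate: %s grid, %d years, seed %d",
                 config.grid_shape, config.n_years, config.seed)
        bconf = default_basin_config(seed=config.seed, grid_shape=tuple(config.grid_shape))
        bconf.n_years = config.n_years
        basin = build_basin(bconf)
        stack = basin["stack"]
        zones = basin["zones"]
        zone_names = basin["zone_names"]
        (out / "ground_truth.json").write_text(truth_sidecar(basin))
        if config.write_rasters:
            write_stack(stack, out / "fvc_stack")
            write_grid(out / "zones.tif", zones.astype(np.float32))
    else:
        from .raster import read_grid, read_stack

        if config.stack_dir is None:
            raise ValueError("stack_dir required when simulate is False")
        stack = read_stack(config.stack_dir)
        zones = None
        zone_names = None
        if config.zones_path:
            zones = read_grid(config.zones_path)
            zones = np.nan_to_num(zones, nan=0.0).astype(int)

    # --- fvc stage
    if config.stack_kind == "ndvi":
        log.info("stage fvc: dichotomous model, endmember percentiles (%g, %g)",
                 config.p_low, config.p_high)
        stack = fvc_stack(stack, config.p_low, config.p_high, config.global_endmembers)
    series = annual_mean_series(stack)
    _write_csv(series, out / "annual_mean_fvc.csv", config.seed)

    # --- trend stage
    log.info("stage trend: per-pixel OLS slope + t-test")
    trend = slope_pvalue(stack, pixel_slope(stack))
    trend, trend_frac = classify_trend(trend)
    _write_csv(trend_frac, out / "trend_class_fractions.csv", config.seed)
    if config.write_rasters:
        write_grid(out / "trend_slope.tif", trend.slope)
        write_grid(out / "trend_pvalue.tif", trend.p_value)
        write_grid(out / "trend_class.tif", trend.change_class.astype(np.float32))

    # --- hurst stage
    log.info("stage hurst: R/S exponent, windows=%s", config.hurst_windows or "auto")
    hg = hurst_grid(stack, windows=config.hurst_windows, literal_eq5=config.literal_eq5)
    hg = classify_hurst(hg, band=config.hurst_band)
    hg, future_frac = classify_future(hg, trend.slope, trend.p_value, alpha=config.alpha)
    _write_csv(future_frac, out / "future_class_fractions.csv", config.seed)
    if config.write_rasters:
        write_grid(out / "hurst.tif", hg.H)
        write_grid(out / "future_class.tif", hg.future_class.astype(np.float32))

    results: dict = {
        "out_dir": out,
        "stack": stack,
        "series": series,
        "trend": trend,
        "trend_fractions": trend_frac,
        "hurst": hg,
        "future_fractions": future_frac,
        "basin": basin,
    }

    # --- zonal stage
    if zones is not None:
        log.info("stage zonal: microtopographic summaries")
        zmean = zonal_mean(stack.values, zones, zone_names)
        _write_csv(zmean, out / "zonal_mean_fvc.csv", config.seed)
        zfrac = zonal_class_fractions(trend.change_class, zones, TREND_CLASSES, zone_names)
        _write_csv(zfrac, out / "zonal_trend_class_fractions.csv", config.seed)
        zffrac = zonal_class_fractions(hg.future_class, zones, FUTURE_CLASSES, zone_names)
        _write_csv(zffrac, out / "zonal_future_class_fractions.csv", config.seed)
        # per-zone regression of zonal annual means on calendar year
        rows = []
        for z in np.unique(zones):
            if z == 0:
                continue
            sel = (zones == z) & stack.valid
            if not sel.any():
                continue
            for i, year in enumerate(stack.years):
                rows.append({
                    "zone": (zone_names or {}).get(int(z), str(int(z))),
                    "year": int(year),
                    "mean_fvc_percent": float(stack.values[i][sel].mean() * 100.0),
                })
        ztrend = zonal_trend(pd.DataFrame(rows))
        _write_csv(ztrend, out / "zonal_trend.csv", config.seed)
        results.update({"zonal_mean": zmean, "zonal_trend": ztrend,
                        "zonal_trend_fractions": zfrac, "zonal_future_fractions": zffrac})

    # --- geodetector stage
    if basin is not None and basin["factors"]:
        log.info("stage geodetector: q / interaction / risk on the FVC slope")
        north = basin["north_mask"] & stack.valid
        y = trend.slope[north]
        strata = {name: grid[north] for name, grid in basin["factors"].items()}
        sample = StratifiedSample(y=y, strata=strata)
        qrows = []
        for name in strata:
            q, p = factor_q(sample, name, permutations=config.permutations,
                            seed=config.seed)
            qrows.append({"factor": name, "q": q, "p_value": p})
        qtab = pd.DataFrame(qrows)
        _write_csv(qtab, out / "factor_q.csv", config.seed)
        names = list(strata)
        irows = [interaction_q(sample, a, b)
                 for ai, a in enumerate(names) for b in names[ai + 1:]]
        itab = pd.DataFrame(irows)
        _write_csv(itab, out / "interactions.csv", config.seed)
        for name in strata:
            risk = risk_detect(sample, name, alpha=config.alpha)
            tab = risk["table"].copy()
            # report the mean FVC slope x 10^4, the conventional display scale
            tab["mean_slope_x1e4"] = tab.pop("mean_y") * 1e4
            tab["most_favorable"] = tab["level_code"] == risk["most_favorable_code"]
            _write_csv(tab, out / f"risk_{name}.csv", config.seed)
        results.update({"factor_q": qtab, "interactions": itab})

    log.info("run complete: %s", out)
    return results


def _setup_log(out: Path):
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(sh)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
    log.addHandler(fh)
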