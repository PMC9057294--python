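"""Raster I/O: one single-band float32 TIFF per year plus a JSON sidecar.

The sidecar (``stack.json``) records the year labels, the nodata value
(-9999 by default), and the per-year file names, so a written stack
round-trips bit-exactly at float32 precision.  Grids are addressed in
raster row/col convention (origin top-left).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import tifffile

from .stack import AnnualStack, NODATA

_YEAR_RE = re.compile(r"(\d{4})\.tiff?$")


def write_grid(path: str | Path, grid: np.ndarray, nodata: float = NODATA) -> Path:
    """Write one grid as float32 TIFF, NaN encoded as the nodata value."""
    path = Path(path)
    arr = np.asarray(grid, dtype=np.float32).copy()
    arr[~np.isfinite(arr)] = nodata
    tifffile.imwrite(path, arr)
    return path


def read_grid(path: str | Path, nodata: float = NODATA) -> np.ndarray:
    """Read a single-band TIFF; nodata decodes to NaN."""
    arr = np.asarray(tifffile.imread(path), dtype=float)
    arr[arr == nodata] = np.nan
    return arr


def write_stack(stack: AnnualStack, directory: str | Path, prefix: str = "fvc",
                nodata: float = NODATA) -> Path:
    """Write an annual stack as per-year TIFFs plus ``stack.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, year in enumerate(stack.years):
        layer = stack.values[i].astype(np.float32)
        layer = layer.copy()
        layer[stack.nodata_mask] = nodata
        layer[~np.isfinite(layer)] = nodata
        name = f"{prefix}_{year}.tif"
        tifffile.imwrite(directory / name, layer)
        files.append(name)
    sidecar = {
        "years": [int(y) for y in stack.years],
        "nodata": nodata,
        "files": files,
    }
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_stack(source: str | Path | list, nodata: float = NODATA) -> AnnualStack:
    """Read an annual stack from a directory (with ``stack.json``) or an
    explicit list of per-year TIFF paths.

    Without a sidecar, years are parsed from trailing 4-digit groups in
    the file names.  All rasters must share the grid shape; the stack mask
    is the union of per-year nodata.
    """
    if isinstance(source, (str, Path)):
        directory = Path(source)
        sidecar_path = directory / "stack.json"
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            paths = [directory / f for f in meta["files"]]
            years = meta["years"]
            nodata = meta.get("nodata", nodata)
        else:
            paths = sorted(directory.glob("*.tif")) + sorted(directory.glob("*.tiff"))
            years = _years_from_names(paths)
    else:
        paths = [Path(p) for p in source]
        years = _years_from_names(paths)
    if not paths:
        raise FileNotFoundError(f"no rasters found in {source}")
    order = np.argsort(years)
    years = [years[i] for i in order]
    paths = [paths[i] for i in order]
    if len(set(years)) != len(years):
        raise ValueError("duplicate year labels in stack")
    layers = []
    shape = None
    for p, y in zip(paths, years):
        arr = np.asarray(tifffile.imread(p), dtype=float)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"grid mismatch in {p.name}: {arr.shape} vs {shape}")
        layers.append(arr)
    values = np.stack(layers)
    mask = np.any((values == nodata) | ~np.isfinite(values), axis=0)
    values[:, mask] = np.nan
    return AnnualStack(values, np.array(years), mask)


def _years_from_names(paths: list) -> list[int]:
    years = []
    for p in paths:
        m = _YEAR_RE.search(Path(p).name)
        if not m:
            raise ValueError(f"cannot parse a year from file name {Path(p).name!r}")
        years.append(int(m.group(1)))
    return years
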