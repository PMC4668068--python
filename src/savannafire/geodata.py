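"""Reading and writing the rasters, vectors and tables the pipeline touches.

Raster formats
--------------
* single-band TIFF (``.tif`` / ``.tiff``) via :mod:`tifffile`, with grid
  geometry (pixel size, origin, CRS label) carried in a small JSON sidecar
  ``<name>.grid.json`` written next to the raster;
* ESRI ASCII grid (``.asc``), a plain-text header-plus-matrix format whose
  header itself carries cell size and origin.

Any nonzero, non-nodata value in a burnt-area raster means "burnt"; nodata is
treated as unburnt (conservative for frequency metrics) and logged.

Vector input is GeoJSON with a ``unit`` property per feature mapping to
lowland / upland; geometries are handled by :mod:`shapely`.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as shapely_shape

from .grid import (
    UNIT_CODES,
    FireHistory,
    GridGeometry,
    LandscapeUnits,
    Season,
    SeasonalBurnMask,
    Unit,
)

logger = logging.getLogger("savannafire")

__all__ = [
    "classify_burn_date",
    "read_burn_raster",
    "write_burn_raster",
    "assemble_history",
    "write_history",
    "read_history",
    "read_unit_polygons",
    "rasterize_units",
]

ASC_NODATA = -9999


def classify_burn_date(month: int) -> Season:
    """Map a calendar month to its dry-season half.

    Months 1-7 (pre-August, including the wet season) are early dry season;
    months 8-12 (post-July) are late dry season.
    """
    month = int(month)
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return Season.EDS if month <= 7 else Season.LDS


# ---------------------------------------------------------------------------
# raster I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".grid.json")


def _write_asc(path: Path, arr: np.ndarray, grid: GridGeometry) -> None:
    x0, y0 = grid.origin
    yll = y0 - grid.n_rows * grid.pixel_size  # ASCII grid origin is the lower-left corner
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {yll}\n"
        f"cellsize {grid.pixel_size}\n"
        f"NODATA_value {ASC_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%d")


def _read_asc(path: Path) -> tuple[np.ndarray, GridGeometry]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            key = line.split()[0].lower() if line.split() else ""
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(line.split()[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        arr = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header.get("cellsize", 250.0)
    y0 = header.get("yllcorner", 0.0) + n_rows * cell
    grid = GridGeometry(n_rows, n_cols, cell, (header.get("xllcorner", 0.0), y0))
    nodata = header.get("nodata_value", ASC_NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    return arr, grid


def write_burn_raster(mask: SeasonalBurnMask, path: str | os.PathLike) -> Path:
    """Write a seasonal burn mask as a single-band raster (.tif or .asc)."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        _write_asc(path, mask.mask.astype(np.int64), mask.grid)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, mask.mask.astype(np.uint8))
        g = mask.grid
        _sidecar_path(path).write_text(
            json.dumps(
                {
                    "pixel_size": g.pixel_size,
                    "origin": list(g.origin),
                    "crs_label": g.crs_label,
                },
                indent=0,
            )
        )
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r} (use .tif or .asc)")
    return path


def read_burn_raster(
    path: str | os.PathLike,
    year: int,
    season: Season | str,
    grid: GridGeometry | None = None,
) -> SeasonalBurnMask:
    """Read a single-band burnt-area raster into a binary seasonal mask.

    Any nonzero, finite value is burnt; nodata/NaN counts as unburnt. If
    ``grid`` is given, the file's shape (and geometry, where the format
    carries one) must match it; a mismatch raises ``ValueError`` naming both
    shapes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".asc":
        arr, file_grid = _read_asc(path)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        arr = np.asarray(tifffile.imread(path), dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster, got shape {arr.shape}")
        meta = {}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        file_grid = GridGeometry(
            arr.shape[0],
            arr.shape[1],
            meta.get("pixel_size", 250.0),
            tuple(meta.get("origin", (0.0, 0.0))),
            meta.get("crs_label", "local"),
        )
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r} (use .tif or .asc)")

    if grid is not None and file_grid.shape != grid.shape:
        raise ValueError(
            f"{path}: raster shape {file_grid.shape} does not match established grid {grid.shape}"
        )
    n_nodata = int(np.isnan(arr).sum())
    if n_nodata:
        logger.warning("%s: %d nodata pixels treated as unburnt", path, n_nodata)
    binary = (np.nan_to_num(arr, nan=0.0) != 0).astype(np.uint8)
    return SeasonalBurnMask(grid or file_grid, int(year), Season(season), binary)


def assemble_history(masks: Iterable[SeasonalBurnMask]) -> FireHistory:
    """Assemble seasonal masks into a validated, gap-free FireHistory.

    A season missing within the covered year range is filled with an all-zero
    mask and logged; a duplicate (year, season) or a grid shape conflict is an
    error.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("no masks supplied")
    grid = masks[0].grid
    by_key: dict[tuple[int, Season], SeasonalBurnMask] = {}
    for m in masks:
        if m.grid.shape != grid.shape:
            raise ValueError(f"grid conflict: {m.grid.shape} vs {grid.shape}")
        key = (m.year, m.season)
        if key in by_key:
            raise ValueError(f"duplicate mask for year {m.year} season {m.season.value}")
        by_key[key] = m
    years = list(range(min(y for y, _ in by_key), max(y for y, _ in by_key) + 1))
    eds = np.zeros((len(years), *grid.shape), dtype=np.uint8)
    lds = np.zeros_like(eds)
    for i, year in enumerate(years):
        for season, stack in ((Season.EDS, eds), (Season.LDS, lds)):
            m = by_key.get((year, season))
            if m is None:
                logger.warning("no %s mask for %d; filled with all-unburnt", season.value, year)
            else:
                stack[i] = m.mask
    return FireHistory(grid, years, eds, lds)


def write_history(history: FireHistory, out_dir: str | os.PathLike, fmt: str = "tif") -> Path:
    """Write a FireHistory under the ``burn_<year>_<EDS|LDS>.<fmt>`` convention."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for m in history.masks():
        write_burn_raster(m, out_dir / f"burn_{m.year}_{m.season.value}.{fmt}")
    return out_dir


def read_history(in_dir: str | os.PathLike) -> FireHistory:
    """Read every ``burn_<year>_<EDS|LDS>.*`` raster in a directory."""
    in_dir = Path(in_dir)
    masks = []
    for path in sorted(in_dir.iterdir()):
        stem_parts = path.stem.split("_")
        if path.suffix.lower() not in {".tif", ".tiff", ".asc"}:
            continue
        if len(stem_parts) != 3 or stem_parts[0] != "burn":
            continue
        masks.append(read_burn_raster(path, int(stem_parts[1]), Season(stem_parts[2])))
    if not masks:
        raise FileNotFoundError(f"no burn_<year>_<EDS|LDS> rasters found in {in_dir}")
    return assemble_history(masks)


# ---------------------------------------------------------------------------
# landscape units


def read_unit_polygons(path: str | os.PathLike) -> list[tuple[object, Unit]]:
    """Read (geometry, unit) pairs from a GeoJSON FeatureCollection.

    Each feature must carry a ``unit`` property equal to "lowland" or
    "upland" (case-insensitive).
    """
    data = json.loads(Path(path).read_text())
    features = data.get("features", [])
    if not features:
        raise ValueError(f"{path}: empty vector layer")
    out = []
    for feat in features:
        props = feat.get("properties") or {}
        raw = props.get("unit")
        if raw is None:
            raise ValueError(f"{path}: feature missing 'unit' property")
        try:
            unit = Unit(str(raw).upper())
        except ValueError:
            raise ValueError(f"{path}: unknown unit {raw!r} (expected lowland/upland)")
        if unit is Unit.OUTSIDE:
            raise ValueError(f"{path}: unit may not be 'outside'")
        out.append((shapely_shape(feat["geometry"]), unit))
    return out


def rasterize_units(
    polygons: Sequence[tuple[object, Unit]] | str | os.PathLike,
    grid: GridGeometry,
) -> LandscapeUnits:
    """Rasterize lowland/upland polygons onto the grid by pixel-centre containment.

    A pixel belongs to the unit whose polygon contains its centre; pixels
    covered by no polygon are OUTSIDE. Overlaps resolve last-wins (layer
    order) with a logged warning.
    """
    if isinstance(polygons, (str, os.PathLike)):
        polygons = read_unit_polygons(polygons)
    polygons = list(polygons)
    if not polygons:
        logger.warning("rasterize_units: no polygons; all pixels OUTSIDE")
    labels = np.full(grid.shape, UNIT_CODES[Unit.OUTSIDE], dtype=np.uint8)
    xs, ys = grid.pixel_centres()
    claimed = np.zeros(grid.shape, dtype=bool)
    for geom, unit in polygons:
        inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(grid.shape)
        n_over = int((inside & claimed & (labels != UNIT_CODES[Unit(unit)])).sum())
        if n_over:
            logger.warning(
                "rasterize_units: %d pixels reassigned by overlapping %s polygon (last wins)",
                n_over,
                Unit(unit).value,
            )
        labels[inside] = UNIT_CODES[Unit(unit)]
        claimed |= inside
    return LandscapeUnits(grid, labels)
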