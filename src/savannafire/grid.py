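"""Core raster containers: grid geometry, seasonal burn masks, fire histories
and landscape-unit rasters.

The pipeline works on a single shared grid (north-up, row-major, origin at the
top-left corner). Masks are plain ``numpy`` ``uint8`` arrays with values in
{0, 1}; a 1 means the pixel burnt at least once in that season. Multiple burns
of the same pixel within one season are indistinguishable at the 250 m mapping
scale and therefore collapse to a single 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Season",
    "Unit",
    "GridGeometry",
    "SeasonalBurnMask",
    "FireHistory",
    "LandscapeUnits",
]


class Season(str, enum.Enum):
    """Dry-season halves used for seasonal burnt-area mapping.

    EDS (early dry season) is the pre-August part of the calendar year, when
    prescribed burns are milder and patchier; LDS (late dry season) is the
    post-July part dominated by severe wildfires.
    """

    EDS = "EDS"
    LDS = "LDS"


class Unit(str, enum.Enum):
    """Landscape strata: lowland (laterised sedimentary) vs upland (rugged
    sandstone) savanna, plus OUTSIDE for pixels in neither."""

    LOWLAND = "LOWLAND"
    UPLAND = "UPLAND"
    OUTSIDE = "OUTSIDE"


# integer codes used in the LandscapeUnits label raster
UNIT_CODES: dict[Unit, int] = {Unit.OUTSIDE: 0, Unit.LOWLAND: 1, Unit.UPLAND: 2}


@dataclass(frozen=True)
class GridGeometry:
    """Regular raster grid shared by every layer of one analysis.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape.
    pixel_size
        Pixel edge length in metres (default 250, the burnt-area mapping
        scale).
    origin
        Map coordinates (x, y) of the top-left corner of pixel (0, 0); y
        decreases down rows (north-up convention).
    crs_label
        Opaque coordinate-system identifier; never interpreted.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 250.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid shape must be >= 1x1, got {self.n_rows}x{self.n_cols}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pixel_area_ha(self) -> float:
        """Pixel area in hectares (6.25 ha at 250 m)."""
        return self.pixel_size**2 / 1e4

    @property
    def pixel_area_km2(self) -> float:
        """Pixel area in square kilometres (0.0625 km2 at 250 m)."""
        return self.pixel_size**2 / 1e6

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every pixel centre, each shaped (n_rows, n_cols)."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        rows = y0 - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        xs, ys = np.meshgrid(cols, rows)
        return xs, ys


def _validate_mask(mask: np.ndarray, grid: GridGeometry) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.shape != grid.shape:
        raise ValueError(f"mask shape {arr.shape} does not match grid {grid.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("burn mask must be binary (values in {0, 1})")
    return arr.astype(np.uint8, copy=False)


@dataclass(frozen=True)
class SeasonalBurnMask:
    """Binary burnt/unburnt raster for one (calendar year, season)."""

    grid: GridGeometry
    year: int
    season: Season
    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "season", Season(self.season))
        object.__setattr__(self, "mask", _validate_mask(self.mask, self.grid))

    @property
    def burnt_pixels(self) -> int:
        return int(self.mask.sum())

    def burnt_area_ha(self) -> float:
        return self.burnt_pixels * self.grid.pixel_area_ha


@dataclass
class FireHistory:
    """A contiguous multi-year stack of seasonal burnt-area masks.

    ``eds`` and ``lds`` are (n_years, n_rows, n_cols) uint8 arrays aligned with
    ``years``, which must be contiguous ascending calendar years.
    """

    grid: GridGeometry
    years: list[int]
    eds: np.ndarray
    lds: np.ndarray

    def __post_init__(self) -> None:
        self.years = [int(y) for y in self.years]
        if not self.years:
            raise ValueError("FireHistory needs at least one year")
        if self.years != list(range(self.years[0], self.years[-1] + 1)):
            raise ValueError(f"years must be contiguous ascending, got {self.years}")
        expect = (len(self.years), self.grid.n_rows, self.grid.n_cols)
        for name in ("eds", "lds"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != expect:
                raise ValueError(f"{name} stack shape {arr.shape} != expected {expect}")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} stack must be binary")
            setattr(self, name, arr.astype(np.uint8, copy=False))

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        if year not in self.years:
            raise KeyError(f"year {year} not in history {self.years[0]}-{self.years[-1]}")
        return year - self.years[0]

    def seasonal_mask(self, year: int, season: Season) -> np.ndarray:
        stack = self.eds if Season(season) is Season.EDS else self.lds
        return stack[self.year_index(year)]

    def annual_mask(self, year: int) -> np.ndarray:
        """Pixelwise union of the year's EDS and LDS masks."""
        i = self.year_index(year)
        return np.logical_or(self.eds[i], self.lds[i]).astype(np.uint8)

    def annual_stack(self) -> np.ndarray:
        return np.logical_or(self.eds, self.lds).astype(np.uint8)

    def masks(self) -> Iterable[SeasonalBurnMask]:
        for i, year in enumerate(self.years):
            yield SeasonalBurnMask(self.grid, year, Season.EDS, self.eds[i])
            yield SeasonalBurnMask(self.grid, year, Season.LDS, self.lds[i])


@dataclass
class LandscapeUnits:
    """Categorical raster assigning each pixel to LOWLAND / UPLAND / OUTSIDE."""

    grid: GridGeometry
    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.shape != self.grid.shape:
            raise ValueError(f"labels shape {arr.shape} != grid {self.grid.shape}")
        if not np.isin(arr, list(UNIT_CODES.values())).all():
            raise ValueError("labels must use codes 0 (outside), 1 (lowland), 2 (upland)")
        self.labels = arr.astype(np.uint8, copy=False)

    def unit_mask(self, unit: Unit) -> np.ndarray:
        return self.labels == UNIT_CODES[Unit(unit)]

    def in_unit_mask(self) -> np.ndarray:
        """Boolean mask of all pixels belonging to any landscape unit."""
        return self.labels != UNIT_CODES[Unit.OUTSIDE]

    def pixel_count(self, unit: Unit) -> int:
        return int(self.unit_mask(unit).sum())

    @property
    def unit_area_ha(self) -> Mapping[Unit, float]:
        return {
            u: self.pixel_count(u) * self.grid.pixel_area_ha
            for u in (Unit.LOWLAND, Unit.UPLAND)
        }

    @property
    def unit_area_km2(self) -> Mapping[Unit, float]:
        return {
            u: self.pixel_count(u) * self.grid.pixel_area_km2
            for u in (Unit.LOWLAND, Unit.UPLAND)
        }

    def present_units(self) -> list[Unit]:
        return [u for u in (Unit.LOWLAND, Unit.UPLAND) if self.pixel_count(u) > 0]


def full_lowland_units(grid: GridGeometry) -> LandscapeUnits:
    """A LandscapeUnits layer assigning the entire grid to LOWLAND.

    Convenience for whole-of-site analyses where no stratification is wanted.
    """
    labels = np.full(grid.shape, UNIT_CODES[Unit.LOWLAND], dtype=np.uint8)
    return LandscapeUnits(grid, labels)
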