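"""Contiguously burnt areas (CBAs): labeling, patch statistics and
patch-size-class distributions.

A CBA is a maximal set of burnt pixels connected orthogonally or diagonally
(8-connectivity). CBAs are labeled per (year, scope) where scope is EDS, LDS
or ANNUAL (the pixelwise union of both seasons — coalescing or continuing
fires merge). Labeling runs on the whole-site mask; a patch straddling the
lowland/upland boundary is one CBA whose area is attributed to units by
pixel membership, while size-class binning uses its total size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import FireHistory, GridGeometry, LandscapeUnits, Unit
from .regime import AssessmentWindow, _mean_sem

logger = logging.getLogger("savannafire")

__all__ = [
    "SCOPES",
    "DEFAULT_BIN_EDGES_KM2",
    "label_cbas",
    "annual_cba_mask",
    "patch_stats",
    "size_class_distribution",
    "patch_table",
    "PatchStats",
    "SizeClassDistribution",
]

SCOPES = ("EDS", "LDS", "ANNUAL")

# (0,1], (1,10], (10,100], (100,1000], (1000,inf) km2 — contains the <1 km2
# ecological guideline and the >10 / >1000 km2 reporting boundaries
DEFAULT_BIN_EDGES_KM2 = (0.0, 1.0, 10.0, 100.0, 1000.0, float("inf"))

_STRUCTURE_8 = np.ones((3, 3), dtype=int)


def _scope_mask(history: FireHistory, year: int, scope: str) -> np.ndarray:
    if scope == "EDS":
        return history.seasonal_mask(year, "EDS")
    if scope == "LDS":
        return history.seasonal_mask(year, "LDS")
    if scope == "ANNUAL":
        return history.annual_mask(year)
    raise ValueError(f"unknown scope {scope!r} (expected EDS, LDS or ANNUAL)")


def annual_cba_mask(history: FireHistory, year: int) -> np.ndarray:
    """Pixelwise union of a year's EDS and LDS burnt masks."""
    return history.annual_mask(year)


def label_cbas(mask: np.ndarray, grid: GridGeometry) -> tuple[np.ndarray, int]:
    """Label 8-connected CBAs in a binary mask.

    Returns (labels, n_patches); labels are 1..n in row-major order of each
    patch's first pixel (deterministic across runs). An empty mask yields
    zero patches.
    """
    arr = np.asarray(mask)
    labels, n = ndimage.label(arr, structure=_STRUCTURE_8)
    # scipy already assigns labels in raster-scan order of first encounter,
    # which is exactly row-major order of each patch's first pixel
    return labels, int(n)


def patch_table(
    history: FireHistory,
    units: LandscapeUnits | None = None,
    years: list[int] | None = None,
    scopes: tuple[str, ...] = SCOPES,
) -> pd.DataFrame:
    """One row per CBA: year, scope, patch id, pixel count, area, per-unit area.

    Patch ids restart at 1 within each (year, scope).
    """
    rows = []
    area_px = history.grid.pixel_area_km2
    for year in years or history.years:
        for scope in scopes:
            mask = _scope_mask(history, year, scope)
            labels, n = label_cbas(mask, history.grid)
            if n == 0:
                continue
            counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
            unit_counts = {}
            if units is not None:
                for unit in (Unit.LOWLAND, Unit.UPLAND):
                    umask = units.unit_mask(unit)
                    unit_counts[unit] = np.bincount(
                        labels[umask].ravel(), minlength=n + 1
                    )[1:]
            for pid in range(1, n + 1):
                row = {
                    "year": year,
                    "scope": scope,
                    "patch_id": pid,
                    "pixel_count": int(counts[pid - 1]),
                    "area_km2": counts[pid - 1] * area_px,
                }
                for unit, uc in unit_counts.items():
                    row[f"area_{unit.value.lower()}_km2"] = uc[pid - 1] * area_px
                rows.append(row)
    cols = ["year", "scope", "patch_id", "pixel_count", "area_km2"]
    if units is not None:
        cols += ["area_lowland_km2", "area_upland_km2"]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class PatchStats:
    """Site-level patch statistics for one window and scope."""

    window: AssessmentWindow
    scope: str
    mean_patch_size_km2: float
    sem_patch_size_km2: float
    mean_annual_count: float
    sem_annual_count: float
    zero_patch_years: int


def patch_stats(
    history: FireHistory,
    units: LandscapeUnits | None,
    window: AssessmentWindow,
    scope: str = "ANNUAL",
) -> PatchStats:
    """Mean annual patch size and patch count (± SEM over window years).

    CBAs are labeled on the full site mask. A year with zero patches
    contributes 0 to the count series but is excluded from the size series
    (its mean size is undefined); such years are flagged in the result.
    """
    window.check_within(history)
    sizes_by_year: list[float] = []
    counts: list[int] = []
    zero_years = 0
    area_px = history.grid.pixel_area_km2
    for year in window.years:
        mask = _scope_mask(history, year, scope)
        labels, n = label_cbas(mask, history.grid)
        counts.append(n)
        if n == 0:
            zero_years += 1
            continue
        patch_px = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        sizes_by_year.append(float(patch_px.mean() * area_px))
    if zero_years:
        logger.warning(
            "patch_stats %s %s: %d year(s) with zero patches excluded from the size mean",
            window.label(), scope, zero_years,
        )
    mean_count, sem_count = _mean_sem(np.array(counts, dtype=float))
    if sizes_by_year:
        mean_size, sem_size = _mean_sem(np.array(sizes_by_year))
    else:
        mean_size, sem_size = float("nan"), float("nan")
    return PatchStats(window, scope, mean_size, sem_size, mean_count, sem_count, zero_years)


@dataclass(frozen=True)
class SizeClassDistribution:
    """Per-unit burnt-area proportions by patch size class, over one window.

    ``mean`` and ``sem`` map unit -> array over bins of the mean (± SEM over
    window years) proportion of the unit's area burnt by CBAs in that size
    class. Bin membership is decided by each CBA's total size; the area
    credited to a unit is only the part of the CBA inside it.
    """

    window: AssessmentWindow
    scope: str
    bin_edges_km2: tuple[float, ...]
    mean: dict[Unit, np.ndarray]
    sem: dict[Unit, np.ndarray]
    yearly: dict[Unit, np.ndarray]  # (n_years, n_bins)

    @property
    def bin_labels(self) -> list[str]:
        e = self.bin_edges_km2
        return [
            f"({e[i]:g},{e[i+1]:g}]" if np.isfinite(e[i + 1]) else f">{e[i]:g}"
            for i in range(len(e) - 1)
        ]


def size_class_distribution(
    history: FireHistory,
    units: LandscapeUnits,
    window: AssessmentWindow,
    scope: str = "ANNUAL",
    bin_edges_km2: tuple[float, ...] = DEFAULT_BIN_EDGES_KM2,
) -> SizeClassDistribution:
    """Patch-size-class distribution of burnt area, as proportions of unit area.

    For each window year, every CBA is assigned to a size class by its total
    area; a unit's proportion for a class is the summed CBA area falling
    inside the unit divided by the unit area. Per year the proportions sum to
    the unit's burnt fraction for the scope.
    """
    window.check_within(history)
    edges = np.asarray(bin_edges_km2, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0) or edges[0] != 0.0:
        raise ValueError("bin edges must be increasing, start at 0 and be exhaustive over (0, inf)")
    if np.isfinite(edges[-1]):
        raise ValueError("last bin edge must be +inf so bins are exhaustive")
    n_bins = len(edges) - 1
    area_px = history.grid.pixel_area_km2
    present = units.present_units()
    yearly = {u: np.zeros((window.length_years, n_bins)) for u in present}
    for yi, year in enumerate(window.years):
        mask = _scope_mask(history, year, scope)
        labels, n = label_cbas(mask, history.grid)
        if n == 0:
            continue
        patch_px = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        total_km2 = patch_px * area_px
        # right-closed bins: patch of exactly 1 km2 falls in (0,1]
        bin_idx = np.searchsorted(edges, total_km2, side="left") - 1
        for unit in present:
            umask = units.unit_mask(unit)
            in_unit_px = np.bincount(labels[umask].ravel(), minlength=n + 1)[1:]
            unit_area = umask.sum() * area_px
            for b in range(n_bins):
                sel = bin_idx == b
                yearly[unit][yi, b] = (in_unit_px[sel] * area_px).sum() / unit_area
    mean, sem = {}, {}
    for unit in present:
        stats = [_mean_sem(yearly[unit][:, b]) for b in range(n_bins)]
        mean[unit] = np.array([s[0] for s in stats])
        sem[unit] = np.array([s[1] for s in stats])
    return SizeClassDistribution(window, scope, tuple(edges), mean, sem, yearly)
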