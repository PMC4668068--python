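"""Seasonal fire frequency and long-unburnt habitat metrics.

Fire frequency for a landscape unit is the mean, over the years of an
assessment window, of the fraction of unit pixels burnt in that year
(equivalently: the mean per-pixel count of burnt years divided by the window
length — both computed and cross-checked in the tests). The standard error
is taken across the window's years (sample SD over n years / sqrt(n)),
matching per-window error bars on five annual values.

Time since last burnt (TSLB) is counted in whole calendar years; a pixel
burnt in the assessment year has TSLB 0, and a pixel with no recorded burn is
censored at (as_of_year - first_year + 1). "Unburnt for at least N years at
the end of year Y" means no burn in years Y-N+1 .. Y inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import FireHistory, LandscapeUnits, Unit

__all__ = [
    "AssessmentWindow",
    "FrequencySummary",
    "UnburntSummary",
    "TSLBRaster",
    "seasonal_frequency",
    "time_since_last_burnt",
    "long_unburnt_proportion",
]


@dataclass(frozen=True)
class AssessmentWindow:
    """A block of consecutive calendar years (default length 5)."""

    start_year: int
    length_years: int = 5

    def __post_init__(self) -> None:
        if self.length_years < 1:
            raise ValueError("window length must be >= 1")

    @property
    def end_year(self) -> int:
        return self.start_year + self.length_years - 1

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))

    def check_within(self, history: FireHistory) -> None:
        if self.start_year not in history.years or self.end_year not in history.years:
            raise ValueError(
                f"window {self.start_year}-{self.end_year} not within history "
                f"{history.years[0]}-{history.years[-1]}"
            )

    def label(self) -> str:
        return f"{self.start_year}-{self.end_year}"


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem


@dataclass(frozen=True)
class FrequencySummary:
    """Per-unit seasonal fire frequencies (fires per year) over one window."""

    unit: Unit
    window: AssessmentWindow
    mean: dict[str, float]  # keys: EDS, LDS, ANNUAL
    sem: dict[str, float]
    valid: bool = True  # False for an empty (zero-pixel) unit


@dataclass(frozen=True)
class UnburntSummary:
    """Proportion of a unit long-unburnt as of a given year."""

    unit: Unit
    as_of_year: int
    proportion_unburnt_ge3: float
    proportion_unburnt_ge5: float
    valid: bool = True


@dataclass(frozen=True)
class TSLBRaster:
    """Whole-year time since last burnt, with right-censoring.

    ``censored`` marks pixels with no burn in the available history; for
    those, ``years`` holds the censoring bound (as_of_year - first_year + 1),
    read as "TSLB >= bound".
    """

    as_of_year: int
    years: np.ndarray
    censored: np.ndarray


def seasonal_frequency(
    history: FireHistory,
    units: LandscapeUnits,
    window: AssessmentWindow,
) -> dict[Unit, FrequencySummary]:
    """Mean EDS / LDS / annual fire frequency (± SEM) per landscape unit.

    The per-year statistic is the burnt fraction of the unit (annual mask =
    EDS ∪ LDS); the window mean and SEM are over the window's years. An empty
    unit yields a flagged invalid summary rather than NaNs.
    """
    window.check_within(history)
    i0 = history.year_index(window.start_year)
    sl = slice(i0, i0 + window.length_years)
    stacks = {
        "EDS": history.eds[sl].astype(bool),
        "LDS": history.lds[sl].astype(bool),
        "ANNUAL": history.annual_stack()[sl].astype(bool),
    }
    out: dict[Unit, FrequencySummary] = {}
    for unit in (Unit.LOWLAND, Unit.UPLAND):
        umask = units.unit_mask(unit)
        n_pix = int(umask.sum())
        if n_pix == 0:
            out[unit] = FrequencySummary(
                unit, window,
                {k: float("nan") for k in stacks},
                {k: float("nan") for k in stacks},
                valid=False,
            )
            continue
        means, sems = {}, {}
        for key, stack in stacks.items():
            yearly = stack[:, umask].sum(axis=1) / n_pix
            means[key], sems[key] = _mean_sem(yearly)
        out[unit] = FrequencySummary(unit, window, means, sems)
    return out


def time_since_last_burnt(history: FireHistory, as_of_year: int) -> TSLBRaster:
    """Per-pixel whole years since the most recent burn at or before as_of_year."""
    idx = history.year_index(as_of_year)
    annual = history.annual_stack()[: idx + 1].astype(bool)
    n = annual.shape[0]
    # most recent burnt year index, or -1 if never burnt
    year_idx = np.arange(n)[:, None, None]
    last = np.where(annual, year_idx, -1).max(axis=0)
    censor_bound = n  # as_of_year - first_year + 1
    tslb = np.where(last >= 0, idx - last, censor_bound).astype(np.int64)
    return TSLBRaster(as_of_year, tslb, censored=(last < 0))


def long_unburnt_proportion(
    history: FireHistory,
    units: LandscapeUnits,
    as_of_year: int,
    min_years_list: tuple[int, ...] = (3, 5),
) -> dict[Unit, UnburntSummary]:
    """Proportion of unit pixels unburnt for >= 3 and >= 5 years as of a year.

    "Unburnt for >= N years at end of year Y" = no burn in Y-N+1 .. Y. The
    history must reach back at least max(min_years) years from as_of_year.
    """
    idx = history.year_index(as_of_year)
    need = max(min_years_list)
    if idx + 1 < need:
        raise ValueError(
            f"history depth {idx + 1} y ending {as_of_year} is insufficient: "
            f"need >= {need} years for the >= {need}-year lookback"
        )
    tslb = time_since_last_burnt(history, as_of_year)
    out: dict[Unit, UnburntSummary] = {}
    for unit in (Unit.LOWLAND, Unit.UPLAND):
        umask = units.unit_mask(unit)
        n_pix = int(umask.sum())
        if n_pix == 0:
            out[unit] = UnburntSummary(unit, as_of_year, float("nan"), float("nan"), valid=False)
            continue
        props = {}
        for m in min_years_list:
            props[m] = float((tslb.years[umask] >= m).sum() / n_pix)
        out[unit] = UnburntSummary(unit, as_of_year, props.get(3, 0.0), props.get(5, 0.0))
    return out
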