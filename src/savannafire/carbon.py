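"""Indicative carbon-credit accounting for savanna burning projects.

Three complementary (additive) accounting methods are modelled at the level
of the published arithmetic:

1. **GHG emissions abatement** — accountable emissions are seasonal burnt
   area times a per-hectare factor, with early-dry-season fire yielding ~50%
   of the late-dry-season factor; credits are the mean annual emissions of a
   pre-project baseline (nominally 10 years) minus the project's, floored at
   zero. One credit = 1 t CO2-e per year abated.
2. **Fine and coarse woody fuel (FCWF) sequestration** — an annualized
   per-hectare sequestration rate, or a stock change annualized over a
   horizon (default 25 years).
3. **Living-tree biomass sequestration** — same arithmetic as FCWF with its
   own rate.

The per-hectare factors of the accredited regulatory methods (fuel-type and
fuel-load detail) are deliberately collapsed into configuration: this module
claims arithmetic fidelity, not regulatory-method fidelity. ``f_lds``
defaults to 1.0 t CO2-e/ha so relative reductions work out of the box, with
a logged warning for absolute estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

logger = logging.getLogger("savannafire")

__all__ = [
    "EmissionParams",
    "SequestrationParams",
    "CreditEstimate",
    "seasonal_emissions",
    "abatement_credits",
    "scenario_abatement_credits",
    "sequestration_credits",
    "total_credits",
    "uncertainty_interval",
    "INDICATIVE_CREDIT_TABLE",
    "implied_sequestration_rates",
]

#: Published indicative per-site annual credits (thousands of t CO2-e/y) and
#: areas (ha) under enhanced fire management, used as worked-example inputs.
#: Components: (area_ha, abatement, fcwf, living_tree, printed_total).
#: The Kakadu lowland printed total (886) differs from its component sum
#: (890) — a rounding inconsistency in the source table, flagged here.
INDICATIVE_CREDIT_TABLE: dict[tuple[str, str], dict[str, float]] = {
    ("Kakadu", "LOWLAND"): dict(area_ha=1_506_144, abatement=78, fcwf=338, tree=474, total=886),
    ("Kakadu", "UPLAND"): dict(area_ha=98_538, abatement=3.3, fcwf=0, tree=30, total=33.3),
    ("Litchfield", "LOWLAND"): dict(area_ha=106_881, abatement=6.4, fcwf=29, tree=34, total=69.4),
    ("Litchfield", "UPLAND"): dict(area_ha=20_506, abatement=1.2, fcwf=1.3, tree=6.2, total=8.7),
    ("Nitmiluk", "LOWLAND"): dict(area_ha=246_231, abatement=15, fcwf=59, tree=77, total=151),
    ("Nitmiluk", "UPLAND"): dict(area_ha=23_856, abatement=1.4, fcwf=0.4, tree=7.2, total=9),
    ("WALFA", "LOWLAND"): dict(area_ha=2_055_131, abatement=121, fcwf=343, tree=603, total=1067),
    ("WALFA", "UPLAND"): dict(area_ha=392_650, abatement=19, fcwf=26, tree=115, total=160),
}

#: Rows whose printed total equals the sum of their printed components.
CONSISTENT_TABLE_ROWS: tuple[tuple[str, str], ...] = tuple(
    key
    for key, row in INDICATIVE_CREDIT_TABLE.items()
    if math.isclose(row["abatement"] + row["fcwf"] + row["tree"], row["total"], abs_tol=1e-9)
)

_DEFAULT_F_LDS = 1.0


@dataclass(frozen=True)
class EmissionParams:
    """Seasonal-factor emissions model parameters.

    f_lds
        Accountable emissions per hectare burnt late in the dry season
        (t CO2-e/ha). Default 1.0 is a placeholder unit factor: configure it
        for absolute estimates (relative reductions are factor-free).
    eds_ratio
        Early-season factor as a fraction of f_lds (default 0.5: EDS fires
        yield ~50% less accountable emissions).
    baseline_years
        Length of the pre-project baseline (default 10).
    cv
        Coefficient of variation for uncertainty reporting (default 0.16).
    """

    f_lds: float = _DEFAULT_F_LDS
    eds_ratio: float = 0.5
    baseline_years: int = 10
    cv: float = 0.16

    def __post_init__(self) -> None:
        if self.f_lds <= 0:
            raise ValueError("f_lds must be positive")
        if not 0 < self.eds_ratio <= 1:
            raise ValueError("eds_ratio must be in (0, 1]")
        if self.baseline_years < 1:
            raise ValueError("baseline_years must be >= 1")


@dataclass(frozen=True)
class SequestrationParams:
    """Sequestration method parameters: a rate, or a stock change + horizon.

    Exactly one of ``rate_per_ha`` (t CO2-e/ha/y) or ``stock_change_per_ha``
    (t CO2-e/ha, annualized over ``horizon_years``, default 25) must be set.
    """

    method: str = "FCWF"  # FCWF | LIVING_TREE
    rate_per_ha: float | None = None
    stock_change_per_ha: float | None = None
    horizon_years: float = 25.0

    def __post_init__(self) -> None:
        if (self.rate_per_ha is None) == (self.stock_change_per_ha is None):
            raise ValueError("set exactly one of rate_per_ha or stock_change_per_ha")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")

    @property
    def annual_rate_per_ha(self) -> float:
        if self.rate_per_ha is not None:
            return self.rate_per_ha
        return self.stock_change_per_ha / self.horizon_years


@dataclass(frozen=True)
class CreditEstimate:
    """Per-site/unit annual credits: one credit = 1 t CO2-e/y."""

    site: str
    unit: str
    area_ha: float
    abatement_credits: float
    fcwf_credits: float
    tree_credits: float
    interval: tuple[float, float] | None = None

    @property
    def total_credits(self) -> float:
        return self.abatement_credits + self.fcwf_credits + self.tree_credits


def seasonal_emissions(
    area_eds_ha: float, area_lds_ha: float, params: EmissionParams | None = None
) -> float:
    """Accountable annual emissions (t CO2-e) from seasonal burnt areas.

    E = f_lds * (eds_ratio * area_EDS + area_LDS).
    """
    params = params or EmissionParams()
    if area_eds_ha < 0 or area_lds_ha < 0:
        raise ValueError("burnt areas must be non-negative")
    return params.f_lds * (params.eds_ratio * area_eds_ha + area_lds_ha)


def _mean_emissions(
    yearly_areas: Sequence[tuple[float, float]], params: EmissionParams
) -> float:
    if not yearly_areas:
        raise ValueError("need at least one year of burnt areas")
    return sum(seasonal_emissions(e, l, params) for e, l in yearly_areas) / len(yearly_areas)


def abatement_credits(
    baseline: Sequence[tuple[float, float]],
    project: Sequence[tuple[float, float]],
    params: EmissionParams | None = None,
) -> float:
    """Annual abatement credits: baseline-mean minus project-mean emissions.

    ``baseline`` and ``project`` are per-year (EDS ha, LDS ha) burnt areas;
    the baseline is nominally the 10 pre-project years. Credits floor at 0
    (no debits).
    """
    params = params or EmissionParams()
    if params.f_lds == _DEFAULT_F_LDS:
        logger.warning(
            "abatement_credits: f_lds left at the placeholder 1.0 t CO2-e/ha; "
            "absolute credit numbers require a configured emission factor"
        )
    return max(0.0, _mean_emissions(baseline, params) - _mean_emissions(project, params))


def scenario_abatement_credits(
    baseline_emissions: float, reduction_fraction: float = 0.38
) -> float:
    """Scenario credits: a flat fractional reduction of baseline emissions.

    The default 0.38 is the realized relative emissions reduction of the
    WALFA project's first seven years, used as an achievable-management
    scenario for comparable sites.
    """
    if not 0.0 <= reduction_fraction <= 1.0:
        raise ValueError("reduction_fraction must be in [0, 1]")
    if baseline_emissions < 0:
        raise ValueError("baseline_emissions must be non-negative")
    return reduction_fraction * baseline_emissions


def sequestration_credits(area_ha: float, params: SequestrationParams) -> float:
    """Annual sequestration credits over an area: area × annualized rate."""
    if area_ha < 0:
        raise ValueError("area must be non-negative")
    return area_ha * params.annual_rate_per_ha


def total_credits(
    abatement: float,
    fcwf: float,
    tree: float,
    site: str = "site",
    unit: str = "LOWLAND",
    area_ha: float = float("nan"),
    cv: float | None = None,
) -> CreditEstimate:
    """Combine the three complementary methods additively into one estimate."""
    for name, v in (("abatement", abatement), ("fcwf", fcwf), ("tree", tree)):
        if v < 0:
            raise ValueError(f"{name} credits must be non-negative, got {v}")
    interval = None
    if cv is not None:
        interval = uncertainty_interval(abatement + fcwf + tree, cv)
    return CreditEstimate(site, unit, area_ha, abatement, fcwf, tree, interval)


def uncertainty_interval(
    estimate: float, cv: float, z: float = 1.96
) -> tuple[float, float]:
    """Normal-approximation interval (estimate × (1 ± z·cv)), floored at 0."""
    if estimate < 0 or cv < 0:
        raise ValueError("estimate and cv must be non-negative")
    half = z * cv * estimate
    return (max(0.0, estimate - half), estimate + half)


def implied_sequestration_rates() -> dict[tuple[str, str], dict[str, float]]:
    """Per-hectare rates implied by the published indicative credit table.

    These are credits ÷ area for each site/unit row (t CO2-e/ha/y), provided
    as documented example configuration — implied, not measured, rates.
    """
    out = {}
    for key, row in INDICATIVE_CREDIT_TABLE.items():
        out[key] = {
            "fcwf_rate_per_ha": row["fcwf"] * 1e3 / row["area_ha"],
            "tree_rate_per_ha": row["tree"] * 1e3 / row["area_ha"],
            "abatement_per_ha": row["abatement"] * 1e3 / row["area_ha"],
        }
    return out
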