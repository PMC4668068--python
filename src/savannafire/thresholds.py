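"""Ecological fire-regime thresholds and compliance scoring.

Each rule compares one computed metric (a point estimate) for one landscape
unit against a published guideline value; SEMs travel with the report for
context but do not enter the verdict. Rules are data, not code: the default
set can be replaced wholesale from YAML/JSON so amended guidance swaps in
without a code change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .grid import Unit

__all__ = ["ThresholdRule", "default_thresholds", "load_thresholds", "assess"]

_COMPARATORS = {"<=", "<", ">="}


@dataclass(frozen=True)
class ThresholdRule:
    """One guideline: metric, unit scope, comparator, threshold, context."""

    id: str
    metric: str  # annual_frequency | lds_frequency | prop_unburnt_ge3 | mean_patch_size
    unit_scope: str  # LOWLAND | UPLAND | BOTH
    comparator: str  # <= | < | >=
    threshold: float
    context: str = ""

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"rule {self.id}: bad comparator {self.comparator!r}")
        if self.threshold <= 0:
            raise ValueError(f"rule {self.id}: threshold must be positive")

    def applies_to(self, unit: Unit) -> bool:
        return self.unit_scope == "BOTH" or self.unit_scope == Unit(unit).value

    def holds(self, observed: float) -> bool:
        if self.comparator == "<=":
            return observed <= self.threshold
        if self.comparator == "<":
            return observed < self.threshold
        return observed >= self.threshold

    def margin(self, observed: float) -> float:
        """Signed observed - threshold: negative = compliant for <= / < rules."""
        return observed - self.threshold


def default_thresholds() -> list[ThresholdRule]:
    """The recommended threshold conditions for north-Australian mesic savanna.

    Frequencies are fires per year over an assessment window; unburnt
    proportions are of unit area; patch sizes are mean CBA sizes in km2.
    """
    return [
        ThresholdRule(
            "fauna_frequency", "annual_frequency", "BOTH", "<=", 0.3,
            "small-mammals and many bird taxa: frequency not to exceed 0.3 fires/y",
        ),
        ThresholdRule(
            "obligate_seeder_frequency", "annual_frequency", "UPLAND", "<", 0.2,
            "persistence of upland obligate-seeder shrubs: <0.2 fires/y",
        ),
        ThresholdRule(
            "callitris_lds_frequency", "lds_frequency", "BOTH", "<", 0.2,
            "Callitris intratropica: severe/LDS fire frequency <0.2 fires/y "
            "(any LDS fire is severe with probability 0.81; raw LDS frequency used)",
        ),
        ThresholdRule(
            "lowland_unburnt_ge3", "prop_unburnt_ge3", "LOWLAND", ">=", 0.25,
            "small-mammals and birds: 25% of lowland savanna unburnt >=3 years",
        ),
        ThresholdRule(
            "upland_unburnt_ge3", "prop_unburnt_ge3", "UPLAND", ">=", 0.40,
            "small-mammals and birds: 40% of upland savanna unburnt >=3 years",
        ),
        ThresholdRule(
            "mean_patch_size", "mean_patch_size", "BOTH", "<", 1.0,
            "poorly dispersed obligate seeders, invertebrates, small vertebrates: "
            "average patch sizes <1 km2, preferably less",
        ),
        ThresholdRule(
            "small_mammal_patch_guideline", "mean_patch_size", "BOTH", "<", 10.0,
            "small-mammal populations: fire size <<10 km2 (strict: bound is a "
            "guideline ceiling, tighten for conservative use)",
        ),
    ]


def load_thresholds(path: str | Path) -> list[ThresholdRule]:
    """Load rules from a YAML or JSON list of rule mappings."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a list of rules")
    return [ThresholdRule(**item) for item in data]


def assess(
    metrics: Mapping[Unit, Mapping[str, float]],
    rules: Sequence[ThresholdRule] | None = None,
    site: str = "site",
    window: str = "",
) -> pd.DataFrame:
    """Score per-unit metrics against threshold rules.

    ``metrics`` maps each unit to its observed point estimates keyed by
    metric name. Returns one row per (unit, applicable rule) with observed,
    threshold, pass/fail and signed margin; a missing metric yields status
    NOT-ASSESSABLE instead of an error.
    """
    rules = list(rules) if rules is not None else default_thresholds()
    rows = []
    for unit, observed_map in metrics.items():
        unit = Unit(unit)
        for rule in rules:
            if not rule.applies_to(unit):
                continue
            observed = observed_map.get(rule.metric)
            if observed is None or (isinstance(observed, float) and observed != observed):
                rows.append(
                    {
                        "site": site, "unit": unit.value, "window": window,
                        "rule": rule.id, "metric": rule.metric,
                        "comparator": rule.comparator, "threshold": rule.threshold,
                        "observed": float("nan"), "margin": float("nan"),
                        "status": "NOT-ASSESSABLE", "context": rule.context,
                    }
                )
                continue
            ok = rule.holds(float(observed))
            rows.append(
                {
                    "site": site, "unit": unit.value, "window": window,
                    "rule": rule.id, "metric": rule.metric,
                    "comparator": rule.comparator, "threshold": rule.threshold,
                    "observed": float(observed), "margin": rule.margin(float(observed)),
                    "status": "PASS" if ok else "FAIL", "context": rule.context,
                }
            )
    return pd.DataFrame(rows)
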