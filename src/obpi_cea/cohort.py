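"""Cohort projection of expected permanent OBPIs per model year.

Two scenarios are compared over the horizon:

* ``CURRENT`` — only the existing covered cohorts train; all other
  births stay at the baseline injury probability for every model year.
* ``NATIONWIDE`` — every previously uncovered birth enrols as a new
  cohort at model year 1 and advances through the decline schedule.

A cohort listed with *k* established years experiences the "*k* years
after training" probability in model year 1 and moves one schedule index
per model year.  The training-cost variant (full programme vs the
shoulder-dystocia component alone) has no epidemiological effect, so
both variants share identical traces.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .params import (
    ConfigError,
    CoverageCohort,
    CoverageTable,
    ModelConfig,
    ProbabilitySchedule,
    validate_inputs,
)

__all__ = [
    "Scenario",
    "TrainingVariant",
    "ScenarioSpec",
    "OBPITrace",
    "cohort_probability",
    "yearly_obpi_counts",
    "obpis_averted",
]

UNCOVERED_ID = "uncovered"


class Scenario(str, Enum):
    NATIONWIDE = "nationwide"
    CURRENT = "current"


class TrainingVariant(str, Enum):
    PROMPT = "prompt"
    SD_ONLY = "sd"


@dataclass(frozen=True)
class ScenarioSpec:
    scenario: Scenario
    variant: TrainingVariant = TrainingVariant.PROMPT


@dataclass(frozen=True)
class OBPITrace:
    """Expected permanent OBPIs per model year, with the per-cohort
    breakdown kept for audit/export."""

    scenario: Scenario
    variant: TrainingVariant
    #: tidy per-cohort frame: model_year, cohort_id, births, probability,
    #: expected_obpis
    by_cohort: pd.DataFrame
    #: expected OBPIs per model year, index 0 == model year 1
    yearly: np.ndarray

    @property
    def horizon(self) -> int:
        return len(self.yearly)

    @property
    def cumulative_total(self) -> float:
        return float(self.yearly.sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.by_cohort.copy()
        out.insert(0, "variant", self.variant.value)
        out.insert(0, "scenario", self.scenario.value)
        return out


def cohort_probability(
    years_established_at_start: int,
    model_year: int,
    schedule: ProbabilitySchedule,
) -> float:
    """Injury probability a cohort experiences in a given model year.

    A cohort with *k* established years sees schedule index
    ``k + model_year - 1`` (zero once past the end of the schedule).
    """
    if model_year < 1:
        raise ConfigError("model_year: must be >= 1")
    if years_established_at_start < 0:
        raise ConfigError("years_established_at_start: must be >= 0")
    return schedule.at(years_established_at_start + model_year - 1)


def yearly_obpi_counts(
    spec: ScenarioSpec,
    config: ModelConfig,
    coverage: CoverageTable,
) -> OBPITrace:
    """Deterministic expected-value projection of permanent OBPIs.

    Expected counts are carried at full precision (fractional injuries
    are expectations, not individuals); rounding is a reporting concern.
    """
    validate_inputs(config, coverage)
    schedule = config.schedule()
    uncovered = config.annual_births - coverage.total_births

    cohorts: list[tuple[str, float, int | None]] = [
        (f"established_{c.years_established_at_start}y", c.births_per_year,
         c.years_established_at_start)
        for c in coverage
    ]
    if spec.scenario is Scenario.NATIONWIDE:
        # previously uncovered births enrol with 0 established years
        cohorts.append(("new_rollout", uncovered, 0))
    else:
        cohorts.append((UNCOVERED_ID, uncovered, None))  # untrained

    rows = []
    horizon = config.horizon_years
    yearly = np.zeros(horizon)
    for t in range(1, horizon + 1):
        for cohort_id, births, k in cohorts:
            if k is None:
                p = config.baseline_obpi_prob
            else:
                p = cohort_probability(k, t, schedule)
            expected = births * p
            yearly[t - 1] += expected
            rows.append((t, cohort_id, births, p, expected))

    by_cohort = pd.DataFrame(
        rows,
        columns=["model_year", "cohort_id", "births", "probability", "expected_obpis"],
    )
    return OBPITrace(spec.scenario, spec.variant, by_cohort, yearly)


def obpis_averted(trace_a: OBPITrace, trace_b: OBPITrace) -> float:
    """Cumulative OBPIs in *b* minus cumulative in *a* (positive when
    *a* is the safer scenario)."""
    if trace_a.horizon != trace_b.horizon:
        raise ConfigError("horizon: traces must share the same horizon")
    return trace_b.cumulative_total - trace_a.cumulative_total
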