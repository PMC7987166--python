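"""Cost accounting: per-birth training costs and litigation-based
injury costs, with claims inflation and discounting.

Injury costs use the mean settled-claim value as a proxy for the
lifetime cost of a permanent OBPI, charged in the year of birth.
Damages inflate at the claims-inflation rate from model year 1; the
standard annual discount is applied on top, so injury costs grow at a
net ~6.3%/yr under the base case (10% inflation vs 3.5% discount).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OBPITrace, Scenario, ScenarioSpec, TrainingVariant
from .params import ConfigError, CoverageTable, ModelConfig, validate_inputs

__all__ = [
    "CostTrace",
    "discount_factor",
    "training_cost_per_year",
    "injury_cost_per_year",
    "total_cost",
]


@dataclass(frozen=True)
class CostTrace:
    scenario: Scenario
    variant: TrainingVariant
    #: undiscounted training spend per model year
    training_cost: np.ndarray
    #: undiscounted, claims-inflated injury cost per model year
    injury_cost: np.ndarray
    #: present-value factor per model year (year 1 == 1.0)
    discount_factors: np.ndarray

    @property
    def discounted_yearly(self) -> np.ndarray:
        return (self.training_cost + self.injury_cost) * self.discount_factors

    @property
    def total_training_discounted(self) -> float:
        return float((self.training_cost * self.discount_factors).sum())

    @property
    def total_injury_discounted(self) -> float:
        return float((self.injury_cost * self.discount_factors).sum())

    @property
    def total_discounted(self) -> float:
        return float(self.discounted_yearly.sum())

    def to_frame(self) -> pd.DataFrame:
        years = np.arange(1, len(self.training_cost) + 1)
        return pd.DataFrame(
            {
                "scenario": self.scenario.value,
                "variant": self.variant.value,
                "model_year": years,
                "training_cost": self.training_cost,
                "injury_cost": self.injury_cost,
                "discount_factor": self.discount_factors,
                "discounted_total": self.discounted_yearly,
            }
        )


def discount_factor(model_year: int, rate: float) -> float:
    """Present-value factor ``(1 + rate)^-(t - 1)``; the first model
    year is undiscounted."""
    if model_year < 1:
        raise ConfigError("model_year: must be >= 1")
    if rate < 0:
        raise ConfigError("rate: must be >= 0")
    return float((1.0 + rate) ** -(model_year - 1))


def _rates(variant: TrainingVariant, config: ModelConfig) -> tuple[float, float]:
    if variant is TrainingVariant.SD_ONLY:
        return config.cost_sd_first, config.cost_sd_subsequent
    return config.cost_prompt_first, config.cost_prompt_subsequent


def training_cost_per_year(
    spec: ScenarioSpec,
    config: ModelConfig,
    coverage: CoverageTable,
    model_year: int,
) -> float:
    """Undiscounted training spend in one model year.

    All pre-existing cohorts are past their first year and pay the
    subsequent-year per-birth rate.  Under nationwide rollout the newly
    enrolled births pay the first-year rate in model year 1 only.
    Uncovered births under current practice cost nothing.
    """
    if model_year < 1:
        raise ConfigError("model_year: must be >= 1")
    validate_inputs(config, coverage)
    first, subsequent = _rates(spec.variant, config)
    cost = coverage.total_births * subsequent
    if spec.scenario is Scenario.NATIONWIDE:
        uncovered = config.annual_births - coverage.total_births
        cost += uncovered * (first if model_year == 1 else subsequent)
    return float(cost)


def injury_cost_per_year(
    expected_obpis: float, model_year: int, config: ModelConfig
) -> float:
    """Claims-inflated (undiscounted) injury cost for one model year."""
    if expected_obpis < 0:
        raise ConfigError("expected_obpis: must be >= 0")
    if model_year < 1:
        raise ConfigError("model_year: must be >= 1")
    return float(
        expected_obpis
        * config.mean_litigation_cost
        * (1.0 + config.claims_inflation) ** (model_year - 1)
    )


def total_cost(
    spec: ScenarioSpec,
    config: ModelConfig,
    coverage: CoverageTable,
    trace: OBPITrace,
) -> CostTrace:
    """Full per-year cost breakdown for one scenario/variant."""
    if trace.horizon != config.horizon_years:
        raise ConfigError("trace: horizon does not match config.horizon_years")
    years = np.arange(1, config.horizon_years + 1)
    training = np.array(
        [training_cost_per_year(spec, config, coverage, int(t)) for t in years]
    )
    injury = np.array(
        [
            injury_cost_per_year(float(o), int(t), config)
            for o, t in zip(trace.yearly, years)
        ]
    )
    factors = np.array([discount_factor(int(t), config.discount_rate) for t in years])
    return CostTrace(spec.scenario, spec.variant, training, injury, factors)
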