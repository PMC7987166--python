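"""Synthetic but structurally valid model inputs, plus a stochastic
micro-simulation oracle.

The generator emulates the structure of the real input table: a
handful of coverage cohorts whose births sum to at most the annual
total, a non-increasing piecewise-linear decline schedule reaching
zero, and cost/utility scalars inside their validity domains.  It
exists so every pipeline stage can be property-tested without external
data.

The Bernoulli oracle treats each birth as an independent trial at its
cohort-year probability, giving an unbiased stochastic check on the
deterministic expected-value engine.  Oracle runs scale the birth rate
down (default /100) to keep simulation cheap; the deterministic engine
is exactly linear in the birth rate, so the comparison is unaffected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Scenario, ScenarioSpec, cohort_probability
from .params import (
    ConfigError,
    CoverageCohort,
    CoverageTable,
    ModelConfig,
    validate_inputs,
)

__all__ = ["GeneratorSpec", "generate_config", "bernoulli_oracle"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Ranges for random model inputs; defaults bracket the real study
    conditions while staying desk-scale for simulation."""

    annual_births: tuple[float, float] = (2_000.0, 10_000.0)
    horizon_years: tuple[int, int] = (10, 40)
    discount_rate: tuple[float, float] = (0.0, 0.06)
    claims_inflation: tuple[float, float] = (0.0, 0.15)
    baseline_obpi_prob: tuple[float, float] = (0.0001, 0.01)
    training_cost: tuple[float, float] = (1.0, 25.0)
    litigation_cost: tuple[float, float] = (50_000.0, 500_000.0)
    utility_low: tuple[float, float] = (0.3, 0.7)
    n_cohorts: tuple[int, int] = (1, 9)
    coverage_fraction: tuple[float, float] = (0.1, 0.9)
    full_effect_year: tuple[int, int] = (6, 15)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name}: range lower bound exceeds upper bound")


def _uniform(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    return float(rng.uniform(*rng_pair))


def generate_config(
    spec: GeneratorSpec = GeneratorSpec(), seed: int | np.random.Generator = 0
) -> tuple[ModelConfig, CoverageTable]:
    """Draw a random valid (config, coverage) pair.

    Deterministic in the seed; every output passes the same validation
    as a loaded configuration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # integer births so the Bernoulli oracle needs no rounding
    births = float(round(_uniform(rng, spec.annual_births)))
    p0 = _uniform(rng, spec.baseline_obpi_prob)
    full_effect = int(rng.integers(spec.full_effect_year[0], spec.full_effect_year[1] + 1))
    # one interior anchor keeps the schedule piecewise (like the real
    # two-segment decline) while staying non-increasing
    mid_year = int(rng.integers(1, full_effect))
    mid_prob = p0 * float(rng.uniform(0.2, 1.0)) * (full_effect - mid_year) / full_effect
    u_pop = _uniform(rng, (0.7, 1.0))
    first = _uniform(rng, spec.training_cost)
    sd_first = first * float(rng.uniform(0.05, 0.5))
    config = ModelConfig(
        annual_births=births,
        horizon_years=int(rng.integers(spec.horizon_years[0], spec.horizon_years[1] + 1)),
        discount_rate=_uniform(rng, spec.discount_rate),
        claims_inflation=_uniform(rng, spec.claims_inflation),
        baseline_obpi_prob=p0,
        cost_prompt_first=first,
        cost_prompt_subsequent=first * float(rng.uniform(0.5, 1.0)),
        cost_sd_first=sd_first,
        cost_sd_subsequent=sd_first * float(rng.uniform(0.5, 1.0)),
        mean_litigation_cost=_uniform(rng, spec.litigation_cost),
        utility_affected_adult=_uniform(rng, spec.utility_low),
        utility_parent_affected=_uniform(rng, (spec.utility_low[0], u_pop)),
        utility_population=u_pop,
        adult_age=int(rng.integers(14, 22)),
        effect_anchor_years=(0, mid_year, full_effect),
        effect_anchor_probs=(p0, mid_prob, 0.0),
        schedule_round_decimals=None,
    )
    n = int(rng.integers(spec.n_cohorts[0], spec.n_cohorts[1] + 1))
    fraction = _uniform(rng, spec.coverage_fraction)
    total_covered = int(round(births * fraction))
    weights = rng.dirichlet(np.ones(n))
    # integer cohort sizes summing exactly to the drawn coverage total
    cuts = np.round(np.cumsum(weights) * total_covered).astype(int)
    sizes = np.diff(np.concatenate(([0], cuts)))
    years = rng.choice(np.arange(1, 16), size=n, replace=False)
    cohorts = tuple(
        CoverageCohort(births_per_year=float(s), years_established_at_start=int(y))
        for s, y in zip(sizes, years)
    )
    coverage = CoverageTable(cohorts)
    validate_inputs(config, coverage)
    return config, coverage


def bernoulli_oracle(
    config: ModelConfig,
    coverage: CoverageTable,
    spec: ScenarioSpec,
    n_reps: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic yearly OBPI counts: every birth an independent
    Bernoulli trial at its cohort-year probability.

    Returns (mean per model year, standard error per model year) over
    ``n_reps`` replicates.  Birth counts are rounded to integers for
    the trials, so pass desk-scale inputs (the deterministic engine's
    linearity in births justifies scaled-down comparisons).
    """
    if n_reps < 1:
        raise ConfigError("n_reps: must be >= 1")
    validate_inputs(config, coverage)
    rng = np.random.default_rng(seed)
    schedule = config.schedule()
    horizon = config.horizon_years
    uncovered = int(round(config.annual_births - coverage.total_births))

    # (cohort births, years established) incl. the uncovered block
    groups: list[tuple[int, int | None]] = [
        (int(round(c.births_per_year)), c.years_established_at_start) for c in coverage
    ]
    if spec.scenario is Scenario.NATIONWIDE:
        groups.append((uncovered, 0))
    else:
        groups.append((uncovered, None))

    counts = np.zeros((n_reps, horizon))
    for births, k in groups:
        if births <= 0:
            continue
        probs = np.array(
            [
                config.baseline_obpi_prob
                if k is None
                else cohort_probability(k, t, schedule)
                for t in range(1, horizon + 1)
            ]
        )
        counts += rng.binomial(births, probs, size=(n_reps, horizon))
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.full(horizon, np.nan)
    return mean, se
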