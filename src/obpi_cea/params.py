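"""Model inputs: configuration, training-coverage cohorts, and the
permanent-OBPI probability-decline schedule.

The base case describes annual simulation training for obstetric
emergencies in English maternity units.  Births covered by established
training carry a probability of permanent obstetric brachial plexus
injury (OBPI) that declines piecewise-linearly with the number of years
the training has been running, reaching zero after 12 years; uncovered
births stay at the baseline probability (0.192 per 1,000 births).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "ModelConfig",
    "CoverageCohort",
    "CoverageTable",
    "ProbabilitySchedule",
    "build_probability_schedule",
    "load_config",
    "save_config",
    "default_config",
    "validate_inputs",
]

#: Schedule index at and beyond which the injury probability is zero in
#: the base case (training fully effective after 12 established years).
FULL_EFFECT_YEARS = 12


class ConfigError(ValueError):
    """Raised when a configuration value violates a model invariant."""


def _check(cond: bool, field_name: str, constraint: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {constraint}")


@dataclass(frozen=True)
class ModelConfig:
    """All scalar model inputs, defaulting to the published base case.

    Currency fields are 2017 GBP.  ``effect_anchor_years`` /
    ``effect_anchor_probs`` define the piecewise-linear decline of the
    permanent-OBPI probability with years of established training.
    """

    annual_births: float = 648_107
    horizon_years: int = 30
    discount_rate: float = 0.035
    claims_inflation: float = 0.10
    baseline_obpi_prob: float = 0.000192
    cost_prompt_first: float = 16.91
    cost_prompt_subsequent: float = 15.56
    cost_sd_first: float = 1.79
    cost_sd_subsequent: float = 1.43
    mean_litigation_cost: float = 338_879.0
    utility_affected_adult: float = 0.56
    utility_parent_affected: float = 0.80
    utility_population: float = 0.86
    adult_age: int = 18
    effect_anchor_years: tuple[int, ...] = (0, 4, FULL_EFFECT_YEARS)
    effect_anchor_probs: tuple[float, ...] = (0.000192, 0.000150, 0.0)
    #: Discount QALYs at ``discount_rate`` (NICE reference case).  An
    #: undiscounted mode is kept first-class because the published QALY
    #: table is consistent with mixed conventions.
    qaly_discounting: bool = True
    #: Decimal places for the tabulated schedule; ``None`` disables
    #: rounding (sensitivity work).  6 reproduces the printed table.
    schedule_round_decimals: int | None = 6

    def __post_init__(self) -> None:
        _check(self.annual_births >= 0, "annual_births", "must be >= 0")
        _check(self.horizon_years >= 1, "horizon_years", "must be >= 1")
        _check(0 <= self.discount_rate, "discount_rate", "must be >= 0")
        _check(0 <= self.claims_inflation, "claims_inflation", "must be >= 0")
        _check(
            0 <= self.baseline_obpi_prob <= 1,
            "baseline_obpi_prob",
            "must be a probability in [0, 1]",
        )
        for name in (
            "cost_prompt_first",
            "cost_prompt_subsequent",
            "cost_sd_first",
            "cost_sd_subsequent",
            "mean_litigation_cost",
        ):
            _check(getattr(self, name) >= 0, name, "cost must be >= 0")
        for name in (
            "utility_affected_adult",
            "utility_parent_affected",
            "utility_population",
        ):
            _check(0 <= getattr(self, name) <= 1, name, "utility must be in [0, 1]")
        _check(self.adult_age >= 0, "adult_age", "must be >= 0")
        _check(
            len(self.effect_anchor_years) == len(self.effect_anchor_probs),
            "effect_anchor_years",
            "must match effect_anchor_probs in length",
        )
        years = self.effect_anchor_years
        probs = self.effect_anchor_probs
        _check(len(years) >= 2, "effect_anchor_years", "need at least two anchors")
        _check(years[0] == 0, "effect_anchor_years", "first anchor must be year 0")
        _check(
            all(a < b for a, b in zip(years, years[1:])),
            "effect_anchor_years",
            "anchor years must be strictly increasing",
        )
        _check(
            all(a >= b for a, b in zip(probs, probs[1:])),
            "effect_anchor_probs",
            "anchor probabilities must be non-increasing",
        )
        _check(probs[-1] == 0, "effect_anchor_probs", "final anchor probability must be 0")
        _check(
            all(0 <= p <= 1 for p in probs),
            "effect_anchor_probs",
            "anchor probabilities must be in [0, 1]",
        )
        _check(
            abs(probs[0] - self.baseline_obpi_prob) < 1e-15,
            "effect_anchor_probs",
            "anchor at year 0 must equal baseline_obpi_prob",
        )

    def replace(self, **changes) -> "ModelConfig":
        return dataclasses.replace(self, **changes)

    def schedule(self) -> "ProbabilitySchedule":
        """The probability-decline schedule implied by the anchors."""
        return build_probability_schedule(
            list(zip(self.effect_anchor_years, self.effect_anchor_probs)),
            round_decimals=self.schedule_round_decimals,
        )


@dataclass(frozen=True)
class CoverageCohort:
    """Births per year in units whose training started a given number of
    whole years before model year 1."""

    births_per_year: float
    years_established_at_start: int

    def __post_init__(self) -> None:
        _check(self.births_per_year >= 0, "births_per_year", "must be >= 0")
        _check(
            self.years_established_at_start >= 0,
            "years_established_at_start",
            "must be >= 0",
        )


@dataclass(frozen=True)
class CoverageTable:
    cohorts: tuple[CoverageCohort, ...]

    def __post_init__(self) -> None:
        years = [c.years_established_at_start for c in self.cohorts]
        _check(
            len(set(years)) == len(years),
            "cohorts",
            "years_established_at_start values must be distinct",
        )

    @property
    def total_births(self) -> float:
        return float(sum(c.births_per_year for c in self.cohorts))

    def __iter__(self):
        return iter(self.cohorts)

    def __len__(self) -> int:
        return len(self.cohorts)

    def scaled(self, factor: float) -> "CoverageTable":
        """Coverage with every cohort's births multiplied by ``factor``
        (used by the PSA to hold coverage at base-case proportions of a
        sampled birth rate)."""
        _check(factor >= 0, "factor", "must be >= 0")
        return CoverageTable(
            tuple(
                CoverageCohort(c.births_per_year * factor, c.years_established_at_start)
                for c in self.cohorts
            )
        )


def validate_inputs(config: ModelConfig, coverage: CoverageTable) -> None:
    """Cross-validate a config/coverage pair."""
    if coverage.total_births > config.annual_births * (1 + 1e-12):
        raise ConfigError(
            "coverage: total covered births "
            f"({coverage.total_births:.0f}) exceed annual_births "
            f"({config.annual_births:.0f})"
        )


@dataclass(frozen=True)
class ProbabilitySchedule:
    """Permanent-OBPI probability indexed by completed years since the
    start of training; index 0 is the untrained baseline.  Values beyond
    the stored range are zero."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        _check(
            all(a >= b for a, b in zip(self.probs, self.probs[1:])),
            "probs",
            "schedule must be non-increasing",
        )
        _check(all(0 <= p <= 1 for p in self.probs), "probs", "must be in [0, 1]")
        _check(self.probs[-1] == 0, "probs", "schedule must end at 0")

    def at(self, years_after: int) -> float:
        if years_after < 0:
            raise ConfigError("years_after: must be >= 0")
        if years_after >= len(self.probs):
            return 0.0
        return self.probs[years_after]

    def __len__(self) -> int:
        return len(self.probs)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    @property
    def baseline(self) -> float:
        return self.probs[0]

    def rescaled(self, new_baseline: float) -> "ProbabilitySchedule":
        """Proportionally rescale the whole schedule to a new baseline
        probability (PSA convention: sampled baselines keep the linear
        decline shape)."""
        if self.baseline == 0:
            raise ConfigError("baseline: cannot rescale a schedule with baseline 0")
        factor = new_baseline / self.baseline
        return ProbabilitySchedule(tuple(p * factor for p in self.probs))


def _round_half_up(value: float, decimals: int) -> float:
    # Pre-round to 12 dp so binary noise (e.g. 3.7499999999999995e-05
    # for the exact 0.0000375) does not flip the half-up result.
    q = Decimal(str(round(value, 12))).quantize(
        Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP
    )
    return float(q)


def build_probability_schedule(
    anchors: Sequence[tuple[float, float]],
    round_decimals: int | None = 6,
) -> ProbabilitySchedule:
    """Piecewise-linear interpolation of (years, probability) anchors at
    integer years, optionally rounded half-up.

    The first anchor must sit at year 0 and the last anchor probability
    must be 0; beyond the last anchor the schedule is identically 0.
    With the base-case anchors (0 y, 0.192per-mille; 4 y, 0.15per-mille; 12 y, 0) and
    ``round_decimals=6`` this reproduces the published 13-value table.
    """
    if len(anchors) < 2:
        raise ConfigError("anchors: need at least two (years, prob) pairs")
    years = [a[0] for a in anchors]
    probs = [a[1] for a in anchors]
    if years[0] != 0:
        raise ConfigError("anchors: first anchor must be at year 0")
    if any(a >= b for a, b in zip(years, years[1:])):
        raise ConfigError("anchors: years must be strictly increasing")
    if any(a < b for a, b in zip(probs, probs[1:])):
        raise ConfigError("anchors: probabilities must be non-increasing")
    if probs[-1] != 0:
        raise ConfigError("anchors: final anchor probability must be 0")
    xs = np.arange(0, int(years[-1]) + 1)
    ys = np.interp(xs, years, probs)
    vals = [float(v) for v in ys]
    if round_decimals is not None:
        vals = [_round_half_up(v, round_decimals) for v in vals]
    return ProbabilitySchedule(tuple(vals))


# ---------------------------------------------------------------------------
# Serialisation

_MODEL_FIELDS = {f.name for f in dataclasses.fields(ModelConfig)}


def _config_from_mapping(model: dict) -> ModelConfig:
    unknown = set(model) - _MODEL_FIELDS
    if unknown:
        raise ConfigError(f"unknown model key(s): {sorted(unknown)}")
    if "effect_anchor_years" in model:
        model["effect_anchor_years"] = tuple(model["effect_anchor_years"])
    if "effect_anchor_probs" in model:
        model["effect_anchor_probs"] = tuple(model["effect_anchor_probs"])
    return ModelConfig(**model)


def load_config(path: str | Path) -> tuple[ModelConfig, CoverageTable]:
    """Load and validate a YAML model configuration.

    Schema::

        model:                   # any ModelConfig field; missing keys
          annual_births: 648107  # take base-case defaults
          ...
        coverage:
          - {years_established: 1, births: 38077}
          - ...

    Raises :class:`ConfigError` naming the offending key on any
    malformed or invariant-violating input.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    model = dict(raw.get("model") or {})
    config = _config_from_mapping(model)
    rows = raw.get("coverage") or []
    cohorts = []
    for i, row in enumerate(rows):
        if not isinstance(row, dict) or {"years_established", "births"} - set(row):
            raise ConfigError(
                f"coverage[{i}]: each row needs 'years_established' and 'births'"
            )
        cohorts.append(
            CoverageCohort(
                births_per_year=float(row["births"]),
                years_established_at_start=int(row["years_established"]),
            )
        )
    coverage = CoverageTable(tuple(cohorts))
    validate_inputs(config, coverage)
    return config, coverage


def save_config(
    config: ModelConfig, coverage: CoverageTable, path: str | Path
) -> None:
    """Write a config/coverage pair back to the YAML schema read by
    :func:`load_config` (round-trip safe)."""
    model = dataclasses.asdict(config)
    model["effect_anchor_years"] = list(config.effect_anchor_years)
    model["effect_anchor_probs"] = list(config.effect_anchor_probs)
    doc = {
        "model": model,
        "coverage": [
            {
                "years_established": c.years_established_at_start,
                "births": c.births_per_year,
            }
            for c in coverage
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_config() -> tuple[ModelConfig, CoverageTable]:
    """The packaged base case: national birth rate, the nine published
    coverage cohorts, and all base-case scalars."""
    ref = resources.files("obpi_cea").joinpath("data/base_case.yaml")
    with resources.as_file(ref) as p:
        return load_config(p)
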