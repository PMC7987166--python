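"""QALY accrual for affected adults, their parents, and the dyad.

Each model year's birth cohort is followed to the end of the horizon.
Individuals injured at birth accrue adult life-years at the
affected-adult utility once they turn 18 (within the horizon);
their parents accrue the parent-of-affected utility over the child
years.  Everyone else accrues the population-norm utility, so scenario
totals are population-scale and incremental QALYs depend only on the
utility differences.  The dyadic QALY is the equal-weight sum of the
adult and parental components.

When ``config.qaly_discounting`` is on, each life-year is weighted by
the discount factor of the calendar year in which it is lived.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cohort import OBPITrace
from .economics import discount_factor
from .params import ConfigError, ModelConfig

__all__ = [
    "QALYTrace",
    "QALYGains",
    "child_years",
    "adult_years",
    "qaly_totals",
    "incremental_qalys",
]


class QALYGains(NamedTuple):
    adult: float
    parental: float
    dyadic: float


@dataclass(frozen=True)
class QALYTrace:
    #: per birth-year frame: birth_year, affected, unaffected,
    #: child_years, adult_years, adult_qalys, parental_qalys, dyadic_qalys
    by_birth_year: pd.DataFrame

    @property
    def adult_qalys(self) -> float:
        return float(self.by_birth_year["adult_qalys"].sum())

    @property
    def parental_qalys(self) -> float:
        return float(self.by_birth_year["parental_qalys"].sum())

    @property
    def dyadic_qalys(self) -> float:
        # defined as the exact sum of the two components
        return self.adult_qalys + self.parental_qalys

    def to_frame(self) -> pd.DataFrame:
        return self.by_birth_year.copy()


def child_years(birth_year: int, horizon: int, adult_age: int) -> int:
    """Years lived as a child (age < ``adult_age``) within the horizon
    by someone born in ``birth_year``."""
    if not 1 <= birth_year <= horizon:
        raise ConfigError("birth_year: must be within 1..horizon")
    return min(adult_age, horizon - birth_year + 1)


def adult_years(birth_year: int, horizon: int, adult_age: int) -> int:
    """Years lived as an adult within the horizon."""
    if not 1 <= birth_year <= horizon:
        raise ConfigError("birth_year: must be within 1..horizon")
    return max(0, horizon - birth_year + 1 - adult_age)


def _life_year_weight(
    birth_year: int, first_age: int, n_years: int, config: ModelConfig
) -> float:
    """Sum of per-life-year weights for ages ``first_age ..
    first_age+n_years-1``, discounted by the calendar year lived."""
    if n_years <= 0:
        return 0.0
    if not config.qaly_discounting:
        return float(n_years)
    calendar = birth_year + first_age + np.arange(n_years)
    return float(
        sum(discount_factor(int(y), config.discount_rate) for y in calendar)
    )


def qaly_totals(trace: OBPITrace, config: ModelConfig) -> QALYTrace:
    """Adult, parental and dyadic QALY totals for one scenario."""
    for name in (
        "utility_affected_adult",
        "utility_parent_affected",
        "utility_population",
    ):
        u = getattr(config, name)
        if not 0 <= u <= 1:
            raise ConfigError(f"{name}: utility must be in [0, 1]")
    horizon = config.horizon_years
    rows = []
    for t in range(1, horizon + 1):
        affected = float(trace.yearly[t - 1])
        unaffected = config.annual_births - affected
        cy = child_years(t, horizon, config.adult_age)
        ay = adult_years(t, horizon, config.adult_age)
        w_child = _life_year_weight(t, 0, cy, config)
        w_adult = _life_year_weight(t, config.adult_age, ay, config)
        adult_q = (
            affected * config.utility_affected_adult
            + unaffected * config.utility_population
        ) * w_adult
        parent_q = (
            affected * config.utility_parent_affected
            + unaffected * config.utility_population
        ) * w_child
        rows.append(
            (t, affected, unaffected, cy, ay, adult_q, parent_q, adult_q + parent_q)
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "birth_year",
            "affected",
            "unaffected",
            "child_years",
            "adult_years",
            "adult_qalys",
            "parental_qalys",
            "dyadic_qalys",
        ],
    )
    return QALYTrace(frame)


def incremental_qalys(a: QALYTrace, b: QALYTrace) -> QALYGains:
    """Componentwise QALY gain of *a* over *b*; the dyadic gain is the
    exact sum of the adult and parental gains."""
    if len(a.by_birth_year) != len(b.by_birth_year):
        raise ConfigError("horizon: QALY traces must share the same horizon")
    adult = a.adult_qalys - b.adult_qalys
    parental = a.parental_qalys - b.parental_qalys
    return QALYGains(adult, parental, adult + parental)
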