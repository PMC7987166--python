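"""Incremental cost-effectiveness analysis of nationwide rollout
against current practice: cost and QALY deltas, ICERs, and dominance
classification on the cost-effectiveness plane."""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .cohort import (
    OBPITrace,
    Scenario,
    ScenarioSpec,
    TrainingVariant,
    obpis_averted,
    yearly_obpi_counts,
)
from .economics import CostTrace, total_cost
from .outcomes import QALYGains, QALYTrace, incremental_qalys, qaly_totals
from .params import CoverageTable, ModelConfig

__all__ = ["Dominance", "IncrementalResult", "icer", "classify", "compare_scenarios"]

QALY_KINDS = ("adult", "parental", "dyadic")


class Dominance(str, Enum):
    DOMINANT = "dominant"          # cheaper and more effective (SE quadrant)
    DOMINATED = "dominated"        # costlier and less effective (NW quadrant)
    TRADEOFF_NE = "tradeoff_ne"    # costlier but more effective
    TRADEOFF_SW = "tradeoff_sw"    # cheaper but less effective


def icer(delta_cost: float, delta_qalys: float) -> float | None:
    """Incremental cost per QALY gained; ``None`` when the QALY delta
    is zero (the ratio is undefined, never a division error)."""
    if delta_qalys == 0:
        return None
    return delta_cost / delta_qalys


def classify(delta_cost: float, delta_qalys: float) -> Dominance:
    """Quadrant of the cost-effectiveness plane.

    Strict dominance requires strict signs; boundary cases (a zero
    delta) fall to the trade-off quadrant given by the cost sign.
    """
    if delta_cost < 0 and delta_qalys > 0:
        return Dominance.DOMINANT
    if delta_cost > 0 and delta_qalys < 0:
        return Dominance.DOMINATED
    return Dominance.TRADEOFF_NE if delta_cost >= 0 else Dominance.TRADEOFF_SW


@dataclass(frozen=True)
class ScenarioOutputs:
    """End-to-end outputs for one scenario under one cost variant."""

    obpi: OBPITrace
    cost: CostTrace
    qaly: QALYTrace


@dataclass(frozen=True)
class IncrementalResult:
    """Nationwide rollout vs current practice.

    Deltas are nationwide minus current, so a negative ``delta_cost``
    is a saving and negative ``delta_obpis`` means injuries averted.
    """

    variant: TrainingVariant
    nationwide: ScenarioOutputs
    current: ScenarioOutputs
    delta_cost: float
    delta_obpis: float
    delta_qalys: QALYGains

    @property
    def obpis_averted(self) -> float:
        return -self.delta_obpis

    def icer_for(self, kind: str) -> float | None:
        return icer(self.delta_cost, getattr(self.delta_qalys, kind))

    def dominance_for(self, kind: str) -> Dominance:
        return classify(self.delta_cost, getattr(self.delta_qalys, kind))

    @property
    def icers(self) -> dict[str, float | None]:
        return {k: self.icer_for(k) for k in QALY_KINDS}

    @property
    def dominance(self) -> dict[str, Dominance]:
        return {k: self.dominance_for(k) for k in QALY_KINDS}

    def summary_frame(self) -> pd.DataFrame:
        """Headline table: totals per scenario plus incrementals."""
        rows = [
            ("obpis", self.nationwide.obpi.cumulative_total,
             self.current.obpi.cumulative_total, self.delta_obpis, None),
            ("cost_gbp", self.nationwide.cost.total_discounted,
             self.current.cost.total_discounted, self.delta_cost, None),
        ]
        for kind in QALY_KINDS:
            nat = getattr(self.nationwide.qaly, f"{kind}_qalys")
            cur = getattr(self.current.qaly, f"{kind}_qalys")
            rows.append(
                (
                    f"qalys_{kind}",
                    nat,
                    cur,
                    getattr(self.delta_qalys, kind),
                    self.dominance_for(kind).value,
                )
            )
        return pd.DataFrame(
            rows,
            columns=["quantity", "nationwide", "current", "difference", "dominance"],
        )

    def report_text(self) -> str:
        """Human-readable summary mirroring the published layout
        (negative ICERs are annotated with their dominance flag, since
        a bare negative ratio is ambiguous without quadrant context)."""
        lines = [
            f"Variant: {self.variant.value}",
            f"OBPIs  nationwide {self.nationwide.obpi.cumulative_total:,.0f}"
            f"  current {self.current.obpi.cumulative_total:,.0f}"
            f"  difference {self.delta_obpis:,.0f}",
            f"Costs  nationwide GBP {self.nationwide.cost.total_discounted:,.0f}"
            f"  current GBP {self.current.cost.total_discounted:,.0f}"
            f"  difference GBP {self.delta_cost:,.0f}",
        ]
        for kind in QALY_KINDS:
            ratio = self.icer_for(kind)
            flag = self.dominance_for(kind).value
            shown = "undefined" if ratio is None else f"GBP {ratio:,.0f}"
            lines.append(
                f"ICER ({kind} QALYs): {shown} per QALY ({flag}); "
                f"QALY gain {getattr(self.delta_qalys, kind):,.0f}"
            )
        return "\n".join(lines)


def run_scenario(
    scenario: Scenario,
    config: ModelConfig,
    coverage: CoverageTable,
    variant: TrainingVariant = TrainingVariant.PROMPT,
) -> ScenarioOutputs:
    spec = ScenarioSpec(scenario, variant)
    obpi = yearly_obpi_counts(spec, config, coverage)
    cost = total_cost(spec, config, coverage, obpi)
    qaly = qaly_totals(obpi, config)
    return ScenarioOutputs(obpi, cost, qaly)


def compare_scenarios(
    config: ModelConfig,
    coverage: CoverageTable,
    variant: TrainingVariant = TrainingVariant.PROMPT,
) -> IncrementalResult:
    """Run both scenarios end-to-end and form all incrementals."""
    nat = run_scenario(Scenario.NATIONWIDE, config, coverage, variant)
    cur = run_scenario(Scenario.CURRENT, config, coverage, variant)
    return IncrementalResult(
        variant=variant,
        nationwide=nat,
        current=cur,
        delta_cost=nat.cost.total_discounted - cur.cost.total_discounted,
        delta_obpis=-obpis_averted(nat.obpi, cur.obpi),
        delta_qalys=incremental_qalys(nat.qaly, cur.qaly),
    )
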