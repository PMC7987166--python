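"""Probabilistic sensitivity analysis.

Each Monte Carlo draw samples the uncertain inputs from their declared
distributions (triangular for birth rate and costs, beta for the
baseline injury probability and the utility scores), rebuilds the model
and records the incremental outputs.  Conventions:

* the decline schedule rescales proportionally to the sampled baseline
  probability, preserving the piecewise-linear shape;
* coverage cohorts keep their base-case *proportions* of the sampled
  birth rate;
* parameters are sampled independently (no correlation structure);
* summaries are means with 2.5/97.5 percentile intervals — percentile
  rather than normal-approximation intervals, because the published
  intervals are asymmetric;
* each draw gets its own child RNG stream spawned deterministically
  from the run seed, so any draw is reproducible in isolation.

Per-draw ICER intervals are percentiles of the per-draw ratios; the
alternative (ratios of percentile bounds) is not computed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cea import QALY_KINDS, compare_scenarios
from .cohort import TrainingVariant
from .params import ConfigError, CoverageTable, ModelConfig

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "beta_shapes_from_moments",
    "sample",
    "default_distributions",
    "load_distributions",
    "run_psa",
    "summarize",
    "ce_plane_points",
    "quadrant_shares",
]

#: outputs recorded per draw
_OUTPUT_COLS = (
    "obpis_nationwide",
    "obpis_current",
    "obpis_averted",
    "delta_cost",
    "delta_qalys_adult",
    "delta_qalys_parental",
    "delta_qalys_dyadic",
    "icer_adult",
    "icer_parental",
    "icer_dyadic",
)


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one scalar input.

    ``fixed(value)`` always returns the base value; ``triangular`` is
    parameterised (min, mode, max); ``beta`` by (mean, sd) with
    method-of-moments shapes, truncated to [lo, hi].
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "triangular", "beta"):
            raise ConfigError(f"kind: unknown distribution '{self.kind}'")
        p = self.params
        if self.kind == "fixed" and "value" not in p:
            raise ConfigError("fixed: needs 'value'")
        if self.kind == "triangular":
            if {"min", "mode", "max"} - set(p):
                raise ConfigError("triangular: needs min, mode, max")
            if not p["min"] <= p["mode"] <= p["max"]:
                raise ConfigError("triangular: requires min <= mode <= max")
        if self.kind == "beta":
            if {"mean", "sd"} - set(p):
                raise ConfigError("beta: needs mean, sd")
            beta_shapes_from_moments(p["mean"], p["sd"])  # feasibility check

    @classmethod
    def fixed(cls, value: float) -> "DistributionSpec":
        return cls("fixed", {"value": value})

    @classmethod
    def triangular(cls, lo: float, mode: float, hi: float) -> "DistributionSpec":
        return cls("triangular", {"min": lo, "mode": mode, "max": hi})

    @classmethod
    def beta_mean_sd(
        cls, mean: float, sd: float, lo: float = 0.0, hi: float = 1.0
    ) -> "DistributionSpec":
        return cls("beta", {"mean": mean, "sd": sd, "lo": lo, "hi": hi})


def beta_shapes_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta shapes for a given mean and sd on [0, 1].

    alpha = mean*nu, beta = (1-mean)*nu with nu = mean(1-mean)/sd^2 - 1.
    """
    if not 0 < mean < 1:
        raise ConfigError("mean: beta mean must be strictly inside (0, 1)")
    var = sd * sd
    if var <= 0:
        raise ConfigError("sd: beta sd must be > 0")
    if var >= mean * (1 - mean):
        raise ConfigError(
            f"sd: variance {var:g} infeasible for beta with mean {mean:g} "
            f"(must be < mean*(1-mean) = {mean * (1 - mean):g})"
        )
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def sample(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value; truncation bounds, where declared, are enforced
    by clipping."""
    p = spec.params
    if spec.kind == "fixed":
        return float(p["value"])
    if spec.kind == "triangular":
        if p["min"] == p["max"]:
            return float(p["mode"])
        return float(rng.triangular(p["min"], p["mode"], p["max"]))
    a, b = beta_shapes_from_moments(p["mean"], p["sd"])
    val = float(rng.beta(a, b))
    lo = p.get("lo", 0.0)
    hi = p.get("hi", 1.0)
    return float(min(max(val, lo), hi))


def default_distributions(config: ModelConfig) -> dict[str, DistributionSpec]:
    """Base-case PSA distributions: birth rate triangular over the
    10-year range (mode = base rate), costs triangular at +/-20%,
    baseline probability and utilities beta from mean and sd (the
    population norm's sd comes from its lower bound because the upper
    was truncated at 1.00)."""
    return {
        "annual_births": DistributionSpec.triangular(611_337, 648_107, 671_255),
        "baseline_obpi_prob": DistributionSpec.beta_mean_sd(0.000192, 0.000055),
        "cost_prompt_first": DistributionSpec.triangular(13.53, 16.91, 20.29),
        "cost_prompt_subsequent": DistributionSpec.triangular(12.45, 15.56, 18.67),
        "cost_sd_first": DistributionSpec.triangular(1.43, 1.79, 2.14),
        "cost_sd_subsequent": DistributionSpec.triangular(1.14, 1.43, 1.71),
        "mean_litigation_cost": DistributionSpec.triangular(271_103, 338_879, 406_654),
        "utility_affected_adult": DistributionSpec.beta_mean_sd(0.56, 0.28),
        "utility_parent_affected": DistributionSpec.beta_mean_sd(0.80, 0.19),
        "utility_population": DistributionSpec.beta_mean_sd(0.86, 0.24, hi=1.00),
    }


def load_distributions(path: str | Path) -> dict[str, DistributionSpec]:
    """Read the ``psa:`` section of a model configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    section = (raw or {}).get("psa") or {}
    out: dict[str, DistributionSpec] = {}
    for name, entry in section.items():
        kind = entry.get("kind")
        if kind == "fixed":
            out[name] = DistributionSpec.fixed(entry["value"])
        elif kind == "triangular":
            out[name] = DistributionSpec.triangular(
                entry["min"], entry["mode"], entry["max"]
            )
        elif kind == "beta":
            out[name] = DistributionSpec.beta_mean_sd(
                entry["mean"], entry["sd"], entry.get("lo", 0.0), entry.get("hi", 1.0)
            )
        else:
            raise ConfigError(f"psa.{name}: unknown distribution kind '{kind}'")
    return out


_SAMPLED_CONFIG_FIELDS = (
    "annual_births",
    "baseline_obpi_prob",
    "cost_prompt_first",
    "cost_prompt_subsequent",
    "cost_sd_first",
    "cost_sd_subsequent",
    "mean_litigation_cost",
    "utility_affected_adult",
    "utility_parent_affected",
    "utility_population",
)


def _draw_inputs(
    config: ModelConfig,
    coverage: CoverageTable,
    dists: Mapping[str, DistributionSpec],
    rng: np.random.Generator,
) -> tuple[ModelConfig, CoverageTable, dict[str, float]]:
    sampled: dict[str, float] = {}
    for name in _SAMPLED_CONFIG_FIELDS:
        spec = dists.get(name)
        sampled[name] = (
            sample(spec, rng) if spec is not None else float(getattr(config, name))
        )
    changes: dict = dict(sampled)
    # the decline schedule keeps its shape, rescaled to the sampled baseline
    p0 = sampled["baseline_obpi_prob"]
    base_p0 = config.baseline_obpi_prob
    if base_p0 > 0 and p0 != base_p0:
        changes["effect_anchor_probs"] = tuple(
            p * p0 / base_p0 for p in config.effect_anchor_probs
        )
        # rescaled anchors are no longer the tabulated values; keep full
        # precision (a degenerate all-fixed PSA reproduces the base case
        # bit-exactly because this branch is never taken)
        changes["schedule_round_decimals"] = None
    draw_config = config.replace(**changes)
    # coverage keeps base-case proportions of the sampled birth rate
    factor = (
        sampled["annual_births"] / config.annual_births
        if config.annual_births > 0
        else 0.0
    )
    return draw_config, coverage.scaled(factor), sampled


@dataclass(frozen=True)
class PSAResult:
    variant: TrainingVariant
    n_draws: int
    seed: int
    #: one row per draw: sampled parameters plus incremental outputs
    draws: pd.DataFrame

    def summarize(self) -> pd.DataFrame:
        return summarize(self)

    def ce_plane_points(self, qaly_kind: str) -> pd.DataFrame:
        return ce_plane_points(self, qaly_kind)


def run_psa(
    config: ModelConfig,
    coverage: CoverageTable,
    variant: TrainingVariant = TrainingVariant.PROMPT,
    n_draws: int = 1000,
    seed: int = 0,
    distributions: Mapping[str, DistributionSpec] | None = None,
) -> PSAResult:
    """Monte Carlo PSA over both scenarios.

    Fully reproducible from ``seed``.  A draw whose model run fails is
    recorded with its error message, never silently dropped.
    """
    if n_draws < 1:
        raise ConfigError("n_draws: must be >= 1")
    if distributions is None:
        distributions = default_distributions(config)
    streams = np.random.SeedSequence(seed).spawn(n_draws)
    rows = []
    for i, child in enumerate(streams):
        rng = np.random.default_rng(child)
        row: dict[str, object] = {"draw": i}
        try:
            draw_config, draw_cov, sampled = _draw_inputs(
                config, coverage, distributions, rng
            )
            row.update(sampled)
            res = compare_scenarios(draw_config, draw_cov, variant)
            row["obpis_nationwide"] = res.nationwide.obpi.cumulative_total
            row["obpis_current"] = res.current.obpi.cumulative_total
            row["obpis_averted"] = res.obpis_averted
            row["delta_cost"] = res.delta_cost
            for kind in QALY_KINDS:
                row[f"delta_qalys_{kind}"] = getattr(res.delta_qalys, kind)
                ratio = res.icer_for(kind)
                row[f"icer_{kind}"] = np.nan if ratio is None else ratio
            row["error"] = ""
        except Exception as exc:  # recorded, not dropped
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    draws = pd.DataFrame(rows)
    return PSAResult(variant, n_draws, seed, draws)


def summarize(result: PSAResult) -> pd.DataFrame:
    """Means and 95% percentile intervals over successful draws."""
    ok = result.draws[result.draws["error"] == ""]
    if len(ok) < 1:
        raise ConfigError("draws: no successful draws to summarise")
    rows = []
    for col in _OUTPUT_COLS:
        vals = ok[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0:
            mean = lo = hi = np.nan
        else:
            mean = float(np.mean(finite))
            if len(finite) >= 2:
                lo, hi = (float(q) for q in np.percentile(finite, [2.5, 97.5]))
            else:
                lo = hi = np.nan
        rows.append((col, mean, lo, hi, len(finite)))
    return pd.DataFrame(rows, columns=["output", "mean", "ci_lo", "ci_hi", "n"])


_QUADRANTS = {
    (True, True): "NE",   # more effective, costlier
    (True, False): "SE",  # more effective, cheaper
    (False, True): "NW",
    (False, False): "SW",
}


def ce_plane_points(result: PSAResult, qaly_kind: str) -> pd.DataFrame:
    """Per-draw (QALY gain, cost difference) points with quadrant
    labels; the SE quadrant (gain > 0, cost < 0) is dominance.

    Quadrant shares are available via
    ``points["quadrant"].value_counts(normalize=True)``.
    """
    if qaly_kind not in QALY_KINDS:
        raise ConfigError(f"qaly_kind: must be one of {QALY_KINDS}")
    ok = result.draws[result.draws["error"] == ""]
    dq = ok[f"delta_qalys_{qaly_kind}"].to_numpy(dtype=float)
    dc = ok["delta_cost"].to_numpy(dtype=float)
    quadrant = [
        _QUADRANTS[(q > 0, c > 0)] for q, c in zip(dq, dc)
    ]
    return pd.DataFrame(
        {
            "draw": ok["draw"].to_numpy(),
            "delta_qalys": dq,
            "delta_cost": dc,
            "quadrant": quadrant,
        }
    )


def quadrant_shares(points: pd.DataFrame) -> dict[str, float]:
    counts = points["quadrant"].value_counts(normalize=True)
    return {q: float(counts.get(q, 0.0)) for q in ("NE", "SE", "SW", "NW")}
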