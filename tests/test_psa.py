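"""Distribution sampling, PSA reproducibility, and summaries."""
import numpy as np
import pytest

from obpi_cea import (
    ConfigError,
    DistributionSpec,
    beta_shapes_from_moments,
    compare_scenarios,
    run_psa,
)
from obpi_cea.psa import (
    _SAMPLED_CONFIG_FIELDS,
    ce_plane_points,
    default_distributions,
    load_distributions,
    quadrant_shares,
    sample,
)

RNG = lambda: np.random.default_rng(123)  # noqa: E731


def fixed_at_base(config):
    return {
        name: DistributionSpec.fixed(float(getattr(config, name)))
        for name in _SAMPLED_CONFIG_FIELDS
    }


class TestDistributionSpec:
    def test_beta_shapes_closed_form(self):
        a, b = beta_shapes_from_moments(0.56, 0.28)
        assert (round(a, 3), round(b, 3)) == (1.200, 0.943)

    def test_infeasible_beta_variance_rejected(self):
        with pytest.raises(ConfigError, match="sd"):
            beta_shapes_from_moments(0.5, 0.6)

    def test_invalid_triangular_rejected(self):
        with pytest.raises(ConfigError, match="triangular"):
            DistributionSpec.triangular(2.0, 1.0, 3.0)

    def test_fixed_always_returns_base(self):
        spec = DistributionSpec.fixed(0.035)
        rng = RNG()
        assert all(sample(spec, rng) == 0.035 for _ in range(10))

    def test_triangular_moments(self):
        spec = DistributionSpec.triangular(1.0, 2.0, 6.0)
        rng = RNG()
        draws = np.array([sample(spec, rng) for _ in range(100_000)])
        mean = (1 + 2 + 6) / 3
        var = (1 + 4 + 36 - 1 * 2 - 1 * 6 - 2 * 6) / 18
        se = np.sqrt(var / len(draws))
        assert abs(draws.mean() - mean) < 3 * se
        assert draws.min() >= 1.0 and draws.max() <= 6.0

    def test_beta_moments(self):
        spec = DistributionSpec.beta_mean_sd(0.56, 0.28)
        rng = RNG()
        draws = np.array([sample(spec, rng) for _ in range(100_000)])
        se = 0.28 / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.56) < 3 * se
        assert abs(draws.std() - 0.28) < 0.01

    def test_population_utility_never_exceeds_one(self):
        spec = DistributionSpec.beta_mean_sd(0.86, 0.24, hi=1.00)
        rng = RNG()
        draws = [sample(spec, rng) for _ in range(20_000)]
        assert max(draws) <= 1.00

    def test_packaged_distributions_cover_all_sampled_fields(self, base_config):
        from importlib import resources

        ref = resources.files("obpi_cea").joinpath("data/base_case.yaml")
        with resources.as_file(ref) as p:
            dists = load_distributions(p)
        assert set(dists) == set(_SAMPLED_CONFIG_FIELDS)
        defaults = default_distributions(base_config)
        assert set(defaults) == set(_SAMPLED_CONFIG_FIELDS)


class TestRunPsa:
    def test_seed_determinism(self, base_config, base_coverage):
        a = run_psa(base_config, base_coverage, n_draws=40, seed=7)
        b = run_psa(base_config, base_coverage, n_draws=40, seed=7)
        assert a.draws.equals(b.draws)
        c = run_psa(base_config, base_coverage, n_draws=40, seed=8)
        assert not a.draws["obpis_averted"].equals(c.draws["obpis_averted"])

    def test_degenerate_psa_equals_base_case_exactly(
        self, base_config, base_coverage
    ):
        res = run_psa(
            base_config,
            base_coverage,
            n_draws=5,
            seed=0,
            distributions=fixed_at_base(base_config),
        )
        det = compare_scenarios(base_config, base_coverage)
        assert (res.draws["obpis_averted"] == det.obpis_averted).all()
        assert (res.draws["delta_cost"] == det.delta_cost).all()
        assert (res.draws["delta_qalys_dyadic"] == det.delta_qalys.dyadic).all()

    def test_zero_width_intervals_for_constant_draws(
        self, base_config, base_coverage
    ):
        res = run_psa(
            base_config,
            base_coverage,
            n_draws=5,
            seed=0,
            distributions=fixed_at_base(base_config),
        )
        summary = res.summarize().set_index("output")
        row = summary.loc["obpis_averted"]
        assert row["ci_lo"] == row["ci_hi"] == row["mean"]

    def test_summary_mean_is_arithmetic_mean(self, base_config, base_coverage):
        res = run_psa(base_config, base_coverage, n_draws=60, seed=3)
        summary = res.summarize().set_index("output")
        assert summary.loc["delta_cost", "mean"] == pytest.approx(
            res.draws["delta_cost"].mean()
        )
        lo, hi = np.percentile(res.draws["obpis_averted"], [2.5, 97.5])
        assert summary.loc["obpis_averted", "ci_lo"] == pytest.approx(lo)
        assert summary.loc["obpis_averted", "ci_hi"] == pytest.approx(hi)

    def test_no_draw_errors_under_base_distributions(
        self, base_config, base_coverage
    ):
        res = run_psa(base_config, base_coverage, n_draws=60, seed=5)
        assert (res.draws["error"] == "").all()

    def test_widening_input_range_never_narrows_output_interval(
        self, base_config, base_coverage
    ):
        """Averted-injury uncertainty grows with baseline-probability
        uncertainty (all other inputs held fixed)."""
        widths = []
        for sd in (0.00002, 0.00006):
            dists = fixed_at_base(base_config)
            dists["baseline_obpi_prob"] = DistributionSpec.beta_mean_sd(
                0.000192, sd
            )
            res = run_psa(
                base_config, base_coverage, n_draws=150, seed=11,
                distributions=dists,
            )
            summary = res.summarize().set_index("output")
            widths.append(
                summary.loc["obpis_averted", "ci_hi"]
                - summary.loc["obpis_averted", "ci_lo"]
            )
        assert widths[1] >= widths[0]


class TestCePlane:
    def test_degenerate_psa_single_point(self, base_config, base_coverage):
        res = run_psa(
            base_config, base_coverage, n_draws=4, seed=0,
            distributions=fixed_at_base(base_config),
        )
        points = ce_plane_points(res, "dyadic")
        assert points["delta_qalys"].nunique() == 1
        assert points["delta_cost"].nunique() == 1
        # the base case is dominant: all mass in the SE quadrant
        assert quadrant_shares(points)["SE"] == 1.0

    def test_shares_sum_to_one(self, base_config, base_coverage):
        res = run_psa(base_config, base_coverage, n_draws=80, seed=2)
        for kind in ("adult", "parental", "dyadic"):
            shares = quadrant_shares(ce_plane_points(res, kind))
            assert sum(shares.values()) == pytest.approx(1.0)

    def test_unknown_qaly_kind_rejected(self, base_config, base_coverage):
        res = run_psa(base_config, base_coverage, n_draws=2, seed=0)
        with pytest.raises(ConfigError):
            ce_plane_points(res, "child")
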