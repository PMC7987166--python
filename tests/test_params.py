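"""Configuration loading, validation, and the probability-decline
schedule."""
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from obpi_cea import (
    ConfigError,
    CoverageCohort,
    CoverageTable,
    ModelConfig,
    build_probability_schedule,
    default_config,
    load_config,
    save_config,
)
from obpi_cea.params import validate_inputs

# the published 13-value schedule (probability of permanent OBPI by
# completed years since training started)
PRINTED_SCHEDULE = [
    0.000192, 0.000182, 0.000171, 0.000161, 0.000150, 0.000131,
    0.000113, 0.000094, 0.000075, 0.000056, 0.000038, 0.000019, 0.0,
]
BASE_ANCHORS = [(0, 0.000192), (4, 0.000150), (12, 0.0)]


class TestDefaultConfig:
    def test_base_case_scalars(self, base_config, base_coverage):
        assert base_config.annual_births == 648_107
        assert base_config.horizon_years == 30
        assert base_config.discount_rate == 0.035
        assert base_config.claims_inflation == 0.10
        assert base_config.mean_litigation_cost == 338_879

    def test_coverage_totals(self, base_coverage):
        # nine cohorts covering 244,498 of the annual births
        assert len(base_coverage) == 9
        assert base_coverage.total_births == 244_498

    def test_defaults_fill_missing_fields(self, tmp_path):
        p = tmp_path / "partial.yaml"
        p.write_text("model: {horizon_years: 10}\ncoverage: []\n")
        config, coverage = load_config(p)
        assert config.horizon_years == 10
        assert config.annual_births == 648_107  # base-case default
        assert coverage.total_births == 0


class TestValidation:
    @pytest.mark.parametrize(
        "changes,field",
        [
            ({"utility_affected_adult": 1.2}, "utility_affected_adult"),
            ({"discount_rate": -0.1}, "discount_rate"),
            ({"horizon_years": 0}, "horizon_years"),
            ({"mean_litigation_cost": -5.0}, "mean_litigation_cost"),
            ({"baseline_obpi_prob": 1.5}, "baseline_obpi_prob"),
        ],
    )
    def test_out_of_range_scalar_names_field(self, changes, field):
        with pytest.raises(ConfigError, match=field):
            ModelConfig(**changes)

    def test_anchor_probs_must_be_nonincreasing(self):
        with pytest.raises(ConfigError, match="effect_anchor"):
            ModelConfig(
                effect_anchor_years=(0, 4, 12),
                effect_anchor_probs=(0.000192, 0.0002, 0.0),
            )

    def test_coverage_cannot_exceed_annual_births(self):
        config = ModelConfig(annual_births=100)
        coverage = CoverageTable((CoverageCohort(200, 1),))
        with pytest.raises(ConfigError, match="coverage"):
            validate_inputs(config, coverage)

    def test_duplicate_cohort_years_rejected(self):
        with pytest.raises(ConfigError, match="distinct"):
            CoverageTable((CoverageCohort(10, 3), CoverageCohort(20, 3)))

    def test_malformed_yaml_names_file(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("model: {annual_births: [}\n")
        with pytest.raises(ConfigError, match="bad.yaml"):
            load_config(p)

    def test_unknown_model_key_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("model: {annualbirths: 1}\n")
        with pytest.raises(ConfigError, match="annualbirths"):
            load_config(p)


class TestSchedule:
    def test_reproduces_printed_table_with_rounding(self):
        sched = build_probability_schedule(BASE_ANCHORS, round_decimals=6)
        assert list(sched.probs) == pytest.approx(PRINTED_SCHEDULE, abs=1e-12)

    def test_unrounded_interpolation(self):
        sched = build_probability_schedule(BASE_ANCHORS, round_decimals=None)
        # one eighth of the 0.15-per-mille-to-zero segment per year
        assert sched.at(5) == pytest.approx(0.00013125, rel=1e-12)

    def test_zero_beyond_final_anchor(self):
        sched = build_probability_schedule(BASE_ANCHORS)
        assert sched.at(20) == 0.0
        assert sched.at(12) == 0.0

    @pytest.mark.parametrize(
        "anchors,msg",
        [
            ([(0, 0.1), (2, 0.2), (4, 0.0)], "non-increasing"),
            ([(1, 0.1), (4, 0.0)], "year 0"),
            ([(0, 0.1), (4, 0.05)], "final anchor"),
            ([(0, 0.1), (0, 0.0)], "increasing"),
        ],
    )
    def test_invalid_anchors_rejected(self, anchors, msg):
        with pytest.raises(ConfigError, match=msg):
            build_probability_schedule(anchors)

    @given(
        probs=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=6,
        ),
        gaps=st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=6),
    )
    def test_schedule_nonincreasing_for_any_valid_anchors(self, probs, gaps):
        """Monotone anchors always give a monotone integer-year schedule."""
        probs = sorted(probs, reverse=True) + [0.0]
        years, y = [0], 0
        for g in gaps[: len(probs) - 1]:
            y += g
            years.append(y)
        anchors = list(zip(years, probs[: len(years) - 1] + [0.0]))
        sched = build_probability_schedule(anchors, round_decimals=None)
        vals = list(sched.probs)
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 0.0


def test_config_round_trip(tmp_path, base_config, base_coverage):
    """save/load reproduces identical values."""
    p = tmp_path / "rt.yaml"
    save_config(base_config, base_coverage, p)
    config2, coverage2 = load_config(p)
    assert config2 == base_config
    assert coverage2 == base_coverage


def test_schedule_rescaling_preserves_shape():
    sched = build_probability_schedule(BASE_ANCHORS, round_decimals=None)
    scaled = sched.rescaled(0.000384)
    assert scaled.baseline == pytest.approx(0.000384)
    for k in range(13):
        assert scaled.at(k) == pytest.approx(2 * sched.at(k), rel=1e-12)
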