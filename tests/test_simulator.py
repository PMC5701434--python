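import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exptrait import (
    LatentModel,
    SimulationConfig,
    ThresholdSpec,
    calibrate_thresholds,
    derive_seed,
    draw_latent,
    draw_thresholds,
    marginal_item_prevalence,
    score_binary,
    simulate_condition,
)


class TestDrawLatent:
    def test_moments_match_exponential(self):
        rng = np.random.default_rng(derive_seed(0, "latent-moments"))
        n = 100_000
        x1 = draw_latent(n, LatentModel(1.0), rng)
        assert abs(x1.mean() - 1.0) < 3.0 / np.sqrt(n)
        x2 = draw_latent(n, LatentModel(2.0), rng)
        # SD of Exp(rate) is 1/rate; MC error of sample SD ~ sd/sqrt(n)
        assert abs(x2.std(ddof=1) - 0.5) < 3.0 * 0.5 / np.sqrt(n)

    def test_support_nonnegative(self):
        rng = np.random.default_rng(1)
        assert draw_latent(1000, LatentModel(3.0), rng).min() >= 0.0


class TestDrawThresholds:
    def test_degenerate_normal_columns_constant(self):
        rng = np.random.default_rng(2)
        spec = ThresholdSpec(family="normal", means=np.array([1.0, 2.0]), sd=0.0)
        t = draw_thresholds(50, spec, rng)
        assert np.all(t[:, 0] == 1.0) and np.all(t[:, 1] == 2.0)

    def test_uniform_bounds_respected(self):
        rng = np.random.default_rng(3)
        spec = ThresholdSpec(family="uniform", bounds=(0.0, 5.0))
        t = draw_thresholds(1000, spec, rng, n_questions=7)
        assert t.shape == (1000, 7)
        assert t.min() >= 0.0 and t.max() <= 5.0

    def test_normal_column_mean_obeys_lln(self):
        rng = np.random.default_rng(derive_seed(0, "threshold-lln"))
        n, sd = 100_000, 2.0
        spec = ThresholdSpec(family="normal", means=np.array([2.9]), sd=sd)
        t = draw_thresholds(n, spec, rng)
        assert abs(t[:, 0].mean() - 2.9) < 3.0 * sd / np.sqrt(n)


class TestScoreBinary:
    def test_strict_comparison(self):
        scores = score_binary(np.array([2.0, 1.5]), np.array([[1.5], [1.5]]))
        assert scores[0, 0] == 1  # above threshold
        assert scores[1, 0] == 0  # tie scores 0

    def test_infinite_thresholds_give_zero_totals(self):
        scores = score_binary(np.ones(4), np.full((4, 3), np.inf))
        assert scores.sum() == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_binary(np.ones(4), np.ones((3, 2)))


class TestSimulateCondition:
    def test_totals_equal_row_sums_and_stay_in_range(self, cisr, fixture_table):
        cfg = SimulationConfig(
            LatentModel(1.0), ThresholdSpec(family="normal", sd=2.0), n=2000, seed=9
        )
        res = simulate_condition(cfg, cisr, fixture_table)
        np.testing.assert_array_equal(res.totals, res.scores.sum(axis=1))
        assert res.totals.min() >= 0 and res.totals.max() <= 57

    def test_same_seed_reproduces_exactly(self, cisr, fixture_table):
        cfg = SimulationConfig(
            LatentModel(2.0), ThresholdSpec(family="normal", sd=1.0), n=2000, seed=4
        )
        a = simulate_condition(cfg, cisr, fixture_table)
        b = simulate_condition(cfg, cisr, fixture_table)
        np.testing.assert_array_equal(a.totals, b.totals)

    def test_noise_free_limit_recovers_table_prevalence(self, cisr, fixture_table):
        # sigma -> 0: each question's endorsement rate is its table value
        cfg = SimulationConfig(
            LatentModel(1.0),
            ThresholdSpec(family="normal", sd=1e-9),
            n=100_000,
            seed=derive_seed(0, "sim-noise-free"),
        )
        res = simulate_condition(cfg, cisr, fixture_table)
        p = fixture_table.p
        se = np.sqrt(p * (1 - p) / cfg.n)
        assert np.all(np.abs(res.empirical_prevalence - p) <= 3.9 * se)

    @pytest.mark.parametrize("sd", [0.0, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("rate", [1.0, 2.0])
    def test_prevalence_converges_to_closed_form(
        self, toy_instrument, toy_table, sd, rate
    ):
        lm = LatentModel(rate)
        spec = calibrate_thresholds(toy_table, lm, sd)
        cfg = SimulationConfig(
            lm, spec, n=100_000, seed=derive_seed(0, f"sim-marginal-{rate}-{sd}")
        )
        res = simulate_condition(cfg, toy_instrument)
        expected = np.array(
            [marginal_item_prevalence(m, sd, rate) for m in spec.means]
        )
        se = np.sqrt(expected * (1 - expected) / cfg.n)
        assert np.all(np.abs(res.empirical_prevalence - expected) <= 3.9 * se)

    def test_uncalibrated_spec_without_table_rejected(self, cisr):
        cfg = SimulationConfig(
            LatentModel(1.0), ThresholdSpec(family="normal", sd=1.0), n=10, seed=0
        )
        with pytest.raises(ValueError):
            simulate_condition(cfg, cisr, prevalence=None)

    def test_config_json_echo_contains_condition(self, cisr):
        cfg = SimulationConfig(
            LatentModel(3.0),
            ThresholdSpec(family="uniform", bounds=(0.0, 5.0)),
            n=10,
            seed=77,
        )
        echo = cfg.to_json()
        assert '"lambda": 3.0' in echo and '"seed": 77' in echo


@given(bump=st.floats(0.0, 10.0), seed=st.integers(0, 2**16))
@settings(deadline=None, derandomize=True, max_examples=25)
def test_raising_latent_never_lowers_scores(bump, seed):
    """Monotone endorsement: a higher latent value can only add symptoms."""
    rng = np.random.default_rng(seed)
    latent = rng.exponential(size=20)
    thresholds = rng.normal(1.0, 2.0, size=(20, 8))
    base = score_binary(latent, thresholds)
    raised = score_binary(latent + bump, thresholds)
    assert np.all(raised >= base)
    assert np.all(raised.sum(axis=1) >= base.sum(axis=1))
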