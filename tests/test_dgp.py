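"""Scenario grid, intervention schedules and the panel generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itspower import (
    ScenarioSpec,
    build_scenario_grid,
    generate_panel,
    intervention_schedule,
    mean_function,
    true_coefficients,
)
from itspower.dgp import (
    DEFAULT_EFFECTS,
    DEFAULT_SUBJECTS,
    DEFAULT_TIMEPOINTS,
    SHAPES,
    occasion_means,
    replication_seed,
)

EVEN_T = st.integers(min_value=3, max_value=15).map(lambda k: 2 * k)


class TestScenarioGrid:
    def test_default_grid_has_384_scenarios(self):
        grid = build_scenario_grid()
        assert len(grid) == 8 * 8 * 6 == 384
        assert len(set(grid)) == 384

    def test_singleton_product(self):
        assert len(build_scenario_grid([6], [100], [0.30])) == 1

    def test_lexicographic_order(self):
        grid = build_scenario_grid([6, 8], [100, 300], [0.01, 0.30])
        assert len(grid) == 8
        first = grid[0]
        assert (first.n_timepoints, first.n_subjects, first.effect_size) == (6, 100, 0.01)
        keys = [(s.n_timepoints, s.n_subjects, s.effect_size) for s in grid]
        assert keys == sorted(keys)

    @pytest.mark.parametrize(
        "args",
        [([], [100], [0.1]), ([6], [], [0.1]), ([6], [100], [])],
    )
    def test_empty_axis_rejected(self, args):
        with pytest.raises(ValueError):
            build_scenario_grid(*args)

    def test_odd_timepoints_rejected(self):
        with pytest.raises(ValueError):
            build_scenario_grid([7], [100], [0.1])

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(6, 100, 0.1, noise_var=-1.0)


class TestInterventionSchedule:
    def test_t6_centering_and_indicators(self):
        s = intervention_schedule(6, "step_slope")
        assert np.allclose(s.centered_times, [-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
        assert s.x1.tolist() == [0, 0, 0, 1, 1, 1]
        assert not s.has_second_intervention
        assert s.x2.tolist() == [0] * 6

    def test_second_boundary_round_half_up(self):
        s = intervention_schedule(8, "two_steps_slope")
        assert s.second_boundary_index == 6
        assert s.x2.tolist() == [0, 0, 0, 0, 0, 0, 1, 1]

    def test_second_boundary_t20(self):
        s = intervention_schedule(20, "two_steps_slope")
        assert s.second_boundary_index == 15
        assert int(s.x2.sum()) == 5

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(t=EVEN_T, shape=st.sampled_from(SHAPES))
    def test_schedule_invariants(self, t, shape):
        s = intervention_schedule(t, shape)
        # midpoint placement: exactly half the occasions are post-intervention
        assert int(s.x1.sum()) == t // 2
        # x2 never precedes x1, and exists only for the two-step shape
        assert np.all(s.x2 <= s.x1)
        if shape != "two_steps_slope":
            assert not s.x2.any()
        else:
            assert 1 <= s.x2.sum() < t // 2 + 1
        # centered times are half-integers symmetric about zero
        assert np.allclose(s.centered_times + s.centered_times[::-1], 0.0)
        assert np.allclose((s.centered_times * 2) % 1, 0.0)

    def test_odd_or_short_series_rejected(self):
        with pytest.raises(ValueError):
            intervention_schedule(7, "step_slope")
        with pytest.raises(ValueError):
            intervention_schedule(4, "step_slope")


class TestTrueCoefficients:
    def test_step_slope_effect_030(self):
        p = true_coefficients(ScenarioSpec(6, 100, 0.30, shape="step_slope"))
        assert p.beta_step == pytest.approx(-4.95)
        assert p.beta_slopechange == pytest.approx(-4.95)
        assert p.beta_step2 == 0.0

    def test_second_step_is_half_the_first(self):
        p = true_coefficients(ScenarioSpec(8, 100, 0.10, shape="two_steps_slope"))
        assert p.beta_step2 == pytest.approx(-0.825)
        assert p.beta_step2 == pytest.approx(0.5 * p.beta_step)

    @pytest.mark.parametrize("effect", [0.01, 0.15, 0.30])
    def test_step_only_has_no_slope_change(self, effect):
        p = true_coefficients(ScenarioSpec(10, 100, effect, shape="step_only"))
        assert p.beta_slopechange == 0.0
        assert p.beta_step == pytest.approx(-effect * 16.5)

    def test_intercept_is_midpoint_extrapolation(self):
        p = true_coefficients(ScenarioSpec(12, 100, 0.1))
        assert p.beta0 == pytest.approx(170 + 16.5 * 5.5)

    def test_quadratic_term_never_generated(self):
        for shape in SHAPES:
            assert true_coefficients(ScenarioSpec(8, 10, 0.3, shape=shape)).beta_t2 == 0

    def test_sign_symmetry(self):
        pos = true_coefficients(ScenarioSpec(8, 10, 0.15, shape="two_steps_slope"))
        neg = true_coefficients(ScenarioSpec(8, 10, -0.15, shape="two_steps_slope"))
        assert neg.beta_step == -pos.beta_step
        assert neg.beta_slopechange == -pos.beta_slopechange
        assert neg.beta_step2 == -pos.beta_step2


class TestMeanFunction:
    def test_pre_intervention_is_uninterrupted_line(self):
        p = true_coefficients(ScenarioSpec(6, 10, 0.30))
        assert mean_function(-0.5, 0, 0, p) == pytest.approx(p.beta0 - 0.5 * 16.5)

    def test_hand_evaluated_post_intervention_point(self):
        # T=6, effect 0.30, step+slope, first post-intervention occasion
        p = true_coefficients(ScenarioSpec(6, 10, 0.30, shape="step_slope"))
        assert mean_function(0.5, 1, 0, p) == pytest.approx(
            170 + 16.5 * 3 - 4.95 - 4.95 * 0.5
        ) == pytest.approx(212.075)

    def test_zero_effect_matches_no_intervention_line(self):
        base = ScenarioSpec(10, 10, 0.0, shape="step_slope")
        p = true_coefficients(base)
        s = intervention_schedule(10, "step_slope")
        line = p.beta0 + p.beta1 * s.centered_times
        assert np.allclose(mean_function(s.centered_times, s.x1, s.x2, p), line)

    def test_post_intervention_increment_is_attenuated_slope(self):
        # each occasion-to-occasion gain after the intervention is 16.5*(1-e)
        e = 0.15
        mu = occasion_means(ScenarioSpec(12, 10, e, shape="slope_only"))
        post_gains = np.diff(mu)[6:]
        assert np.allclose(post_gains, 16.5 * (1 - e))


class TestGeneratePanel:
    def test_noiseless_panel_lies_on_mean_function(self, noiseless_scenario):
        panel = generate_panel(noiseless_scenario, seed=3)
        mu = occasion_means(noiseless_scenario)
        expected = np.repeat(mu, noiseless_scenario.n_subjects)
        assert np.array_equal(panel.score, expected)

    def test_noiseless_no_intervention_is_pure_growth_line(self):
        s = ScenarioSpec(8, 3, 0.0, baseline_var=0.0, noise_var=0.0)
        panel = generate_panel(s, seed=0)
        for occ in range(1, 9):
            scores = panel.score[panel.occasion == occ]
            assert np.allclose(scores, 170 + 16.5 * (occ - 1))

    def test_record_counts_and_layout(self, small_scenario):
        panel = generate_panel(small_scenario, seed=7)
        assert len(panel) == 8 * 50
        counts = np.bincount(panel.occasion)[1:]
        assert (counts == 50).all()
        df = panel.to_frame()
        assert list(df.columns) == ["subject_id", "occasion", "centered_time", "score"]

    def test_seeded_determinism(self, small_scenario):
        a = generate_panel(small_scenario, seed=42)
        b = generate_panel(small_scenario, seed=42)
        assert np.array_equal(a.score, b.score)
        c = generate_panel(small_scenario, seed=43)
        assert not np.array_equal(a.score, c.score)

    def test_cross_sectional_variance_near_50(self):
        s = ScenarioSpec(6, 100_000, 0.0)
        panel = generate_panel(s, seed=11)
        v = panel.score[panel.occasion == 3].var(ddof=1)
        # var = baseline 25 + noise 25; sampling error ~ sqrt(2/n)*50
        assert v == pytest.approx(50.0, rel=0.03)

    def test_occasion_means_converge_to_mean_function(self):
        s = ScenarioSpec(6, 100_000, 0.15, shape="two_steps_slope")
        panel = generate_panel(s, seed=5)
        mu = occasion_means(s)
        se = np.sqrt(50.0 / s.n_subjects)
        for occ in range(1, 7):
            observed = panel.score[panel.occasion == occ].mean()
            assert abs(observed - mu[occ - 1]) < 3 * se

    def test_longitudinal_shares_baseline_within_subject(self):
        s = ScenarioSpec(
            6, 40, 0.1, sampling_mode="longitudinal", noise_var=0.0
        )
        panel = generate_panel(s, seed=9)
        mu = occasion_means(s)
        dev = panel.score - np.repeat(mu, s.n_subjects)
        by_subject = dev.reshape(6, 40)  # occasion-major layout
        # each subject's baseline deviation is constant across occasions
        assert np.allclose(by_subject.std(axis=0), 0.0, atol=1e-12)
        assert by_subject[0].std() > 0

    def test_replication_seed_ignores_model_but_not_rep(self, small_scenario):
        s1 = replication_seed(1, small_scenario, 0)
        s2 = replication_seed(1, small_scenario, 0)
        s3 = replication_seed(1, small_scenario, 1)
        assert s1.entropy == s2.entropy
        assert s1.entropy != s3.entropy
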