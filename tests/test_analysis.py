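"""Tests for the trajectory/rewiring analysis tools."""

import numpy as np
import pytest

from synsample.analysis import (
    SnapshotSeries,
    ci_correlation_significance,
    ci_pair_correlations,
    classify_synapse_fate,
    contribution_decomposition,
    detect_movement_onset,
    fate_fractions,
    movement_completion_time,
    parameter_change_amplitude,
    pca_parameter_trajectory,
    dpca_reward_projection,
    trial_averaged_activity,
    turnover_count,
)


class TestPerformance:
    def test_mean_of_durations(self):
        trials = [{"duration_ms": d} for d in (800, 1000, 1200)]
        mean, sem = movement_completion_time(trials)
        assert mean == pytest.approx(1.0)
        assert sem > 0

    def test_all_timeouts_censored_at_ten_seconds(self):
        trials = [{"duration_ms": 10_000}] * 5
        mean, sem = movement_completion_time(trials)
        assert mean == pytest.approx(10.0) and sem == 0.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            movement_completion_time([])


class TestTurnover:
    def test_single_disappearance(self):
        assert turnover_count(np.array([1.0]), np.array([-1.0])) == (0, 1, 1)

    def test_identical_snapshots(self):
        theta = np.array([1.0, -0.5, 0.0])
        assert turnover_count(theta, theta) == (0, 0, 0)

    def test_counts_and_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 1000)
        b = a + rng.normal(0, 0.5, 1000)
        app, dis, tot = turnover_count(a, b)
        assert tot == app + dis
        perm = rng.permutation(1000)
        assert turnover_count(a[perm], b[perm]) == (app, dis, tot)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            turnover_count(np.zeros(3), np.zeros(4))


class TestFate:
    @pytest.mark.parametrize(
        "t1, t2, expected",
        [
            (0.5, -0.2, "transient_decaying"),
            (-1.0, -1.0, "stable_nonfunctional"),
            (0.1, 3.0, "stable_functional"),
            (-0.1, 0.2, "transient_emerging"),
            (0.0, 0.0, "stable_nonfunctional"),  # theta = 0 is nonfunctional
        ],
    )
    def test_classification(self, t1, t2, expected):
        assert classify_synapse_fate(np.array([t1]), np.array([t2]))[0] == expected

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        frac = fate_fractions(rng.normal(size=500), rng.normal(size=500))
        assert sum(frac.values()) == pytest.approx(1.0)


class TestCICorrelations:
    def test_duplicated_weights_fully_correlated(self):
        # every (pre, post) pair hosts two synapses with identical weight
        n = 200
        rng = np.random.default_rng(0)
        w_pair = rng.uniform(0.1, 1.0, n)
        weights = np.repeat(w_pair, 2)
        pre = np.repeat(np.arange(n) % 20, 2)
        post = np.repeat(np.arange(n) // 20, 2)
        r_ci, r_nci, n_ci, n_nci = ci_pair_correlations(weights, pre, post, rng)
        assert r_ci == pytest.approx(1.0)
        assert abs(r_nci) < 0.3

    def test_independent_weights_uncorrelated(self):
        rng = np.random.default_rng(2)
        n = 4000
        pre = rng.integers(0, 40, n)
        post = rng.integers(0, 10, n)
        weights = rng.uniform(0.05, 1.0, n)
        r_ci, r_nci, *_ = ci_pair_correlations(weights, pre, post, rng)
        assert abs(r_ci) < 0.1 and abs(r_nci) < 0.1

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ci_pair_correlations(
                np.array([1.0, 1.0]), np.array([0, 1]), np.array([0, 1])
            )

    def test_significance_across_trials(self):
        p = ci_correlation_significance(
            [0.45, 0.47, 0.44, 0.46, 0.48], [0.07, 0.09, 0.08, 0.06, 0.10]
        )
        assert p < 0.01


class TestContributionDecomposition:
    @pytest.mark.parametrize(
        "r_ci, r_nci, expected",
        [
            (0.46, 0.08, (0.38, 0.54, 0.08)),
            (1.0, 0.0, (1.0, 0.0, 0.0)),
            (0.5, 0.2, (0.3, 0.5, 0.2)),
        ],
    )
    def test_values(self, r_ci, r_nci, expected):
        out = contribution_decomposition(r_ci, r_nci)
        assert out == pytest.approx(expected)
        assert sum(out) == pytest.approx(1.0)

    def test_ordering_violation_warns(self):
        with pytest.warns(UserWarning):
            contribution_decomposition(0.2, 0.5)


class TestMovementOnset:
    def test_constructed_step_detected(self):
        # flat, then a steep ramp: velocity exceeds 1.5 right at the step
        lever = np.concatenate([np.zeros(100), np.arange(1, 61) * 2.0])
        onset = detect_movement_onset(lever, sample_ms=5.0)
        assert onset == pytest.approx(100 * 5 / 1000.0, abs=0.015)

    def test_constant_trace_uses_fallback(self):
        lever = np.zeros(200)
        onset = detect_movement_onset(lever)
        assert onset == pytest.approx(5e-3, abs=5e-3)  # argmax of zero velocity

    def test_downward_movement_not_detected_as_onset(self):
        lever = np.concatenate([np.zeros(100), -np.arange(1, 61) * 2.0, np.zeros(100)])
        onset = detect_movement_onset(lever)
        # no upward super-threshold velocity -> fallback (max velocity)
        assert onset != pytest.approx(0.5, abs=0.01)


class TestTrialAveragedActivity:
    def test_reliable_neuron_peaks_at_one(self):
        rng = np.random.default_rng(0)
        onsets = np.arange(1000, 21_000, 2000)
        t_spk, n_spk = [], []
        for onset in onsets:
            for k in range(3):
                t_spk.append(onset + 100 + 10 * k)
                n_spk.append(0)
            t_spk.append(onset - 300)
            n_spk.append(1)
        mat, order = trial_averaged_activity(
            np.array(t_spk), np.array(n_spk), onsets, n_neurons=3
        )
        assert mat[0].max() == pytest.approx(1.0)
        assert mat[2].max() == 0.0  # silent neuron -> zero row
        assert sorted(order.tolist()) == [0, 1, 2]  # a permutation

    def test_peak_ordering(self):
        onsets = [1000.0, 3000.0]
        t_spk = [1200, 3200, 1050, 3050]
        n_spk = [0, 0, 1, 1]
        mat, order = trial_averaged_activity(
            np.array(t_spk), np.array(n_spk), onsets, n_neurons=2
        )
        assert order.tolist() == [1, 0]  # neuron 1 peaks earlier

    def test_insufficient_trials(self):
        with pytest.raises(ValueError):
            trial_averaged_activity(
                np.array([10]), np.array([0]), [], n_neurons=1
            )


class TestParameterChangeAmplitude:
    def test_identical_snapshots_zero(self):
        s = SnapshotSeries(np.array([0.0, 1.0]), np.zeros((2, 5)))
        np.testing.assert_allclose(parameter_change_amplitude(s), 0.0)

    def test_normalized_max_is_one(self):
        rng = np.random.default_rng(0)
        s = SnapshotSeries(np.arange(10.0), rng.normal(size=(10, 50)))
        steps = parameter_change_amplitude(s, normalize=True)
        assert steps.max() == pytest.approx(1.0)

    def test_ou_step_norm_scales_with_sqrt_temperature(self):
        """Prior-only diffusion: expected step norm ~ sqrt(2 beta T dt K);
        quadrupling T doubles the step amplitude."""
        from synsample.dynamics import LearningConfig, PriorSpec, theta_sde_step
        from dataclasses import replace

        rng = np.random.default_rng(3)
        K = 4000
        prior = PriorSpec("gaussian", mu=0.0, sigma=2.0)
        norms = {}
        for T in (0.1, 0.4):
            cfg = replace(LearningConfig(), temperature=T, clip=None)
            theta = np.zeros(K)
            snaps = [theta.copy()]
            for _ in range(20):
                theta = np.asarray(
                    theta_sde_step(
                        theta, prior.log_gradient(theta), cfg, rng.standard_normal(K)
                    )
                )
                snaps.append(theta.copy())
            s = SnapshotSeries(np.arange(21.0), np.array(snaps))
            norms[T] = parameter_change_amplitude(s).mean()
        assert norms[0.4] / norms[0.1] == pytest.approx(2.0, rel=0.05)


class TestPCA:
    def test_line_trajectory_single_component(self):
        t = np.linspace(0, 1, 50)
        direction = np.ones(40)
        s = SnapshotSeries(t, np.outer(t, direction))
        proj, ev = pca_parameter_trajectory(s, fraction=1.0)
        assert ev[0] == pytest.approx(1.0)
        assert proj.shape == (50, 3)

    def test_variance_fractions_sorted_and_bounded(self):
        rng = np.random.default_rng(0)
        s = SnapshotSeries(np.arange(30.0), rng.normal(size=(30, 100)))
        _, ev = pca_parameter_trajectory(s, fraction=0.5, rng=rng)
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1.0 + 1e-9

    def test_too_few_snapshots(self):
        s = SnapshotSeries(np.arange(3.0), np.zeros((3, 10)))
        with pytest.raises(ValueError):
            pca_parameter_trajectory(s)


class TestDPCA:
    def test_affine_function_of_reward_fully_explained(self):
        rng = np.random.default_rng(0)
        reward = rng.uniform(0, 1, 200)
        direction = rng.normal(size=50)
        thetas = np.outer(reward, direction)
        s = SnapshotSeries(np.arange(200.0), thetas)
        out = dpca_reward_projection(s, reward, n_params=50, rng=rng)
        assert not out["degenerate"]
        assert out["reward_variance_fraction"][0] > 0.999

    def test_constant_reward_degenerate(self):
        rng = np.random.default_rng(0)
        s = SnapshotSeries(np.arange(50.0), rng.normal(size=(50, 20)))
        out = dpca_reward_projection(s, np.full(50, 0.3), rng=rng)
        assert out["degenerate"]
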