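"""Tests for the routing task, lever task and STDP pairing protocol."""

import numpy as np
import pytest

from synsample.dynamics import LearningConfig
from synsample.network import simulate
from synsample.tasks import (
    LeverTask,
    RoutingTask,
    TrialState,
    TuningCurvePattern,
    apply_task_switch,
    build_lever_scaffold,
    build_routing_scaffold,
    generate_tuning_input,
    lever_decode,
    lever_trial_step,
    routing_reward,
    run_stdp_protocol,
)
from synsample.tasks.lever import (
    PHASE_CUE,
    PHASE_HOLDING,
    PHASE_REWARD,
    REWARD_WINDOW_MS,
    TRIAL_TIMEOUT_MS,
)


class TestRoutingScaffold:
    def test_counts_and_structure(self):
        sc = build_routing_scaffold(seed=0)
        assert sc.n_inputs == 200 and sc.n_net == 20
        assert len(sc.pools["T1"]) == 10 and len(sc.pools["T2"]) == 10
        assert np.intersect1d(sc.pools["T1"], sc.pools["T2"]).size == 0
        # Binomial(10, 0.5) per pair -> ~20,000 potential synapses
        assert sc.n_synapses == pytest.approx(20_000, rel=0.05)
        per_pair = sc.n_synapses / (200 * 20)
        assert per_pair == pytest.approx(5.0, rel=0.05)

    def test_lateral_inhibition_nonpositive(self):
        sc = build_routing_scaffold(seed=1)
        lateral = sc.w_fixed[200:, :]
        assert np.all(lateral <= 0.0)
        assert (lateral < 0).mean() == pytest.approx(0.5 * 19 / 20, rel=0.15)

    def test_plastic_synapses_are_input_sourced(self):
        sc = build_routing_scaffold(seed=2)
        assert sc.pre.max() < 200  # inputs only


class TestTuningInput:
    def test_rate_extremes(self):
        rng = np.random.default_rng(0)
        pat = TuningCurvePattern.generate(rng)
        pat.jitter_sigma = 0.0
        pat.centers[0] = pat.stimulus_points[0]  # center on the stimulus
        rates = generate_tuning_input(pat, 0, rng)
        assert rates[0] == pytest.approx(62.0)  # 60 Hz peak + 2 Hz background
        far = np.argmax(np.sum((pat.centers - pat.stimulus_points[0]) ** 2, axis=1))
        assert rates[far] == pytest.approx(2.0, abs=0.5)
        assert np.all(rates >= 2.0) and np.all(rates <= 62.0)

    def test_background_segment(self):
        rng = np.random.default_rng(0)
        pat = TuningCurvePattern.generate(rng)
        np.testing.assert_allclose(generate_tuning_input(pat, -1, rng), 2.0)

    def test_segment_durations_in_range(self):
        sc = build_routing_scaffold(seed=3)
        task = RoutingTask()
        task.reset(np.random.default_rng(0), sc)
        durations = {"pattern": [], "gap": []}
        current, length = None, 0
        for t in range(0, 60_000, task.chunk_ms):
            _, phase = task.input_rates(t)
            kind = "gap" if phase == 0 else "pattern"
            if current is None or kind == current:
                length += task.chunk_ms
            else:
                durations[current].append(length)
                length = task.chunk_ms
            current = kind
        assert all(745 <= d <= 1505 for d in durations["pattern"])
        assert all(995 <= d <= 2005 for d in durations["gap"])
        assert len(durations["pattern"]) > 5


class TestRoutingReward:
    def test_wrong_direction_is_zero(self):
        assert routing_reward(10.0, 30.0, 1) == 0.0
        assert routing_reward(30.0, 10.0, 2) == 0.0

    def test_soft_threshold_midpoint(self):
        assert routing_reward(50.0, 25.0 - 0.0, 1) == pytest.approx(0.5)
        assert routing_reward(10.0, 35.0, 2) == pytest.approx(0.5)

    def test_background_is_zero(self):
        assert routing_reward(100.0, 0.0, 0) == 0.0

    def test_bounded(self):
        for nu1 in (0.0, 10.0, 200.0):
            r = routing_reward(nu1, 0.0, 1)
            assert 0.0 <= r <= 1.0


class TestLeverScaffold:
    def test_populations(self):
        sc = build_lever_scaffold(seed=0)
        assert sc.n_inputs == 200 and sc.n_net == 80 and sc.n_plastic_post == 60
        d, u, hid = sc.pools["D"], sc.pools["U"], sc.pools["hidden"]
        assert len(d) == 10 and len(u) == 10 and len(hid) == 40
        assert np.intersect1d(d, u).size == 0
        # D and U receive no direct input synapses
        input_targets = np.unique(sc.post[sc.pre < 200])
        assert np.intersect1d(input_targets, np.concatenate([d, u])).size == 0

    def test_synapse_count_near_47k(self):
        sc = build_lever_scaffold(seed=0)
        assert sc.n_synapses == pytest.approx(47_700, rel=0.05)

    def test_fixed_weight_signs_and_probability(self):
        sc = build_lever_scaffold(seed=1)
        exc_to_inh = sc.w_fixed[200:260, 60:]
        inh_out = sc.w_fixed[260:, :]
        assert np.all(exc_to_inh >= 0.0)
        assert np.all(inh_out <= 0.0)
        assert (exc_to_inh > 0).mean() == pytest.approx(0.575, abs=0.04)
        assert (inh_out[:, :60] < 0).mean() == pytest.approx(0.6, abs=0.05)

    def test_inhibitory_neuron_constants(self):
        sc = build_lever_scaffold(seed=0)
        assert np.all(sc.src_tau_m[260:] == 0.010)
        assert np.all(sc.t_ref[60:] == 0.002)
        assert np.all(sc.t_ref[:60] == 0.005)


class TestLeverDecode:
    def test_no_spikes_is_zero(self):
        np.testing.assert_allclose(lever_decode([], [], 100), 0.0)

    def test_antisymmetry(self):
        lever = lever_decode([10], [10], 500)
        np.testing.assert_allclose(lever, 0.0, atol=1e-12)
        up = lever_decode([], [10], 500)
        down = lever_decode([10], [], 500)
        np.testing.assert_allclose(up, -down, atol=1e-12)

    def test_single_up_spike_peak_time(self):
        lever = lever_decode([], [0], 1000)
        assert np.all(lever >= 0)
        assert np.argmax(lever) == pytest.approx(128, abs=2)

    def test_linearity_in_spike_counts(self):
        one = lever_decode([], [5], 400)
        three = lever_decode([], [5, 5, 5], 400)
        np.testing.assert_allclose(three, 3 * one, rtol=1e-9)


class TestLeverTrialStep:
    def _run_path(self, lever_path, rng=None):
        rng = rng or np.random.default_rng(0)
        trial = TrialState()
        trials = []
        rewards = []
        for t, pos in enumerate(lever_path):
            r, trial = lever_trial_step(trial, pos, t, rng, trials)
            rewards.append(r)
        return np.array(rewards), trial, trials

    def test_high_without_low_gives_no_reward(self):
        path = np.concatenate([np.zeros(50), np.full(100, 6.0)])
        rewards, trial, trials = self._run_path(path)
        assert rewards.sum() == 0.0 and trial.phase == PHASE_CUE

    def test_success_and_reward_duration(self):
        path = np.concatenate([np.zeros(20), np.full(30, -6.0), np.full(600, 6.0)])
        rewards, trial, trials = self._run_path(path)
        assert trials and trials[0]["completed"]
        assert rewards.sum() == REWARD_WINDOW_MS  # r = 1 for exactly 400 ms
        assert trial.phase in (PHASE_REWARD, PHASE_HOLDING)

    def test_timeout_aborts_without_reward(self):
        path = np.zeros(TRIAL_TIMEOUT_MS + 10)
        rewards, trial, trials = self._run_path(path)
        assert rewards.sum() == 0.0
        assert trials and not trials[0]["completed"]
        assert trials[0]["duration_ms"] == TRIAL_TIMEOUT_MS
        assert trial.phase == PHASE_HOLDING


class TestTaskSwitch:
    def _task(self, seed=0):
        sc = build_lever_scaffold(seed)
        task = LeverTask()
        task.reset(np.random.default_rng(seed), sc)
        return task, sc

    def test_switch_negates_lever(self):
        task, sc = self._task()
        counts = np.zeros(sc.n_net, dtype=np.int64)
        counts[task._pool_u[0]] = 2
        task.reward(0, counts)
        lever_before = task.lever_positions[-1]
        task2, _ = self._task()
        apply_task_switch(task2)
        task2.reward(0, counts)
        assert task2.lever_positions[-1] == pytest.approx(-lever_before)

    def test_switch_regenerates_cue(self):
        task, _ = self._task()
        cue_before = task._cue.copy()
        apply_task_switch(task)
        assert not np.allclose(task._cue, cue_before)

    def test_double_switch_restores_decoding(self):
        task, _ = self._task()
        sign0 = task.decode_sign
        apply_task_switch(task)
        apply_task_switch(task)
        assert task.decode_sign == sign0


class TestSTDPProtocol:
    def test_protocol_span_and_pairings(self):
        res = run_stdp_protocol(n_synapses=5, seed=0, duration_s=150.0)
        assert res.times_s[-1] == pytest.approx(150.0)
        from synsample.tasks.stdp import _protocol_events

        pre, post, reward = _protocol_events(True, 0.6, 150_000)
        assert pre.sum() == 15 * 10  # 15 pairings x 10 pre spikes
        assert post.sum() == 15 * 10 * 3
        assert reward.sum() == 15 * 300  # 300-ms pulse per pairing

    def test_reward_drives_potentiation(self):
        res = run_stdp_protocol(with_reward=True, n_synapses=20, seed=1)
        assert res.final_mean_pct > 5.0

    def test_no_pre_no_change(self):
        a = run_stdp_protocol(with_reward=True, with_pre=False, n_synapses=20, seed=1)
        # pure prior + diffusion drift: small compared to the reward effect
        b = run_stdp_protocol(with_reward=True, with_pre=True, n_synapses=20, seed=1)
        assert abs(a.final_mean_pct) < 5.0
        assert b.final_mean_pct > a.final_mean_pct

    def test_common_seed_shares_noise(self):
        a = run_stdp_protocol(with_reward=False, with_pre=False, n_synapses=5, seed=3)
        b = run_stdp_protocol(with_reward=False, with_pre=False, n_synapses=5, seed=3)
        np.testing.assert_array_equal(a.w, b.w)


def test_routing_task_smoke_run():
    """A short closed-loop routing run wires together scaffold, stimulus,
    reward and plasticity without errors and records sane values."""
    sc = build_routing_scaffold(seed=4)
    buf = simulate(sc, RoutingTask(), LearningConfig(), 30.0, seed=4)
    assert buf.reward.size == 3000
    assert np.all((buf.reward >= 0) & (buf.reward <= 1))
    assert set(np.unique(buf.phase)).issubset({0, 1, 2})


def test_lever_task_smoke_run():
    sc = build_lever_scaffold(seed=4)
    task = LeverTask()
    buf = simulate(sc, task, LearningConfig(), 15.0, seed=4)
    assert buf.reward.size == 15_000
    lever = np.array(task.lever_positions)
    assert lever.shape[0] == 15_000
    assert np.all(np.isfinite(lever))
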