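"""Cortex-to-striatum pattern routing task.

Two distributed rate patterns P1, P2 over 200 Poisson input neurons
("cortex") must be routed to two pools of 10 medium spiny neurons (MSNs)
each, projecting to downstream targets T1 and T2.  All input-to-MSN
potential synapses are plastic; the MSNs inhibit each other through fixed
lateral connections.  Reward is a sigmoidal function of the rate difference
between the pool matching the currently presented pattern and the other
pool, recomputed every 10 ms from 500-ms sliding-window rate estimates, and
zero during background segments and whenever the wrong pool leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.special import expit

from ..dynamics import LearningConfig
from ..network import (
    NetworkScaffold,
    RecorderConfig,
    RecordingBuffer,
    simulate,
)

N_INPUTS = 200
N_MSN = 20
POOL_SIZE = 10

#: phase labels recorded alongside the reward trace
PHASE_BACKGROUND, PHASE_P1, PHASE_P2 = 0, 1, 2


@dataclass
class TuningCurvePattern:
    """Gaussian-tuning-curve stimulus ensemble in the unit cube.

    Each input neuron has a fixed tuning-curve center; a pattern is a point
    in the cube and drives neuron ``i`` at
    ``60 Hz * exp(-||c_i - x||^2 / (2 sigma_tc^2)) + 2 Hz``.  The stimulus
    point is jittered per presentation; presentations of 750-1500 ms
    alternate with 1000-2000 ms background (2 Hz) segments.
    """

    centers: np.ndarray  # (n_inputs, 3)
    stimulus_points: np.ndarray  # (n_patterns, 3)
    sigma_tc: float = 0.2
    jitter_sigma: float = 0.05
    max_rate: float = 60.0
    background: float = 2.0
    pattern_dur_ms: Tuple[int, int] = (750, 1500)
    gap_dur_ms: Tuple[int, int] = (1000, 2000)

    @classmethod
    def generate(
        cls, rng: np.random.Generator, n_inputs: int = N_INPUTS, n_patterns: int = 2
    ) -> "TuningCurvePattern":
        return cls(
            centers=rng.uniform(0.0, 1.0, size=(n_inputs, 3)),
            stimulus_points=rng.uniform(0.0, 1.0, size=(n_patterns, 3)),
        )

    def rates_at(self, point: np.ndarray) -> np.ndarray:
        d2 = np.sum((self.centers - point[None, :]) ** 2, axis=1)
        return self.max_rate * np.exp(-d2 / (2.0 * self.sigma_tc**2)) + self.background


def generate_tuning_input(
    pattern: TuningCurvePattern,
    pattern_id: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Input rates (Hz) for one presentation of pattern ``pattern_id``.

    The stimulus point receives fresh Gaussian jitter per presentation;
    ``pattern_id`` < 0 yields the pure 2-Hz background.
    """
    if pattern_id < 0:
        return np.full(pattern.centers.shape[0], pattern.background)
    point = pattern.stimulus_points[pattern_id] + rng.normal(
        0.0, pattern.jitter_sigma, size=3
    )
    return pattern.rates_at(point)


def routing_reward(
    nu1: float,
    nu2: float,
    pattern_id: int,
    nu_threshold: float = 25.0,
    slope: float = 5.0,
) -> float:
    """Reward for the current pool-rate estimates (pool rates in Hz).

    With ``I = +1`` for P1 and ``-1`` for P2: zero if ``I (nu1 - nu2) < 0``,
    otherwise the logistic sigmoid of ``(I nu1 - I nu2 - nu_threshold)/slope``
    with the soft firing threshold at 25 Hz.  Zero during background.
    """
    if pattern_id == PHASE_BACKGROUND:
        return 0.0
    sign = 1.0 if pattern_id == PHASE_P1 else -1.0
    diff = sign * (nu1 - nu2)
    if diff < 0.0:
        return 0.0
    return float(expit((diff - nu_threshold) / slope))


def build_routing_scaffold(seed: int) -> NetworkScaffold:
    """200 input neurons, 20 MSNs (10 per target pool), plastic feedforward.

    The number of potential synapses per (input, MSN) pair is
    Binomial(10, 0.5); lateral inhibition between MSNs has Bernoulli(0.5)
    connectivity with weights N(-1, 0.2) truncated at zero.
    """
    rng = np.random.default_rng(seed)
    n_src = N_INPUTS + N_MSN

    counts = rng.binomial(10, 0.5, size=(N_INPUTS, N_MSN))
    pre, post = np.nonzero(counts)
    reps = counts[pre, post]
    pre = np.repeat(pre, reps)
    post = np.repeat(post, reps)

    w_fixed = np.zeros((n_src, N_MSN))
    for i in range(N_MSN):
        for j in range(N_MSN):
            if i == j:
                continue
            if rng.random() < 0.5:
                w = rng.normal(-1.0, 0.2)
                while w > 0.0:  # truncation at zero by rejection
                    w = rng.normal(-1.0, 0.2)
                w_fixed[N_INPUTS + i, j] = w

    perm = rng.permutation(N_MSN)
    pools = {"T1": np.sort(perm[:POOL_SIZE]), "T2": np.sort(perm[POOL_SIZE:])}

    tags = ["input"] * N_INPUTS + ["MSN-T1" if k in pools["T1"] else "MSN-T2" for k in range(N_MSN)]
    return NetworkScaffold(
        n_inputs=N_INPUTS,
        n_net=N_MSN,
        n_plastic_post=N_MSN,
        tags=tags,
        src_tau_m=np.full(n_src, 0.020),
        src_tau_r=np.full(n_src, 0.002),
        t_ref=np.full(N_MSN, 0.005),
        pre=pre,
        post=post,
        w_fixed=w_fixed,
        pools=pools,
    )


@dataclass
class RoutingTask:
    """Driver-facing routing task: schedule, stimulus and reward.

    Pool rates are boxcar averages of spike counts over the trailing 500 ms,
    refreshed on the 10-ms reward grid.  Segment durations are drawn from
    the pattern/gap distributions and rounded to that grid.
    """

    chunk_ms: int = 10
    rate_window_ms: int = 500
    nu_threshold: float = 25.0
    slope: float = 5.0
    pattern: Optional[TuningCurvePattern] = None
    _rng: np.random.Generator = field(default=None, repr=False)  # type: ignore

    def reset(self, rng: np.random.Generator, scaffold: NetworkScaffold) -> None:
        self._rng = rng
        if self.pattern is None:
            self.pattern = TuningCurvePattern.generate(rng, scaffold.n_inputs)
        self._pool1 = scaffold.pools["T1"]
        self._pool2 = scaffold.pools["T2"]
        n_win = self.rate_window_ms // self.chunk_ms
        self._counts1 = np.zeros(n_win)
        self._counts2 = np.zeros(n_win)
        self._win_pos = 0
        self._segment_left = 0
        self._phase = PHASE_BACKGROUND
        self._rates = np.full(scaffold.n_inputs, self.pattern.background)
        self._in_gap = True

    def _next_segment(self) -> None:
        if self._in_gap:
            # start a pattern presentation
            pid = int(self._rng.integers(2))
            self._phase = PHASE_P1 if pid == 0 else PHASE_P2
            self._rates = generate_tuning_input(self.pattern, pid, self._rng)
            lo, hi = self.pattern.pattern_dur_ms
            self._segment_left = self._round_chunks(self._rng.uniform(lo, hi))
            self._in_gap = False
        else:
            self._phase = PHASE_BACKGROUND
            self._rates = generate_tuning_input(self.pattern, -1, self._rng)
            lo, hi = self.pattern.gap_dur_ms
            self._segment_left = self._round_chunks(self._rng.uniform(lo, hi))
            self._in_gap = True

    def _round_chunks(self, dur_ms: float) -> int:
        return max(1, int(round(dur_ms / self.chunk_ms)))

    def input_rates(self, t_ms: int):
        if self._segment_left == 0:
            self._next_segment()
        self._segment_left -= 1
        return self._rates, self._phase

    def pool_rates(self) -> Tuple[float, float]:
        """Pool output rates in Hz: boxcar spike count per pool / window."""
        denom = self.rate_window_ms / 1000.0
        return self._counts1.sum() / denom, self._counts2.sum() / denom

    def reward(self, t_ms: int, chunk_counts: np.ndarray) -> float:
        self._counts1[self._win_pos] = chunk_counts[self._pool1].sum()
        self._counts2[self._win_pos] = chunk_counts[self._pool2].sum()
        self._win_pos = (self._win_pos + 1) % self._counts1.shape[0]
        nu1, nu2 = self.pool_rates()
        return routing_reward(nu1, nu2, self._phase, self.nu_threshold, self.slope)


def run_routing_experiment(
    seed: int,
    duration_s: float,
    cfg: Optional[LearningConfig] = None,
    recorders: Optional[RecorderConfig] = None,
    slope: float = 5.0,
) -> RecordingBuffer:
    """Build the routing scaffold and run the full learning experiment.

    The scaffold, stimulus, spiking and plasticity-noise streams all derive
    from ``seed``.
    """
    cfg = cfg if cfg is not None else LearningConfig()
    scaffold = build_routing_scaffold(seed)
    task = RoutingTask(slope=slope)
    return simulate(scaffold, task, cfg, duration_s, seed, recorders=recorders)


def mean_pattern_reward(buf: RecordingBuffer, t_from_s: float, t_to_s: float) -> float:
    """Mean reward over pattern-presentation time in [t_from_s, t_to_s).

    This is the task performance as a fraction of the maximum achievable
    reward (r = 1 throughout every presentation).
    """
    t_s = buf.reward_t_ms / 1000.0
    sel = (t_s >= t_from_s) & (t_s < t_to_s) & (buf.phase != PHASE_BACKGROUND)
    if not np.any(sel):
        raise ValueError("no pattern presentations in the requested interval")
    return float(buf.reward[sel].mean())
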