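"""Cue-driven lever-press task for a recurrent excitatory/inhibitory network.

A recurrent scaffold of 60 excitatory and 20 inhibitory neurons receives a
fixed random cue pattern from 200 input neurons.  Two pools D and U of 10
excitatory neurons each control a virtual lever: the difference of their
pooled spike trains, filtered with a slow double-exponential kernel
(rise 50 ms, decay 500 ms), is the lever position.  A trial is successful
when the lever crosses +5 after first crossing -5 within 10 s of cue onset;
success triggers a 400-ms reward window (r = 1) followed by a 1-2-s holding
phase at 2-Hz background input.  A task switch exchanges the decoding signs
of D and U and regenerates the cue pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ..dynamics import LearningConfig
from ..network import (
    NetworkScaffold,
    RecorderConfig,
    RecordingBuffer,
    simulate,
)
from .routing import TuningCurvePattern

N_INPUTS = 200
N_EXC = 60
N_INH = 20
POOL_SIZE = 10
N_RECEIVING = 30

LEVER_TAU_M = 0.500
LEVER_TAU_R = 0.050
THRESH_LOW = -5.0
THRESH_HIGH = 5.0
TRIAL_TIMEOUT_MS = 10_000
REWARD_WINDOW_MS = 400
HOLDING_MS = (1000, 2000)

PHASE_HOLDING, PHASE_CUE, PHASE_REWARD = 0, 1, 2


def build_lever_scaffold(seed: int) -> NetworkScaffold:
    """Recurrent scaffold with cortex-like connection statistics.

    Half of the excitatory neurons can receive input synapses; pools D and U
    are drawn from the non-receiving half.  Potential plastic synapses
    (input->receiving and all ordered excitatory pairs) are Binomial(10, 0.5)
    per pair, about 47,000 in total.  Excitatory->inhibitory wiring is fixed
    with connection probability 0.575 and weights N(0.5, 0.1) truncated at
    zero; inhibitory->excitatory (p = 0.6) and inhibitory->inhibitory
    (p = 0.55) weights are N(-1, 0.2) truncated at zero.
    """
    rng = np.random.default_rng(seed)
    n_net = N_EXC + N_INH
    n_src = N_INPUTS + n_net

    exc = np.arange(N_EXC)
    receiving = np.sort(rng.choice(exc, N_RECEIVING, replace=False))
    others = np.setdiff1d(exc, receiving)
    perm = rng.permutation(others)
    pool_d = np.sort(perm[:POOL_SIZE])
    pool_u = np.sort(perm[POOL_SIZE : 2 * POOL_SIZE])
    hidden = np.setdiff1d(exc, np.concatenate([pool_d, pool_u]))

    pre_list: List[np.ndarray] = []
    post_list: List[np.ndarray] = []
    # input -> receiving excitatory
    counts = rng.binomial(10, 0.5, size=(N_INPUTS, N_RECEIVING))
    src, tgt = np.nonzero(counts)
    reps = counts[src, tgt]
    pre_list.append(np.repeat(src, reps))
    post_list.append(np.repeat(receiving[tgt], reps))
    # excitatory -> excitatory (no autapses)
    counts = rng.binomial(10, 0.5, size=(N_EXC, N_EXC))
    np.fill_diagonal(counts, 0)
    src, tgt = np.nonzero(counts)
    reps = counts[src, tgt]
    pre_list.append(np.repeat(N_INPUTS + src, reps))
    post_list.append(np.repeat(tgt, reps))
    pre = np.concatenate(pre_list)
    post = np.concatenate(post_list)

    def _truncated(mu, sigma, size, positive):
        w = rng.normal(mu, sigma, size=size)
        bad = w < 0.0 if positive else w > 0.0
        while np.any(bad):
            w[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
            bad = w < 0.0 if positive else w > 0.0
        return w

    w_fixed = np.zeros((n_src, n_net))
    # excitatory -> inhibitory
    mask = rng.random((N_EXC, N_INH)) < 0.575
    w_fixed[N_INPUTS : N_INPUTS + N_EXC, N_EXC:][mask] = _truncated(
        0.5, 0.1, int(mask.sum()), True
    )
    # inhibitory -> excitatory
    mask = rng.random((N_INH, N_EXC)) < 0.6
    w_fixed[N_INPUTS + N_EXC :, :N_EXC][mask] = _truncated(
        -1.0, 0.2, int(mask.sum()), False
    )
    # inhibitory -> inhibitory (no self-inhibition)
    mask = rng.random((N_INH, N_INH)) < 0.55
    np.fill_diagonal(mask, False)
    w_fixed[N_INPUTS + N_EXC :, N_EXC:][mask] = _truncated(
        -1.0, 0.2, int(mask.sum()), False
    )

    tau_m = np.full(n_src, 0.020)
    tau_r = np.full(n_src, 0.002)
    tau_m[N_INPUTS + N_EXC :] = 0.010
    tau_r[N_INPUTS + N_EXC :] = 0.001
    t_ref = np.full(n_net, 0.005)
    t_ref[N_EXC:] = 0.002

    def _tag(k: int) -> str:
        if k in pool_d:
            return "D"
        if k in pool_u:
            return "U"
        return "hidden"

    tags = ["input"] * N_INPUTS + [_tag(k) for k in range(N_EXC)] + ["inhibitory"] * N_INH
    return NetworkScaffold(
        n_inputs=N_INPUTS,
        n_net=n_net,
        n_plastic_post=N_EXC,
        tags=tags,
        src_tau_m=tau_m,
        src_tau_r=tau_r,
        t_ref=t_ref,
        pre=pre,
        post=post,
        w_fixed=w_fixed,
        pools={
            "D": pool_d,
            "U": pool_u,
            "hidden": hidden,
            "receiving": receiving,
            "inhibitory": np.arange(N_EXC, n_net),
        },
    )


def lever_decode(
    spikes_d_ms: np.ndarray,
    spikes_u_ms: np.ndarray,
    duration_ms: int,
    tau_m: float = LEVER_TAU_M,
    tau_r: float = LEVER_TAU_R,
) -> np.ndarray:
    """Lever position per ms from pooled D/U spike times.

    U spikes are weighted +1 and D spikes -1; the summed impulse train is
    filtered with the slow double-exponential PSP kernel (the same
    incremental two-exponential implementation as in the simulation).
    """
    impulses = np.zeros(duration_ms)
    for t in np.asarray(spikes_u_ms, dtype=np.int64):
        impulses[t] += 1.0
    for t in np.asarray(spikes_d_ms, dtype=np.int64):
        impulses[t] -= 1.0
    dm = np.exp(-0.001 / tau_m)
    dr = np.exp(-0.001 / tau_r)
    coef = tau_m / (tau_m - tau_r)
    a = b = 0.0
    out = np.empty(duration_ms)
    for t in range(duration_ms):
        a = a * dm + impulses[t]
        b = b * dr + impulses[t]
        out[t] = coef * (a - b)
    return out


@dataclass
class TrialState:
    """Phase machine of the lever task."""

    phase: int = PHASE_CUE
    crossed_low: bool = False
    t_in_trial_ms: int = 0
    phase_left_ms: int = 0
    onset_ms: int = 0


def lever_trial_step(
    trial: TrialState,
    lever: float,
    t_ms: int,
    rng: np.random.Generator,
    trials: Optional[List[dict]] = None,
) -> Tuple[float, TrialState]:
    """Advance the trial machine by one 1-ms step; returns (reward, state).

    Success -- the lever crossing +5 after having crossed -5, within 10 s of
    cue onset -- starts a 400-ms reward window (r = 1) followed by a holding
    phase of U[1, 2] s; a timeout aborts straight into the holding phase.
    """
    r = 0.0
    if trial.phase == PHASE_CUE:
        trial.t_in_trial_ms += 1
        if lever < THRESH_LOW:
            trial.crossed_low = True
        if trial.crossed_low and lever > THRESH_HIGH:
            if trials is not None:
                trials.append(
                    {
                        "onset_ms": trial.onset_ms,
                        "completed": True,
                        "duration_ms": trial.t_in_trial_ms,
                    }
                )
            trial.phase = PHASE_REWARD
            # the success step itself is the first of the 400 reward ms
            trial.phase_left_ms = REWARD_WINDOW_MS - 1
            r = 1.0
        elif trial.t_in_trial_ms >= TRIAL_TIMEOUT_MS:
            if trials is not None:
                trials.append(
                    {
                        "onset_ms": trial.onset_ms,
                        "completed": False,
                        "duration_ms": TRIAL_TIMEOUT_MS,
                    }
                )
            trial.phase = PHASE_HOLDING
            trial.phase_left_ms = int(rng.integers(HOLDING_MS[0], HOLDING_MS[1] + 1))
    elif trial.phase == PHASE_REWARD:
        r = 1.0
        trial.phase_left_ms -= 1
        if trial.phase_left_ms <= 0:
            trial.phase = PHASE_HOLDING
            trial.phase_left_ms = int(rng.integers(HOLDING_MS[0], HOLDING_MS[1] + 1))
    else:  # holding
        trial.phase_left_ms -= 1
        if trial.phase_left_ms <= 0:
            trial.phase = PHASE_CUE
            trial.crossed_low = False
            trial.t_in_trial_ms = 0
            trial.onset_ms = t_ms
    return r, trial


def apply_task_switch(task: "LeverTask") -> "LeverTask":
    """Exchange the decoding signs of pools D and U and redraw the cue."""
    task.decode_sign *= -1.0
    if task._lever_sign is not None:
        task._lever_sign *= -1.0
    task._regenerate_cue()
    return task


@dataclass
class LeverTask:
    """Driver-facing lever task (1-ms reward grid during trials)."""

    chunk_ms: int = 1
    switch_at_s: Optional[float] = None
    decode_sign: float = 1.0
    trials: List[dict] = field(default_factory=list)

    def reset(self, rng: np.random.Generator, scaffold: NetworkScaffold) -> None:
        self._rng = rng
        self._scaffold = scaffold
        self._pattern = TuningCurvePattern.generate(rng, scaffold.n_inputs, 1)
        self._cue = self._pattern.rates_at(self._pattern.stimulus_points[0])
        self._background = np.full(scaffold.n_inputs, 2.0)
        self._pool_d = scaffold.pools["D"]
        self._pool_u = scaffold.pools["U"]
        self._lever_sign = np.zeros(scaffold.n_net)
        self._lever_sign[self._pool_u] = self.decode_sign
        self._lever_sign[self._pool_d] = -self.decode_sign
        self._fa = self._fb = 0.0
        self._dm = np.exp(-0.001 / LEVER_TAU_M)
        self._dr = np.exp(-0.001 / LEVER_TAU_R)
        self._coef = LEVER_TAU_M / (LEVER_TAU_M - LEVER_TAU_R)
        self._trial = TrialState()
        self._switched = False
        self.trials = self.trials.__class__()
        self.lever_positions: List[float] = []

    def _regenerate_cue(self) -> None:
        point = self._rng.uniform(0.0, 1.0, size=3)
        self._cue = self._pattern.rates_at(point)

    def lever_readout(self):
        return self._lever_sign, LEVER_TAU_M, LEVER_TAU_R

    def input_rates(self, t_ms: int):
        if (
            self.switch_at_s is not None
            and not self._switched
            and t_ms >= self.switch_at_s * 1000.0
        ):
            apply_task_switch(self)
            self._switched = True
        if self._trial.phase == PHASE_CUE:
            return self._cue, PHASE_CUE
        return self._background, self._trial.phase

    def reward(self, t_ms: int, chunk_counts: np.ndarray) -> float:
        impulse = self.decode_sign * (
            chunk_counts[self._pool_u].sum() - chunk_counts[self._pool_d].sum()
        )
        self._fa = self._fa * self._dm + impulse
        self._fb = self._fb * self._dr + impulse
        lever = self._coef * (self._fa - self._fb)
        self.lever_positions.append(lever)
        r, self._trial = lever_trial_step(
            self._trial, lever, t_ms, self._rng, self.trials
        )
        return r


def run_lever_experiment(
    seed: int,
    duration_s: float,
    cfg: Optional[LearningConfig] = None,
    recorders: Optional[RecorderConfig] = None,
    switch_at_s: Optional[float] = None,
    rewiring_off_after_s: Optional[float] = None,
    consolidate_at_s: Optional[float] = None,
) -> RecordingBuffer:
    """Build the lever scaffold and run the self-configuration experiment."""
    cfg = cfg if cfg is not None else LearningConfig()
    scaffold = build_lever_scaffold(seed)
    task = LeverTask(switch_at_s=switch_at_s)
    return simulate(
        scaffold,
        task,
        cfg,
        duration_s,
        seed,
        recorders=recorders,
        rewiring_off_after_s=rewiring_off_after_s,
        consolidate_at_s=consolidate_at_s,
    )
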