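"""Dopamine-gated STDP pairing protocol.

Reproduces the classic uncaging experiment on a population of model
synapses: 15 pre/post pairings, one every 10 s.  Each pairing consists of 10
presynaptic spikes at 10 Hz, each followed after 10 ms by a brief
postsynaptic burst of 3 spikes at 100 Hz (total pairing duration 1 s).  The
postsynaptic membrane potential is clamped at u = -2.4 and the synapse
equations (eligibility trace, reward baseline, gradient trace, parameter
SDE) are integrated for each synapse.  Reward is a rectangular pulse of
amplitude 1 and duration 300 ms delivered at a configurable delay from each
pairing onset.

The protocol isolates the synapse model from any network, so it runs the
per-synapse recursions directly through the functions of
:mod:`synsample.dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dynamics import (
    LearningConfig,
    PriorSpec,
    eligibility_step,
    gradient_trace_step,
    reward_baseline_step,
    theta_sde_step,
    weight_from_theta,
)
from ..neurons import psp_kernel

N_PAIRINGS = 15
PAIRING_PERIOD_S = 10.0
PRE_SPIKES_PER_PAIRING = 10
PRE_RATE_HZ = 10.0
BURST_SPIKES = 3
BURST_RATE_HZ = 100.0
PRE_POST_LAG_MS = 10
REWARD_AMPLITUDE = 1.0
REWARD_DURATION_MS = 300
CLAMPED_U = -2.4


@dataclass
class STDPResult:
    """Weight-change time course of the pairing protocol."""

    times_s: np.ndarray  # sampling times (parameter-update grid)
    mean_pct: np.ndarray  # mean weight change, % of the pairing-onset value
    sem_pct: np.ndarray  # SEM across synapses
    w: np.ndarray  # (n_synapses, n_times) raw efficacies
    theta: np.ndarray  # final parameters

    @property
    def final_mean_pct(self) -> float:
        return float(self.mean_pct[-1])


def _protocol_events(with_pre: bool, delay_reward_s: float, n_ms: int):
    """Scripted pre/post spike indicator arrays and the reward trace."""
    pre = np.zeros(n_ms)
    post = np.zeros(n_ms)
    reward = np.zeros(n_ms)
    for p in range(N_PAIRINGS):
        onset = int(round(p * PAIRING_PERIOD_S * 1000))
        for k in range(PRE_SPIKES_PER_PAIRING):
            t_pre = onset + int(round(k * 1000.0 / PRE_RATE_HZ))
            if with_pre and t_pre < n_ms:
                pre[t_pre] = 1.0
            for b in range(BURST_SPIKES):
                t_post = t_pre + PRE_POST_LAG_MS + int(round(b * 1000.0 / BURST_RATE_HZ))
                if t_post < n_ms:
                    post[t_post] = 1.0
        r0 = onset + int(round(delay_reward_s * 1000))
        reward[max(r0, 0) : max(r0, 0) + REWARD_DURATION_MS] = REWARD_AMPLITUDE
    return pre, post, reward


def run_stdp_protocol(
    delay_reward_s: float = 0.6,
    with_reward: bool = True,
    with_pre: bool = True,
    n_synapses: int = 50,
    seed: int = 0,
    cfg: LearningConfig | None = None,
    prior: PriorSpec | None = None,
    theta_init: float = 3.0,
    duration_s: float = N_PAIRINGS * PAIRING_PERIOD_S,
) -> STDPResult:
    """Run the pairing protocol on ``n_synapses`` independent synapses.

    Conditions are compared at matched ``seed`` so that the Wiener increments
    of each synapse are identical across conditions and differences reflect
    the deterministic plasticity signal alone.  Default reward delay 0.6 s
    places the pulse inside the pairing window, near the optimum of the
    delay dependence.
    """
    cfg = cfg if cfg is not None else LearningConfig()
    prior = prior if prior is not None else PriorSpec()
    rng = np.random.default_rng(seed)
    n_ms = int(round(duration_s * 1000))
    dt = cfg.dt

    pre, post, reward = _protocol_events(with_pre, delay_reward_s, n_ms)
    if not with_reward:
        reward[:] = 0.0

    # presynaptic PSP trace shared by all synapses (1-ms transmission delay)
    kernel = psp_kernel(np.arange(1, n_ms + 1) * dt)
    y = np.convolve(pre, kernel)[:n_ms]
    y = np.concatenate([[0.0], y[:-1]])  # delay

    # postsynaptic intensity: exponential escape at the clamped potential,
    # silenced for t_ref after each scripted spike
    t_ref_ms = 5
    f = np.full(n_ms, np.exp(CLAMPED_U))
    spike_t = np.nonzero(post)[0]
    for t in spike_t:
        f[t + 1 : t + 1 + t_ref_ms] = 0.0

    theta = np.full(n_synapses, float(theta_init))
    w = np.asarray(weight_from_theta(theta, cfg.theta0))
    e = np.zeros(n_synapses)
    g = np.zeros(n_synapses)
    r_hat = cfg.rhat_floor

    window_ms = int(round(cfg.theta_update_interval / dt))
    n_windows = n_ms // window_ms
    w_series = np.empty((n_synapses, n_windows + 1))
    w_series[:, 0] = w
    times = np.arange(n_windows + 1) * cfg.theta_update_interval

    for t in range(n_ms):
        e = eligibility_step(e, w, y[t], post[t], f[t], dt, cfg.tau_e)
        r_hat = reward_baseline_step(r_hat, reward[t], dt, cfg.tau_a, cfg.rhat_floor)
        g = gradient_trace_step(g, e, reward[t], r_hat, cfg, dt)
        if (t + 1) % window_ms == 0:
            drift = prior.log_gradient(theta) + g
            noise = rng.standard_normal(n_synapses)
            theta = np.asarray(theta_sde_step(theta, drift, cfg, noise))
            w = np.asarray(weight_from_theta(theta, cfg.theta0))
            w_series[:, (t + 1) // window_ms] = w

    w0 = w_series[:, :1]
    pct = 100.0 * (w_series - w0) / w0
    return STDPResult(
        times_s=times,
        mean_pct=pct.mean(axis=0),
        sem_pct=pct.std(axis=0, ddof=1) / np.sqrt(n_synapses),
        w=w_series,
        theta=theta,
    )
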