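"""Shared fixtures: a tiny scaffold and a plain per-ms reference integrator.

The reference integrator advances every synapse's eligibility and gradient
trace individually on the 1-ms grid, with none of the pair-aggregation used
by the production kernel.  Feeding both the same externally drawn random
numbers makes them comparable trajectory-by-trajectory.
"""

from __future__ import annotations

import numpy as np
import pytest

from synsample.dynamics import LearningConfig, PriorSpec, weight_from_theta
from synsample.network import NetworkScaffold

U_CAP = 6.0  # membrane-potential cap used by the simulation kernel


@pytest.fixture
def tiny_scaffold() -> NetworkScaffold:
    """4 Poisson inputs, 3 network neurons (2 plastic targets, 1 inhibitory)."""
    n_in, n_net = 4, 3
    n_src = n_in + n_net
    pre = np.array([0, 0, 1, 2, 3, 4, 5, 0])  # includes a duplicate (0 -> 0) pair
    post = np.array([0, 1, 0, 1, 0, 1, 0, 0])
    w_fixed = np.zeros((n_src, n_net))
    w_fixed[n_in + 2, 0] = -0.8  # fixed inhibition onto neuron 0
    w_fixed[n_in + 0, 2] = 0.5  # fixed excitation onto the inhibitory neuron
    tau_m = np.full(n_src, 0.020)
    tau_r = np.full(n_src, 0.002)
    tau_m[n_in + 2] = 0.010
    tau_r[n_in + 2] = 0.001
    t_ref = np.array([0.005, 0.005, 0.002])
    return NetworkScaffold(
        n_inputs=n_in,
        n_net=n_net,
        n_plastic_post=2,
        tags=["input"] * n_in + ["excitatory", "excitatory", "inhibitory"],
        src_tau_m=tau_m,
        src_tau_r=tau_r,
        t_ref=t_ref,
        pre=pre,
        post=post,
        w_fixed=w_fixed,
        pools={"A": np.array([0]), "B": np.array([1])},
    )


class ScriptedRewardTask:
    """Deterministic rates and reward schedule for equivalence tests."""

    def __init__(self, rate_hz: float = 15.0, chunk_ms: int = 10):
        self.rate_hz = rate_hz
        self.chunk_ms = chunk_ms

    def reset(self, rng, scaffold):
        self._rates = np.full(scaffold.n_inputs, self.rate_hz)

    def input_rates(self, t_ms):
        return self._rates, 0

    def reward(self, t_ms, chunk_counts):
        # deterministic, time-varying, independent of spikes
        return 0.25 + 0.2 * np.sin(t_ms / 300.0)


def reference_simulate(
    scaffold: NetworkScaffold,
    task,
    cfg: LearningConfig,
    duration_s: float,
    theta_init: np.ndarray,
    uni_in: np.ndarray,
    uni_net: np.ndarray,
    noise: np.ndarray,
    prior: PriorSpec | None = None,
):
    """Per-ms per-synapse integration of the full coupled dynamics."""
    prior = prior or PriorSpec()
    dt = cfg.dt
    n_in, n_net, n_src = scaffold.n_inputs, scaffold.n_net, scaffold.n_src
    n_pp = scaffold.n_plastic_post
    K = scaffold.n_synapses
    theta = theta_init.copy()
    w = np.asarray(weight_from_theta(theta, cfg.theta0))
    e = np.zeros(K)
    g = np.zeros(K)
    vartheta = np.full(n_net, -3.0)
    rho = np.full(n_net, 1_000_000, dtype=np.int64)
    tref = np.rint(scaffold.t_ref / dt).astype(np.int64)
    yA = np.zeros(n_src)
    yB = np.zeros(n_src)
    dm = np.exp(-dt / scaffold.src_tau_m)
    dr = np.exp(-dt / scaffold.src_tau_r)
    coef = scaffold.src_tau_m / (scaffold.src_tau_m - scaffold.src_tau_r)
    ke = 1.0 - dt / cfg.tau_e
    kg = 1.0 - dt / cfg.tau_g

    w_fix = scaffold.w_fixed
    pre, post = scaffold.pre, scaffold.post
    chunk = task.chunk_ms
    n_ms = int(duration_s * 1000)
    window_ms = int(round(cfg.theta_update_interval / dt))
    task.reset(np.random.default_rng(0), scaffold)
    rates, _ = task.input_rates(0)
    r = 0.0
    rhat = cfg.rhat_floor
    chunk_counts = np.zeros(n_net, dtype=np.int64)
    thetas, spikes = [], []
    window = 0

    for t in range(n_ms):
        if t % chunk == 0 and t > 0:
            r = float(task.reward(t, chunk_counts))
            chunk_counts[:] = 0
            rates, _ = task.input_rates(t)
        y = coef * (yA - yB)
        w_pairs = np.zeros((n_src, n_pp))
        np.add.at(w_pairs, (pre, post), w)
        u = vartheta + y @ (w_fix + np.pad(w_pairs, ((0, 0), (0, n_net - n_pp))))
        u = np.minimum(u, U_CAP)
        f = np.where(rho >= tref, np.exp(u), 0.0)
        p = -np.expm1(-f * dt)
        z_net = (uni_net[t] < p).astype(np.int64)
        rho = np.where(z_net == 1, 0, rho + 1)
        vartheta = vartheta + dt * scaffold.nu_0 / scaffold.tau_theta - z_net / scaffold.tau_theta
        chunk_counts += z_net
        p_in = -np.expm1(-rates * dt)
        z_in = (uni_in[t] < p_in).astype(np.int64)

        rhat = max(rhat + dt / cfg.tau_a * (r - rhat), cfg.rhat_floor)
        c = cfg.c_r * (r / rhat + cfg.alpha)
        zf = z_net[:n_pp] - f[:n_pp] * dt
        e = e * ke + w * y[pre] * zf[post]
        g = g * kg + dt * c * e

        yA *= dm
        yB *= dr
        yA[:n_in] += z_in
        yB[:n_in] += z_in
        yA[n_in:] += z_net
        yB[n_in:] += z_net
        spikes.append(z_net.copy())

        if (t + 1) % window_ms == 0:
            drift = prior.log_gradient(theta) + g
            dtheta = cfg.beta * drift * cfg.theta_update_interval
            dtheta = dtheta + np.sqrt(
                2 * cfg.beta * cfg.temperature * cfg.theta_update_interval
            ) * noise[window]
            if cfg.clip is not None:
                dtheta = np.clip(dtheta, -cfg.clip, cfg.clip)
            theta = theta + dtheta
            if cfg.theta_bounds is not None:
                theta = np.clip(theta, *cfg.theta_bounds)
            w = np.asarray(weight_from_theta(theta, cfg.theta0))
            thetas.append(theta.copy())
            window += 1

    return {
        "theta": theta,
        "theta_series": np.array(thetas),
        "e": e,
        "g": g,
        "spikes": np.array(spikes),
    }
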