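"""Numba-compiled inner loops of the network simulation.

The simulation advances on a fixed 1-ms grid.  Synaptic parameters (and thus
weights) only change at the 100-ms parameter updates, so within a window the
per-synapse eligibility and gradient traces

    e_i <- e_i * (1 - dt/tau_e) + w_i * y_pre(i) * (z_post(i) - f_post(i) dt)
    g_i <- g_i * (1 - dt/tau_g) + dt * c(t) * e_i

are linear in the window-start state ``(e_i, g_i)`` and in ``w_i``, with a
drive shared by all synapses of the same (pre, post) pair.  The kernel
therefore integrates *pair-level* accumulators ``ehat``/``ghat`` (unit-weight
eligibility/gradient responses) and two scalar chains per ms, and the driver
scatters them back to the per-synapse traces once per window:

    e_i(t1) = e_i(t0) * s_e            + w_i * ehat[pre, post]
    g_i(t1) = g_i(t0) * (1-dt/tau_g)^n + e_i(t0) * s_eg + w_i * ghat[pre, post]

which reproduces the per-ms per-synapse recursion exactly (up to float
associativity); see tests for the equivalence check against a plain
reference integrator.

Spiking randomness uses numba's internal RNG (seeded once per run through
``seed_rng``); the parameter-update Wiener increments are drawn by the driver
from a separate numpy Generator so that retracted-synapse trajectories do not
depend on network activity.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def advance_chunk(
    n_ms,
    t0_ms,
    rates_in,  # (n_in,) input rates in Hz, constant over the chunk
    yA,
    yB,  # (n_src,) PSP exponential states
    dm,
    dr,
    coef,  # (n_src,) per-source kernel decay factors / prefactor
    Wtot,  # (n_src, n_net) total weight matrix (fixed + plastic sums)
    vartheta,  # (n_net,) bias potentials
    rho_ms,  # (n_net,) int64 ms since last spike
    tref_ms,  # (n_net,) int64 refractory period in ms
    nu0_dt_over_tau,  # scalar: nu_0 * dt / tau_theta
    inv_tau_theta,  # scalar: 1 / tau_theta
    ehat,
    ghat,  # (n_src, n_pp) pair-level trace accumulators
    ke,
    kg,  # scalars: 1 - dt/tau_e, 1 - dt/tau_g
    r,  # scalar reward, constant over the chunk
    rhat,  # scalar reward baseline at chunk start
    ka_dt,  # dt / tau_a
    rhat_floor,
    cr,
    alpha,
    se_sg,  # (2,) scalar chains [s_e, s_eg]
    dt,  # 1e-3
    chunk_counts,  # (n_net,) int64, spike counts of this chunk (reset here)
    use_ext_uniforms,
    uni_in,  # (n_ms, n_in) external uniforms (tests) or (1,1) dummy
    uni_net,  # (n_ms, n_net)
    record_spikes,
    ev_t,
    ev_id,  # int64 event buffers
    rec_lever,
    lever_state,  # (2,) exponential states of the lever readout filter
    lever_dm,
    lever_dr,
    lever_coef,
    lever_sign,  # (n_net,) +1 for pool U, -1 for pool D, 0 otherwise
    lever_trace,  # (n_ms,) output, per-ms lever position
):
    n_src = yA.shape[0]
    n_net = vartheta.shape[0]
    n_pp = ehat.shape[1]
    n_in = rates_in.shape[0]

    y = np.empty(n_src)
    f = np.empty(n_net)
    zf = np.empty(n_pp)
    p_in = np.empty(n_in)
    for s in range(n_in):
        p_in[s] = -np.expm1(-rates_in[s] * dt)

    for k in range(n_net):
        chunk_counts[k] = 0
    ev_n = 0

    for m in range(n_ms):
        # PSP trace values; spikes of this ms enter the traces at the end of
        # the loop body, which realizes the 1-ms synaptic delay.
        for s in range(n_src):
            y[s] = coef[s] * (yA[s] - yB[s])

        # membrane potentials and escape intensities; u is capped so that the
        # intensity stays finite if a configuration transiently overdrives a
        # neuron (the refractory period bounds realized rates anyway)
        for k in range(n_net):
            acc = vartheta[k]
            for s in range(n_src):
                acc += Wtot[s, k] * y[s]
            if acc > 6.0:
                acc = 6.0
            if rho_ms[k] >= tref_ms[k]:
                f[k] = np.exp(acc)
            else:
                f[k] = 0.0

        # network spikes, refractoriness, bias adaptation
        lever_impulse = 0.0
        for k in range(n_net):
            p = -np.expm1(-f[k] * dt)
            if use_ext_uniforms:
                un = uni_net[m, k]
            else:
                un = np.random.random()
            if un < p:
                z = 1
                rho_ms[k] = 0
                chunk_counts[k] += 1
                if record_spikes:
                    ev_t[ev_n] = t0_ms + m
                    ev_id[ev_n] = n_in + k
                    ev_n += 1
                if rec_lever:
                    lever_impulse += lever_sign[k]
            else:
                z = 0
                rho_ms[k] += 1
            vartheta[k] += nu0_dt_over_tau - z * inv_tau_theta
        for k in range(n_pp):
            if rho_ms[k] == 0:  # spiked this ms
                zf[k] = 1.0 - f[k] * dt
            else:
                zf[k] = -f[k] * dt

        # reward baseline and modulation factor for this ms
        rhat = rhat + ka_dt * (r - rhat)
        if rhat < rhat_floor:
            rhat = rhat_floor
        c = cr * (r / rhat + alpha)
        dtc = dt * c

        # pair-level eligibility / gradient accumulators
        for s in range(n_src):
            ys = y[s]
            for k in range(n_pp):
                eh = ehat[s, k] * ke + ys * zf[k]
                ehat[s, k] = eh
                ghat[s, k] = ghat[s, k] * kg + dtc * eh
        se_sg[0] *= ke
        se_sg[1] = se_sg[1] * kg + dtc * se_sg[0]

        # lever readout (same double-exponential filter as the PSP kernel)
        if rec_lever:
            lever_state[0] = lever_state[0] * lever_dm + lever_impulse
            lever_state[1] = lever_state[1] * lever_dr + lever_impulse
            lever_trace[m] = lever_coef * (lever_state[0] - lever_state[1])

        # advance PSP traces and inject this ms's spikes
        for s in range(n_src):
            yA[s] *= dm[s]
            yB[s] *= dr[s]
        for s in range(n_in):
            if use_ext_uniforms:
                ui = uni_in[m, s]
            else:
                ui = np.random.random()
            if ui < p_in[s]:
                yA[s] += 1.0
                yB[s] += 1.0
                if record_spikes:
                    ev_t[ev_n] = t0_ms + m
                    ev_id[ev_n] = s
                    ev_n += 1
        for k in range(n_net):
            if rho_ms[k] == 0:
                yA[n_in + k] += 1.0
                yB[n_in + k] += 1.0

    return rhat, ev_n


@njit(cache=True)
def scatter_window(e, g, e0, w, pre, post, ehat, ghat, s_e, s_eg, g_decay):
    """Fold the pair-level window accumulators back into per-synapse traces."""
    n_pp = ehat.shape[1]
    for i in range(e.shape[0]):
        ph_e = ehat[pre[i], post[i]]
        ph_g = ghat[pre[i], post[i]]
        e[i] = e0[i] * s_e + w[i] * ph_e
        g[i] = g[i] * g_decay + e0[i] * s_eg + w[i] * ph_g


@njit(cache=True)
def accumulate_pair_weights(w, pre, post, out):
    """Sum plastic synapse weights into the (n_src, n_pp) pair matrix."""
    out[:] = 0.0
    for i in range(w.shape[0]):
        out[pre[i], post[i]] += w[i]
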