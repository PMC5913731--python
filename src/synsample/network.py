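"""Network scaffold and the master simulation loop.

A :class:`NetworkScaffold` is the fixed part of a model: the neuron
populations, the list of *potential* plastic synapses (pre, post, 1-ms
delay; several potential synapses may connect the same pair of neurons) and
the fixed (inhibitory and excitatory-to-inhibitory) wiring.  A parameter
vector ``theta`` over the potential synapses then defines a concrete network
configuration.

:func:`simulate` couples the scaffold with a task (stimulus generation and
reward computation), integrates the neuron and synapse dynamics on a 1-ms
grid with parameter updates every 100 ms, and returns a
:class:`RecordingBuffer`.  Runs are bit-reproducible given (scaffold, task
config, master seed): the master seed fans out to named child streams for
parameter initialization, stimulus generation, spiking and plasticity noise,
and the plasticity-noise stream is consumed one draw per potential synapse
per update regardless of network activity, so retracted synapses follow the
same trajectory whether or not the network is stimulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Tuple

import numpy as np

from . import _kernels
from .dynamics import (
    LearningConfig,
    PriorSpec,
    SynapseState,
    consolidate,
    sample_reactivation_time,
    theta_sde_step,
    weight_from_theta,
)

#: default initialization of synaptic parameters: N(-0.5, 0.5^2)
THETA_INIT_MEAN = -0.5
THETA_INIT_STD = 0.5


@dataclass
class NetworkScaffold:
    """Fixed structure of a model network.

    Sources are indexed ``0 .. n_inputs-1`` (Poisson input generators)
    followed by the network neurons; network neurons are ordered so that the
    plastic targets (excitatory neurons) come first.
    """

    n_inputs: int
    n_net: int
    n_plastic_post: int  # leading network neurons that receive plastic synapses
    tags: List[str]  # population tag per source (inputs + network neurons)
    src_tau_m: np.ndarray  # outgoing PSP kernel constants per source (s)
    src_tau_r: np.ndarray
    t_ref: np.ndarray  # per network neuron (s)
    pre: np.ndarray  # (K_syn,) source index of each potential synapse
    post: np.ndarray  # (K_syn,) network-local index (< n_plastic_post)
    w_fixed: np.ndarray  # (n_src, n_net) fixed signed weights
    pools: Dict[str, np.ndarray] = field(default_factory=dict)  # net-local indices
    nu_0: float = 5.0
    tau_theta: float = 50.0

    def __post_init__(self) -> None:
        self.pre = np.ascontiguousarray(self.pre, dtype=np.int64)
        self.post = np.ascontiguousarray(self.post, dtype=np.int64)
        self.src_tau_m = np.asarray(self.src_tau_m, dtype=float)
        self.src_tau_r = np.asarray(self.src_tau_r, dtype=float)
        self.t_ref = np.asarray(self.t_ref, dtype=float)
        self.w_fixed = np.ascontiguousarray(self.w_fixed, dtype=float)
        if self.w_fixed.shape != (self.n_src, self.n_net):
            raise ValueError("w_fixed must have shape (n_src, n_net)")
        if self.post.size and self.post.max() >= self.n_plastic_post:
            raise ValueError("plastic synapse targets a non-plastic neuron")

    @property
    def n_src(self) -> int:
        return self.n_inputs + self.n_net

    @property
    def n_synapses(self) -> int:
        return self.pre.shape[0]

    def synapse_table(self) -> np.ndarray:
        """(K_syn, 2) array of (pre, post) with post as global neuron index."""
        return np.column_stack([self.pre, self.post + self.n_inputs])


class Task(Protocol):
    """Stimulus/reward interface consumed by :func:`simulate`.

    ``chunk_ms`` sets the reward-recomputation grid.  Per chunk the driver
    calls :meth:`input_rates` for the rate vector to apply and, after the
    chunk has been simulated, :meth:`reward` with the per-neuron spike counts
    of the chunk; the returned reward is applied during the next chunk.
    """

    chunk_ms: int

    def reset(self, rng: np.random.Generator, scaffold: NetworkScaffold) -> None: ...

    def input_rates(self, t_ms: int) -> Tuple[np.ndarray, int]:
        """Return (rates in Hz, integer phase label) for the coming chunk."""
        ...

    def reward(self, t_ms: int, chunk_counts: np.ndarray) -> float: ...


class BackgroundTask:
    """Constant-rate inputs, zero reward; used for controls and tests."""

    def __init__(self, rate_hz: float = 2.0, chunk_ms: int = 10):
        self.rate_hz = rate_hz
        self.chunk_ms = chunk_ms
        self._rates: Optional[np.ndarray] = None

    def reset(self, rng, scaffold) -> None:
        self._rates = np.full(scaffold.n_inputs, self.rate_hz, dtype=float)

    def input_rates(self, t_ms):
        return self._rates, 0

    def reward(self, t_ms, chunk_counts) -> float:
        return 0.0


@dataclass
class RecorderConfig:
    """What :func:`simulate` stores.

    Full spike events scale with duration; for multi-hour runs keep
    ``record_spikes`` off and rely on the per-second rate counters.
    """

    record_spikes: bool = False
    record_input_spikes: bool = True  # only honoured when record_spikes is set
    record_reward: bool = True
    record_rates: bool = True  # per-second per-network-neuron spike counts
    record_lever: bool = False  # per-ms lever trace (lever task)
    snapshot_interval_s: Optional[float] = None  # theta snapshots


@dataclass
class RecordingBuffer:
    """Time-stamped events and periodic snapshots of one run."""

    duration_s: float
    seed: int
    spike_times_ms: np.ndarray
    spike_neuron: np.ndarray
    reward_t_ms: np.ndarray
    reward: np.ndarray
    phase: np.ndarray  # task phase label per reward sample
    rate_counts: Optional[np.ndarray]  # (n_net, n_seconds) spike counts
    snapshot_times_s: np.ndarray
    snapshots: np.ndarray  # (n_snapshots, K_syn) theta values
    lever: Optional[np.ndarray]  # per-ms lever trace
    trials: List[dict] = field(default_factory=list)
    final_state: Optional[SynapseState] = None
    theta_init: Optional[np.ndarray] = None
    rhat_final: float = 0.0


def _child_seeds(seed: int) -> Dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("init", "stimulus", "spiking", "plasticity")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def simulate(
    scaffold: NetworkScaffold,
    task: Task,
    cfg: LearningConfig,
    duration_s: float,
    seed: int,
    prior: Optional[PriorSpec] = None,
    recorders: Optional[RecorderConfig] = None,
    theta_init: Optional[np.ndarray] = None,
    rewiring_off_after_s: Optional[float] = None,
    consolidate_at_s: Optional[float] = None,
    _ext_uniforms: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    _ext_noise: Optional[np.ndarray] = None,
) -> RecordingBuffer:
    """Run the coupled neuron/synapse dynamics for ``duration_s`` seconds.

    ``rewiring_off_after_s`` forbids theta sign changes from that time on;
    ``consolidate_at_s`` re-anchors the Gaussian prior at the current
    parameters.  ``_ext_uniforms``/``_ext_noise`` feed externally drawn
    random numbers to the kernel (testing hook for the reference-integrator
    equivalence check).
    """
    prior = prior if prior is not None else PriorSpec()
    rec = recorders if recorders is not None else RecorderConfig()
    seeds = _child_seeds(seed)
    rng_init = np.random.default_rng(seeds["init"])
    rng_stim = np.random.default_rng(seeds["stimulus"])
    rng_plast = np.random.default_rng(seeds["plasticity"])
    _kernels.seed_rng(seeds["spiking"])

    n_in, n_net, n_src = scaffold.n_inputs, scaffold.n_net, scaffold.n_src
    n_pp = scaffold.n_plastic_post
    K = scaffold.n_synapses
    dt = cfg.dt
    dt_ms = dt * 1000.0
    if abs(dt_ms - 1.0) > 1e-9:
        raise ValueError("the simulation kernel runs on a 1-ms grid")

    # synapse state
    if theta_init is None:
        theta = rng_init.normal(THETA_INIT_MEAN, THETA_INIT_STD, size=K)
    else:
        theta = np.array(theta_init, dtype=float, copy=True)
    syn = SynapseState(theta=theta, theta0=cfg.theta0)
    theta_start = syn.theta.copy()
    w = np.asarray(weight_from_theta(syn.theta, cfg.theta0))

    # neuron state
    vartheta = np.full(n_net, -3.0)
    rho_ms = np.full(n_net, 1_000_000, dtype=np.int64)
    tref_ms = np.rint(scaffold.t_ref / dt).astype(np.int64)
    yA = np.zeros(n_src)
    yB = np.zeros(n_src)
    dm = np.exp(-dt / scaffold.src_tau_m)
    dr = np.exp(-dt / scaffold.src_tau_r)
    coef = scaffold.src_tau_m / (scaffold.src_tau_m - scaffold.src_tau_r)

    # pair-level accumulators and weight matrix
    ehat = np.zeros((n_src, n_pp))
    ghat = np.zeros((n_src, n_pp))
    se_sg = np.array([1.0, 0.0])
    w_pairs = np.zeros((n_src, n_pp))
    _kernels.accumulate_pair_weights(w, scaffold.pre, scaffold.post, w_pairs)
    Wtot = scaffold.w_fixed.copy()
    Wtot[:, :n_pp] += w_pairs

    ke = 1.0 - dt / cfg.tau_e
    kg = 1.0 - dt / cfg.tau_g
    ka_dt = dt / cfg.tau_a

    chunk_ms = int(task.chunk_ms)
    window_ms = int(round(cfg.theta_update_interval / dt))
    if window_ms % chunk_ms != 0:
        raise ValueError("theta_update_interval must be a multiple of the task chunk")
    n_chunks = int(np.floor(duration_s * 1000.0 + 1e-9)) // chunk_ms

    task.reset(rng_stim, scaffold)

    # recording setup
    ev_cap = chunk_ms * (n_net + n_in) if rec.record_spikes else 1
    ev_t = np.zeros(ev_cap, dtype=np.int64)
    ev_id = np.zeros(ev_cap, dtype=np.int64)
    spike_t_acc: List[np.ndarray] = []
    spike_id_acc: List[np.ndarray] = []
    reward_trace = np.zeros(n_chunks) if rec.record_reward else None
    phase_trace = np.zeros(n_chunks, dtype=np.int64) if rec.record_reward else None
    n_seconds = int(np.ceil(n_chunks * chunk_ms / 1000.0))
    rate_counts = (
        np.zeros((n_net, max(n_seconds, 1)), dtype=np.int64)
        if rec.record_rates
        else None
    )
    lever_acc: List[np.ndarray] = []
    lever_state = np.zeros(2)
    lever_sign = np.zeros(n_net)
    lever_dm = lever_dr = lever_coef = 0.0
    if rec.record_lever:
        sign, tau_m_l, tau_r_l = getattr(task, "lever_readout")()
        lever_sign = np.asarray(sign, dtype=float)
        lever_dm = float(np.exp(-dt / tau_m_l))
        lever_dr = float(np.exp(-dt / tau_r_l))
        lever_coef = tau_m_l / (tau_m_l - tau_r_l)
    snap_times: List[float] = []
    snaps: List[np.ndarray] = []
    snap_every = (
        None
        if rec.snapshot_interval_s is None
        else max(1, int(round(rec.snapshot_interval_s * 1000.0 / window_ms)))
    )

    # rewiring bookkeeping
    approx = cfg.rewiring == "approximate"
    frozen = syn.theta <= 0.0 if approx else None
    react_clock = None
    if approx:
        react_clock = np.where(
            frozen,
            sample_reactivation_time(rng_plast, cfg.reactivation_mean, size=K),
            np.inf,
        )
    no_rewiring_now = cfg.rewiring == "disabled"

    use_ext = _ext_uniforms is not None
    dummy = np.zeros((1, 1))
    uni_in_all, uni_net_all = (_ext_uniforms if use_ext else (dummy, dummy))

    chunk_counts = np.zeros(n_net, dtype=np.int64)
    r = 0.0
    rhat = cfg.rhat_floor
    e0 = np.zeros(K)
    window_chunks = window_ms // chunk_ms
    windows_done = 0
    dummy_lever = np.zeros(1)

    for ci in range(n_chunks):
        t_ms = ci * chunk_ms
        rates, phase = task.input_rates(t_ms)
        if use_ext:
            sl = slice(t_ms, t_ms + chunk_ms)
            uni_in = np.ascontiguousarray(uni_in_all[sl])
            uni_net = np.ascontiguousarray(uni_net_all[sl])
        else:
            uni_in, uni_net = dummy, dummy
        lever_out = np.zeros(chunk_ms) if rec.record_lever else dummy_lever
        rhat, ev_n = _kernels.advance_chunk(
            chunk_ms,
            t_ms,
            np.ascontiguousarray(rates, dtype=float),
            yA,
            yB,
            dm,
            dr,
            coef,
            Wtot,
            vartheta,
            rho_ms,
            tref_ms,
            scaffold.nu_0 * dt / scaffold.tau_theta,
            1.0 / scaffold.tau_theta,
            ehat,
            ghat,
            ke,
            kg,
            r,
            rhat,
            ka_dt,
            cfg.rhat_floor,
            cfg.c_r,
            cfg.alpha,
            se_sg,
            dt,
            chunk_counts,
            use_ext,
            uni_in,
            uni_net,
            rec.record_spikes,
            ev_t,
            ev_id,
            rec.record_lever,
            lever_state,
            lever_dm,
            lever_dr,
            lever_coef,
            lever_sign,
            lever_out,
        )
        if rec.record_spikes and ev_n:
            keep = slice(0, ev_n)
            if rec.record_input_spikes:
                spike_t_acc.append(ev_t[keep].copy())
                spike_id_acc.append(ev_id[keep].copy())
            else:
                mask = ev_id[keep] >= n_in
                spike_t_acc.append(ev_t[keep][mask])
                spike_id_acc.append(ev_id[keep][mask])
        if rec.record_lever:
            lever_acc.append(lever_out)
        if rate_counts is not None:
            rate_counts[:, t_ms // 1000] += chunk_counts
        r = float(task.reward(t_ms + chunk_ms, chunk_counts))
        if reward_trace is not None:
            reward_trace[ci] = r
            phase_trace[ci] = phase

        # parameter update at window boundaries
        if (ci + 1) % window_chunks == 0:
            e0[:] = syn.e
            _kernels.scatter_window(
                syn.e,
                syn.g,
                e0,
                w,
                scaffold.pre,
                scaffold.post,
                ehat,
                ghat,
                se_sg[0],
                se_sg[1],
                kg**window_ms,
            )
            ehat[:] = 0.0
            ghat[:] = 0.0
            se_sg[0] = 1.0
            se_sg[1] = 0.0

            t_s = (t_ms + chunk_ms) / 1000.0
            if consolidate_at_s is not None and t_s >= consolidate_at_s:
                prior = consolidate(prior, syn.theta)
                consolidate_at_s = None
            if rewiring_off_after_s is not None and t_s >= rewiring_off_after_s:
                no_rewiring_now = True

            noise = (
                _ext_noise[windows_done]
                if _ext_noise is not None
                else rng_plast.standard_normal(K)
            )
            drift = prior.log_gradient(syn.theta) + syn.g
            new_theta = np.asarray(theta_sde_step(syn.theta, drift, cfg, noise))
            if no_rewiring_now:
                was_on = syn.theta > 0.0
                new_theta = np.where(
                    was_on, np.maximum(new_theta, 1e-10), np.minimum(new_theta, 0.0)
                )
            if approx:
                # frozen retracted synapses keep their parameter until the
                # exponential waiting time elapses
                new_theta = np.where(frozen, syn.theta, new_theta)
                react_clock -= cfg.theta_update_interval
                wake = frozen & (react_clock <= 0.0)
                if np.any(wake):
                    new_theta[wake] = 1e-5
                    syn.e[wake] = 0.0
                    syn.g[wake] = 0.0
                    frozen[wake] = False
                newly_off = (~frozen) & (new_theta <= 0.0)
                if np.any(newly_off):
                    frozen |= newly_off
                    react_clock[newly_off] = sample_reactivation_time(
                        rng_plast, cfg.reactivation_mean, size=int(newly_off.sum())
                    )
            syn.theta[:] = new_theta
            w = np.asarray(weight_from_theta(syn.theta, cfg.theta0))
            _kernels.accumulate_pair_weights(w, scaffold.pre, scaffold.post, w_pairs)
            Wtot[:, :n_pp] = scaffold.w_fixed[:, :n_pp] + w_pairs
            windows_done += 1
            if snap_every is not None and windows_done % snap_every == 0:
                snap_times.append(t_s)
                snaps.append(syn.theta.copy())

        if not np.isfinite(rhat):
            raise FloatingPointError(
                f"non-finite reward baseline at t={t_ms} ms; aborting"
            )

    if not (np.all(np.isfinite(syn.theta)) and np.all(np.isfinite(vartheta))):
        raise FloatingPointError("non-finite network state at end of run")

    spikes_t = (
        np.concatenate(spike_t_acc) if spike_t_acc else np.zeros(0, dtype=np.int64)
    )
    spikes_id = (
        np.concatenate(spike_id_acc) if spike_id_acc else np.zeros(0, dtype=np.int64)
    )
    return RecordingBuffer(
        duration_s=n_chunks * chunk_ms / 1000.0,
        seed=seed,
        spike_times_ms=spikes_t,
        spike_neuron=spikes_id,
        reward_t_ms=(
            np.arange(n_chunks, dtype=np.int64) * chunk_ms + chunk_ms
            if reward_trace is not None
            else np.zeros(0, dtype=np.int64)
        ),
        reward=reward_trace if reward_trace is not None else np.zeros(0),
        phase=phase_trace if phase_trace is not None else np.zeros(0, dtype=np.int64),
        rate_counts=rate_counts,
        snapshot_times_s=np.asarray(snap_times),
        snapshots=(
            np.asarray(snaps) if snaps else np.zeros((0, K))
        ),
        lever=np.concatenate(lever_acc) if lever_acc else None,
        trials=list(getattr(task, "trials", [])),
        final_state=syn,
        theta_init=theta_start,
        rhat_final=float(rhat),
    )
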