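"""Synapse-level dynamics for reward-based synaptic sampling.

Each potential synaptic connection ``i`` carries a real-valued parameter
``theta_i``.  The connection is functional with efficacy
``w_i = exp(theta_i - theta0)`` when ``theta_i > 0`` and retracted
(``w_i = 0``) otherwise.  The parameters evolve by a Langevin-type
stochastic differential equation

    d theta_i = beta * (d/dtheta_i log p_S(theta)  +  g_i(t)) dt
                + sqrt(2 beta T) dW_i ,

where ``p_S`` is a structural prior, ``g_i`` is an online estimate of the
gradient of the log expected discounted reward, ``T`` is a temperature and
``W_i`` a Wiener process.  Its stationary distribution is proportional to
``(prior x expected reward)^(1/T)``, so the network *samples* well-rewarded
configurations instead of converging to one.

The reward gradient is estimated from two synapse-local traces:

* an eligibility trace ``e_i`` integrating the STDP-like coincidence signal
  ``w_i * y_pre * (z_post - f_post dt)`` with time constant ``tau_e``;
* a gradient trace ``g_i`` integrating ``c_r (r/r_hat + alpha) * e_i`` with
  time constant ``tau_g``, where ``r_hat`` is a slow running average of the
  reward ``r``.

All functions operate elementwise on scalars or numpy arrays.  Time is in
seconds throughout; the traces are integrated with the forward Euler scheme
on a 1-ms grid and the parameter SDE with Euler-Maruyama at the (slower)
parameter-update interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

#: twelve hours, the mean waiting time for the approximate rewiring variant
DEFAULT_REACTIVATION_MEAN_S = 12.0 * 3600.0


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------


@dataclass
class PriorSpec:
    """Structural prior over synaptic parameters.

    Parameters
    ----------
    family:
        ``"gaussian"`` (mean ``mu``, std ``sigma``) or ``"laplace"``
        (zero-mode scale ``b``).
    mu:
        Prior mean; a scalar, or a per-synapse vector after consolidation.
    sigma:
        Standard deviation of the Gaussian prior (> 0).
    b:
        Scale of the Laplace prior (> 0).
    """

    family: str = "gaussian"
    mu: ArrayLike = 0.0
    sigma: float = 2.0
    b: float = 2.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "laplace"):
            raise ValueError(f"unknown prior family: {self.family!r}")
        if self.family == "gaussian" and not self.sigma > 0:
            raise ValueError("gaussian prior requires sigma > 0")
        if self.family == "laplace" and not self.b > 0:
            raise ValueError("laplace prior requires b > 0")

    def log_gradient(self, theta: ArrayLike) -> np.ndarray:
        return prior_log_gradient(theta, self)


@dataclass
class LearningConfig:
    """Parameters of the synapse model and of its numerical integration.

    Defaults are the reference values of the model: learning rate
    ``beta = 1e-5 / s``, temperature ``T = 0.1``, eligibility time constant
    ``tau_e = 1 s``, gradient-trace time constant ``tau_g = 50 s``,
    reward-baseline time constant ``tau_a = 50 s``, reward offset
    ``alpha = 0.02``, reward scaling ``c_r = 1``, weight-mapping offset
    ``theta0 = 3``.  The simulation step is ``dt = 1 ms``; the parameter SDE
    is advanced every ``theta_update_interval = 100 ms`` with per-update
    changes clipped at ``+-4e-4`` and parameters confined to ``[-2, 5]``.
    """

    beta: float = 1e-5
    temperature: float = 0.1
    tau_e: float = 1.0
    tau_g: float = 50.0
    tau_a: float = 50.0
    alpha: float = 0.02
    c_r: float = 1.0
    theta0: float = 3.0
    dt: float = 1e-3
    theta_update_interval: float = 0.1
    clip: Optional[float] = 4e-4
    theta_bounds: Optional[Tuple[float, float]] = (-2.0, 5.0)
    rhat_floor: float = 1e-4
    #: retracted-synapse dynamics: "exact" evolves theta <= 0 by prior+noise,
    #: "approximate" freezes it and redraws a functional state after an
    #: exponential waiting time, "disabled" forbids any sign crossing.
    rewiring: str = "exact"
    reactivation_mean: float = DEFAULT_REACTIVATION_MEAN_S

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.beta < 0:
            raise ValueError("learning rate beta must be >= 0")
        for name in ("tau_e", "tau_g", "tau_a", "dt", "theta_update_interval"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.rewiring not in ("exact", "approximate", "disabled"):
            raise ValueError(f"unknown rewiring variant: {self.rewiring!r}")
        if self.theta_bounds is not None:
            lo, hi = self.theta_bounds
            if not lo < hi:
                raise ValueError("theta_bounds must be an increasing pair")


@dataclass
class RewardState:
    """Instantaneous reward and its slow running average."""

    r: float = 0.0
    r_hat: float = 0.0

    def __post_init__(self) -> None:
        self.r_hat = max(self.r_hat, 0.0)


@dataclass
class SynapseState:
    """Vector state of all potential synapses of a scaffold."""

    theta: np.ndarray
    theta0: float = 3.0
    e: np.ndarray = field(default=None)  # type: ignore[assignment]
    g: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.e is None:
            self.e = np.zeros_like(self.theta)
        if self.g is None:
            self.g = np.zeros_like(self.theta)

    @property
    def w(self) -> np.ndarray:
        return weight_from_theta(self.theta, self.theta0)

    @property
    def functional(self) -> np.ndarray:
        return self.theta > 0.0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def weight_from_theta(theta: ArrayLike, theta0: float = 3.0) -> ArrayLike:
    """Map a synaptic parameter to an efficacy.

    ``w = exp(theta - theta0)`` for ``theta > 0`` (functional connection) and
    ``w = 0`` otherwise (retracted potential connection).  The offset
    ``theta0`` sets the efficacy of a freshly formed synapse,
    ``exp(-theta0)`` just above threshold.
    """
    theta = np.asarray(theta, dtype=float)
    w = np.where(theta > 0.0, np.exp(theta - theta0), 0.0)
    return w if w.ndim else float(w)


def prior_log_gradient(theta: ArrayLike, prior: PriorSpec) -> ArrayLike:
    """Drift contributed by the structural prior, d/dtheta log p_S(theta).

    Gaussian: ``(mu - theta) / sigma^2``.  Laplace: ``-sign(theta)/b`` with
    the subgradient midpoint 0 at ``theta = 0``.
    """
    theta = np.asarray(theta, dtype=float)
    if prior.family == "gaussian":
        out = (np.asarray(prior.mu, dtype=float) - theta) / prior.sigma**2
    elif prior.family == "laplace":
        out = -np.sign(theta) / prior.b
    else:  # pragma: no cover - guarded in PriorSpec
        raise ValueError(f"unknown prior family: {prior.family!r}")
    return out if out.ndim else float(out)


def eligibility_step(
    e: ArrayLike,
    w: ArrayLike,
    y_pre: ArrayLike,
    z_post: ArrayLike,
    f_post: ArrayLike,
    dt: float = 1e-3,
    tau_e: float = 1.0,
) -> ArrayLike:
    """One Euler step of the eligibility trace.

    ``e <- e (1 - dt/tau_e) + w * y_pre * (z_post - f_post * dt)`` where
    ``z_post`` is the 0/1 spike indicator of the bin (the integrated spike
    train) and ``f_post`` the postsynaptic firing intensity in 1/s, so
    ``z_post - f_post*dt`` is zero-mean under the neuron model.  For a
    retracted synapse (``w = 0``) the drive vanishes and the trace decays.
    """
    e = np.asarray(e, dtype=float)
    drive = np.asarray(w, dtype=float) * np.asarray(y_pre, dtype=float) * (
        np.asarray(z_post, dtype=float) - np.asarray(f_post, dtype=float) * dt
    )
    out = e * (1.0 - dt / tau_e) + drive
    return out if out.ndim else float(out)


def reward_baseline_step(
    r_hat: float,
    r: float,
    dt: float = 1e-3,
    tau_a: float = 50.0,
    floor: float = 1e-4,
) -> float:
    """First-order low pass ``tau_a d r_hat/dt = -r_hat + r``, floored.

    The floor keeps the modulation factor ``r / r_hat`` defined before the
    first reward has been observed.
    """
    r_hat = r_hat + (dt / tau_a) * (r - r_hat)
    return max(r_hat, floor)


def gradient_trace_step(
    g: ArrayLike,
    e: ArrayLike,
    r: float,
    r_hat: float,
    cfg: LearningConfig,
    dt: Optional[float] = None,
) -> ArrayLike:
    """One Euler step of the reward-gated gradient trace.

    ``g <- g (1 - dt/tau_g) + dt * c_r * (r/r_hat + alpha) * e``.  The trace
    is an online estimate of ``d/dtheta log V(theta)``; the offset ``alpha``
    allows small parameter changes even without reward and ``c_r`` scales the
    overall reward influence.
    """
    dt = cfg.dt if dt is None else dt
    g = np.asarray(g, dtype=float)
    modulation = cfg.c_r * (r / r_hat + cfg.alpha)
    out = g * (1.0 - dt / cfg.tau_g) + dt * modulation * np.asarray(e, dtype=float)
    return out if out.ndim else float(out)


def theta_sde_step(
    theta: ArrayLike,
    drift: ArrayLike,
    cfg: LearningConfig,
    noise: ArrayLike,
    dt: Optional[float] = None,
) -> ArrayLike:
    """One Euler-Maruyama step of the parameter SDE.

    ``dtheta = beta * drift * dt + sqrt(2 beta T dt) * noise`` with
    ``drift = prior_log_gradient + g`` in normal operation and ``noise`` one
    independent standard-normal draw per synapse.  The proposed change is
    clipped at ``+-cfg.clip`` and the result clamped to ``cfg.theta_bounds``
    (both numerical-stability guards; either may be ``None``).
    """
    dt = cfg.theta_update_interval if dt is None else dt
    theta = np.asarray(theta, dtype=float)
    dtheta = cfg.beta * np.asarray(drift, dtype=float) * dt
    if cfg.temperature > 0:
        dtheta = dtheta + np.sqrt(2.0 * cfg.beta * cfg.temperature * dt) * np.asarray(
            noise, dtype=float
        )
    if cfg.clip is not None:
        dtheta = np.clip(dtheta, -cfg.clip, cfg.clip)
    out = theta + dtheta
    if cfg.theta_bounds is not None:
        out = np.clip(out, cfg.theta_bounds[0], cfg.theta_bounds[1])
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# rewiring variants and consolidation
# ---------------------------------------------------------------------------


def sample_reactivation_time(
    rng: np.random.Generator,
    mean: float = DEFAULT_REACTIVATION_MEAN_S,
    size=None,
) -> ArrayLike:
    """Exponential waiting time until a retracted synapse becomes functional.

    Used by the approximate rewiring variant, which replaces the
    Ornstein-Uhlenbeck first-passage time of the exact rule by an
    exponential waiting time (default mean 12 h).
    """
    return rng.exponential(mean, size=size)


def reactivate_synapse(state: SynapseState, index) -> None:
    """Reintroduce retracted synapses at ``theta = 1e-5`` with cleared traces.

    ``index`` may be an integer, an index array or a boolean mask; every
    addressed synapse must currently be nonfunctional (``theta <= 0``).
    """
    if np.any(state.theta[index] > 0.0):
        raise ValueError("reactivate_synapse called on a functional synapse")
    state.theta[index] = 1e-5
    state.e[index] = 0.0
    state.g[index] = 0.0


def consolidate(prior: PriorSpec, thetas: np.ndarray, sigma: float = 0.05) -> PriorSpec:
    """Anchor the Gaussian prior at the current parameters.

    Returns a new prior with per-synapse mean ``mu_i = theta_i`` and reduced
    standard deviation (default 0.05), which stabilizes the learned
    configuration against diffusion while the temperature stays unchanged.
    """
    if prior.family != "gaussian":
        raise ValueError("consolidation is only defined for the gaussian prior")
    return replace(prior, mu=np.array(thetas, dtype=float, copy=True), sigma=sigma)
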