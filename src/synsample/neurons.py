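"""Stochastic spike-response neuron model.

A neuron's membrane potential is the weighted sum of presynaptic PSP traces
plus a slowly adapting bias, ``u_k = sum_i w_i y_pre_i + vartheta_k``.  The
instantaneous firing intensity follows an exponential escape function with
absolute refractoriness, ``f_k = exp(u_k) * Theta(rho_k - t_ref)`` in 1/s,
and spikes are realized per 1-ms bin as an inhomogeneous Bernoulli
approximation of the point process.  The bias ``vartheta`` is regulated by a
slow linear controller toward a target rate ``nu_0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]


@dataclass
class NeuronConfig:
    """Membrane and excitability constants of one neuron class.

    ``tau_m``/``tau_r`` are the PSP decay/rise time constants of the
    *outgoing* PSP kernel of this neuron, ``t_ref`` its absolute refractory
    period, ``nu_0`` the target rate of the bias controller and ``tau_theta``
    the controller time constant (all times in seconds).
    """

    tau_m: float = 0.020
    tau_r: float = 0.002
    t_ref: float = 0.005
    nu_0: float = 5.0
    tau_theta: float = 50.0
    is_inhibitory: bool = False

    def __post_init__(self) -> None:
        if self.tau_m == self.tau_r:
            raise ValueError("PSP kernel requires tau_m != tau_r")

    @classmethod
    def excitatory(cls) -> "NeuronConfig":
        return cls()

    @classmethod
    def inhibitory(cls) -> "NeuronConfig":
        # faster membrane dynamics and shorter refractoriness
        return cls(tau_m=0.010, tau_r=0.001, t_ref=0.002, is_inhibitory=True)


@dataclass
class NeuronState:
    """Per-neuron dynamic variables (vectorized over a population)."""

    vartheta: np.ndarray  # bias potential, initialized at -3
    rho: np.ndarray  # time since last spike (s)
    u: np.ndarray  # membrane potential

    @classmethod
    def initial(cls, n: int, vartheta0: float = -3.0) -> "NeuronState":
        return cls(
            vartheta=np.full(n, vartheta0, dtype=float),
            rho=np.full(n, np.inf),
            u=np.full(n, vartheta0, dtype=float),
        )


def psp_prefactor(tau_m: float, tau_r: float) -> float:
    """Amplitude prefactor ``tau_m/(tau_m - tau_r)`` of the PSP kernel.

    This normalization gives the kernel unit *charge per decay time*
    (integral ``tau_m``) and an O(1) peak (about 0.78 for the 20/2-ms pair),
    which puts unit synaptic weights on the scale of the model's fixed
    inhibitory weights (~ -1) and makes single presynaptic spikes move the
    membrane potential by O(w).
    """
    if tau_m == tau_r:
        raise ValueError("PSP kernel requires tau_m != tau_r")
    return tau_m / (tau_m - tau_r)


def psp_kernel(t: ArrayLike, tau_m: float = 0.020, tau_r: float = 0.002) -> ArrayLike:
    """Causal double-exponential PSP kernel.

    ``eps(t) = Theta(t) * tau_m/(tau_m - tau_r) * (exp(-t/tau_m) - exp(-t/tau_r))``
    with integral ``tau_m``; it peaks at
    ``t* = tau_m tau_r/(tau_m - tau_r) * ln(tau_m/tau_r)`` (about 5.12 ms for
    the 20/2-ms excitatory pair).  In simulations the convolution is carried
    incrementally with two exponential state variables per presynaptic neuron.
    """
    c = psp_prefactor(tau_m, tau_r)
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0.0, c * (np.exp(-t / tau_m) - np.exp(-t / tau_r)), 0.0)
    return out if out.ndim else float(out)


def psp_kernel_argmax(tau_m: float, tau_r: float) -> float:
    """Time of the PSP kernel peak."""
    return tau_m * tau_r / (tau_m - tau_r) * np.log(tau_m / tau_r)


def membrane_potential(vartheta: ArrayLike, weights, y_pre) -> ArrayLike:
    """``u = sum_i w_i y_pre_i + vartheta``.

    Fixed (e.g. inhibitory) connections enter the sum with their signed
    weights exactly like plastic ones.
    """
    drive = np.dot(np.asarray(weights, dtype=float), np.asarray(y_pre, dtype=float))
    out = np.asarray(vartheta, dtype=float) + drive
    return out if np.ndim(out) else float(out)


def firing_intensity(u: ArrayLike, rho: ArrayLike, t_ref: float = 0.005) -> ArrayLike:
    """Exponential escape intensity ``f = exp(u) Theta(rho - t_ref)`` in 1/s."""
    u = np.asarray(u, dtype=float)
    out = np.where(np.asarray(rho, dtype=float) >= t_ref, np.exp(u), 0.0)
    return out if out.ndim else float(out)


def sample_spike(
    f: ArrayLike, dt: float, rng: np.random.Generator
) -> Union[int, np.ndarray]:
    """Realize at most one spike per bin with probability ``1 - exp(-f dt)``.

    This is the proper Bernoulli discretization of a point process with
    intensity ``f`` (rather than ``min(1, f dt)``); a refractory neuron has
    ``f = 0`` and deterministically stays silent.
    """
    f = np.asarray(f, dtype=float)
    p = -np.expm1(-f * dt)
    out = (rng.random(f.shape if f.ndim else None) < p).astype(np.int64)
    return out if np.ndim(out) else int(out)


def bias_adaptation_step(
    vartheta: ArrayLike,
    z: ArrayLike,
    dt: float = 1e-3,
    nu_0: float = 5.0,
    tau_theta: float = 50.0,
) -> ArrayLike:
    """Euler step of ``tau_theta d vartheta/dt = nu_0 - z(t)``.

    ``z`` is the 0/1 bin spike indicator (integrated spike train), so each
    spike decrements the bias by ``1/tau_theta`` while silence lets it drift
    up at ``nu_0/tau_theta`` per second; the long-run rate settles near
    ``nu_0``.
    """
    out = (
        np.asarray(vartheta, dtype=float)
        + dt * nu_0 / tau_theta
        - np.asarray(z, dtype=float) / tau_theta
    )
    return out if np.ndim(out) else float(out)
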