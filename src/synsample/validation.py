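"""Numerical validation of the sampler's stationary law.

Two checks connect the simulated parameter SDE to its theory:

* With the reward-gradient trace forced to zero and a Gaussian prior, the
  SDE is an Ornstein-Uhlenbeck process with stationary mean ``mu`` and
  variance ``T sigma^2``; :func:`ou_stationary_test` verifies both moments
  on an ensemble.
* For an arbitrary smooth target density ``p*``, substituting the analytic
  ``d/dtheta log p*`` for the prior-plus-gradient drift must leave the
  empirical distribution proportional to ``p*^(1/T)``;
  :func:`toy_posterior_sampling_test` measures the KL divergence between
  the histogram of simulated samples and the quadrature-normalized tempered
  density.

Both use :func:`synsample.dynamics.theta_sde_step` -- the very integrator the
network simulation uses -- with validation-specific defaults: a larger
learning rate (``beta = 0.01``, relaxation time ``sigma^2/beta = 400 s``
instead of days, so the budgeted step counts cover several relaxation times)
and no update clip or parameter bounds (those are numerical guards for
network runs that would distort the pure SDE).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Tuple

import numpy as np

from .dynamics import LearningConfig, PriorSpec, theta_sde_step


def validation_config(
    beta: float = 0.01, temperature: float = 0.1, dt: float = 0.1
) -> LearningConfig:
    """SDE-only configuration: no clipping, no bounds."""
    return LearningConfig(
        beta=beta,
        temperature=temperature,
        theta_update_interval=dt,
        clip=None,
        theta_bounds=None,
    )


@dataclass
class ToyTargetDensity:
    """1-D target density with analytic score, normalized by quadrature."""

    log_density: Callable[[np.ndarray], np.ndarray]
    grad_log_density: Callable[[np.ndarray], np.ndarray]
    support: Tuple[float, float]
    name: str = "toy"

    def tempered_pdf(self, grid: np.ndarray, temperature: float) -> np.ndarray:
        """``p*(theta)^(1/T)`` normalized on the grid by the trapezoid rule."""
        logp = self.log_density(grid) / temperature
        logp -= logp.max()
        p = np.exp(logp)
        z = np.trapezoid(p, grid)
        if not np.isfinite(z) or z <= 0:
            raise ValueError("target density is not normalizable on its support")
        return p / z

    @classmethod
    def double_well(cls, barrier: float = 2.0, well: float = 1.0) -> "ToyTargetDensity":
        """Symmetric double well, log p* = -barrier * (theta^2 - well^2)^2."""
        a = barrier / well**4

        def logp(x):
            return -a * (np.asarray(x) ** 2 - well**2) ** 2

        def grad(x):
            x = np.asarray(x)
            return -4.0 * a * x * (x**2 - well**2)

        return cls(logp, grad, (-3.0 * well, 3.0 * well), "double_well")

    @classmethod
    def gaussian(cls, mu: float = 0.0, sigma: float = 1.0) -> "ToyTargetDensity":
        def logp(x):
            return -((np.asarray(x) - mu) ** 2) / (2 * sigma**2)

        def grad(x):
            return (mu - np.asarray(x)) / sigma**2

        return cls(logp, grad, (mu - 6 * sigma, mu + 6 * sigma), "gaussian")


@dataclass
class OUTestResult:
    mean: float
    variance: float
    expected_mean: float
    expected_variance: float
    se_mean: float
    se_variance: float
    passed: bool


def ou_stationary_test(
    prior: Optional[PriorSpec] = None,
    cfg: Optional[LearningConfig] = None,
    n_synapses: int = 10_000,
    n_updates: int = 20_000,
    burn_in_fraction: float = 0.2,
    seed: int = 0,
    n_se: float = 3.0,
) -> OUTestResult:
    """Ensemble check of the prior-only Ornstein-Uhlenbeck stationary moments.

    Simulates ``n_synapses`` independent parameters with the gradient trace
    forced to zero, starting at the prior mean, and compares the final
    ensemble mean and variance with the analytic values ``mu`` and
    ``T sigma^2`` within ``n_se`` standard errors.
    """
    prior = prior if prior is not None else PriorSpec(family="gaussian", mu=0.0, sigma=2.0)
    if prior.family != "gaussian":
        raise ValueError("the OU check requires a gaussian prior")
    cfg = cfg if cfg is not None else validation_config()
    rng = np.random.default_rng(seed)
    theta = np.full(n_synapses, float(np.mean(prior.mu)))
    relax = prior.sigma**2 / cfg.beta
    if n_updates * cfg.theta_update_interval < 3 * relax:
        raise ValueError(
            "insufficient effective samples: the run covers fewer than three "
            f"relaxation times (sigma^2/beta = {relax:.3g} s)"
        )
    for _ in range(n_updates):
        drift = prior.log_gradient(theta)
        theta = np.asarray(
            theta_sde_step(theta, drift, cfg, rng.standard_normal(n_synapses))
        )
    exp_mean = float(np.mean(prior.mu))
    exp_var = cfg.temperature * prior.sigma**2
    m, v = float(theta.mean()), float(theta.var(ddof=1))
    se_m = np.sqrt(exp_var / n_synapses)
    se_v = exp_var * np.sqrt(2.0 / (n_synapses - 1))
    passed = abs(m - exp_mean) < n_se * se_m and abs(v - exp_var) < n_se * se_v
    return OUTestResult(m, v, exp_mean, exp_var, float(se_m), float(se_v), bool(passed))


@dataclass
class ToySamplingResult:
    kl: float
    temperature: float
    occupancy_left: float
    occupancy_right: float
    #: standard error of the left-well occupancy, from the between-chain
    #: spread (chains decorrelate across wells slowly, so per-sample counts
    #: would understate the Monte-Carlo error)
    occupancy_sem: float
    entropy: float
    n_samples: int
    passed: bool


def _fd_bins(samples: np.ndarray, support: Tuple[float, float]) -> np.ndarray:
    """Freedman-Diaconis bin edges on the support."""
    q75, q25 = np.percentile(samples, [75, 25])
    width = 2.0 * (q75 - q25) / samples.size ** (1.0 / 3.0)
    lo, hi = support
    n = max(10, min(200, int(np.ceil((hi - lo) / max(width, 1e-6)))))
    return np.linspace(lo, hi, n + 1)


def toy_posterior_sampling_test(
    target: Optional[ToyTargetDensity] = None,
    temperature: float = 1.0,
    cfg: Optional[LearningConfig] = None,
    n_steps: int = 1_000_000,
    n_chains: int = 100,
    burn_in_fraction: float = 0.2,
    seed: int = 0,
    kl_threshold: float = 0.05,
) -> ToySamplingResult:
    """Sample a toy density with the parameter SDE and compare to theory.

    ``n_steps`` total SDE steps are split over ``n_chains`` parallel chains
    initialized uniformly on the support.  After discarding the burn-in, the
    sample histogram (Freedman-Diaconis bins, 1e-12 additive smoothing) is
    compared against the quadrature-normalized ``p*^(1/T)`` by the KL
    divergence KL(empirical || theory).

    The default configuration uses ``beta = 0.1`` with the 0.1-s update step,
    i.e. an effective Langevin step ``beta dt = 0.01``: small enough for the
    Euler-Maruyama weak error to be far below the KL threshold, large enough
    that a chain decorrelates within tens of steps.
    """
    target = target if target is not None else ToyTargetDensity.double_well()
    cfg = cfg if cfg is not None else validation_config(beta=0.1)
    cfg = replace(cfg, temperature=temperature)
    rng = np.random.default_rng(seed)
    steps_per_chain = int(n_steps) // n_chains
    burn = int(burn_in_fraction * steps_per_chain)
    lo, hi = target.support
    theta = rng.uniform(lo, hi, size=n_chains)
    kept = np.empty((steps_per_chain - burn, n_chains))
    for s in range(steps_per_chain):
        drift = target.grad_log_density(theta)
        theta = np.asarray(
            theta_sde_step(theta, drift, cfg, rng.standard_normal(n_chains))
        )
        if s >= burn:
            kept[s - burn] = theta
    samples = kept.ravel()

    edges = _fd_bins(samples, target.support)
    counts, _ = np.histogram(samples, bins=edges)
    emp = counts.astype(float) / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = target.tempered_pdf(centers, temperature)
    theory = pdf * np.diff(edges)
    theory = theory / theory.sum()
    emp_s = emp + 1e-12
    th_s = theory + 1e-12
    kl = float(np.sum(emp_s * np.log(emp_s / th_s)))

    occ_chain = np.mean(kept < 0.0, axis=0)
    occ_left = float(occ_chain.mean())
    occ_sem = float(occ_chain.std(ddof=1) / np.sqrt(n_chains))
    ent = float(-np.sum(emp_s * np.log(emp_s)))
    return ToySamplingResult(
        kl=kl,
        temperature=temperature,
        occupancy_left=occ_left,
        occupancy_right=1.0 - occ_left,
        occupancy_sem=occ_sem,
        entropy=ent,
        n_samples=samples.size,
        passed=bool(kl < kl_threshold),
    )
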