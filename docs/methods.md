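# Methods

## Model

`synsample` simulates reward-gated structural plasticity in spiking neural
networks as *synaptic sampling*.  A network scaffold fixes the neurons, a
list of potential synaptic connections (several may link the same ordered
neuron pair) and all non-plastic wiring.  Each potential synapse `i`
carries a parameter `theta_i`; the connection is functional with efficacy

    w_i = exp(theta_i - theta0)      if theta_i > 0
    w_i = 0                          otherwise (retracted),

with offset `theta0 = 3`, so newly formed synapses start weak
(`w ~ 0.05`) and additive parameter changes act multiplicatively on the
weight.  The parameters follow the Langevin dynamics

    d theta_i = beta ( d/dtheta_i log p_S(theta) + g_i(t) ) dt
                + sqrt(2 beta T) dW_i ,

whose stationary distribution is proportional to
`(p_S(theta) x V(theta))^(1/T)`, the structural prior times the expected
discounted reward, tempered by `T`.  The network therefore keeps moving
through parameter space forever, spending most time in well-rewarded,
prior-compatible configurations; learning is sampling, not convergence.

### Neurons

Stochastic spike-response neurons: membrane potential
`u_k = sum_i w_i y_pre(i) + vartheta_k`, where `y` is the presynaptic spike
train filtered with the causal double-exponential PSP kernel

    eps(t) = tau_m/(tau_m - tau_r) (exp(-t/tau_m) - exp(-t/tau_r)),

(rise 2 ms, decay 20 ms for excitatory sources; 1/10 ms for inhibitory
ones; peak ~0.78 at 5.12 ms).  The prefactor `tau_m/(tau_m - tau_r)` makes
single-spike PSPs order one, the scale on which the model's fixed weights
(inhibitory ~ -1, excitatory-to-inhibitory ~ +0.5) and the lever-readout
thresholds are defined.  One PSP trace is kept per presynaptic neuron and
shared by all its outgoing synapses; transmission delay is one 1-ms step.

The firing intensity is the exponential escape function
`f = exp(u) * Theta(rho - t_ref)` in s^-1 (5-ms absolute refractory period
for excitatory, 2 ms for inhibitory neurons).  We read `exp(u)` in
per-second units: it makes the clamped potential `u = -2.4` of the pairing
protocol a near-silent resting state (0.09 Hz) and gives the pairing
protocol its potentiation-dominated eligibility (a per-millisecond reading
would make the `-f dt` term dominate the scripted bursts and turn the
rewarded protocol into depression).  Spikes are realized per 1-ms bin with
probability `1 - exp(-f dt)`, the exact point-process discretization.  A
slow intrinsic-excitability control `tau_theta d vartheta/dt = nu_0 - z(t)`
(`nu_0 = 5 Hz`, `tau_theta = 50 s`, `vartheta(0) = -3`) drives every
network neuron's long-run rate toward `nu_0`.

### Synapses

The reward-gradient estimate is built from two local traces on the 1-ms
grid (forward Euler):

    e_i <- e_i (1 - dt/tau_e) + w_i y_pre(i) (z_post(i) - f_post(i) dt)
    g_i <- g_i (1 - dt/tau_g) + dt c_r (r/r_hat + alpha) e_i
    r_hat <- r_hat + dt/tau_a (r - r_hat),   floored at 1e-4

with `tau_e = 1 s`, `tau_g = tau_a = 50 s`, `alpha = 0.02`, `c_r = 1`.
Because the eligibility drive carries the factor `w_i`, retracted synapses
(`w = 0`) receive no activity information: their parameters evolve by prior
and noise alone (verified bit-exactly in the tests).  The parameter SDE is
integrated by Euler-Maruyama every 100 ms (`beta = 1e-5 / s`, `T = 0.1`,
prior N(0, 2^2) unless stated), with per-update changes clipped at
`+-4e-4` and parameters confined to `[-2, 5]`.  Parameters are initialized
from N(-0.5, 0.5^2).

Numerical notes:

* The clip is ~0.9 standard deviations of the per-update diffusion term,
  so it visibly truncates the noise; it is a stability guard inherited
  from the model definition, and the stationary-law validation therefore
  runs without it.
* The membrane potential is capped at `u <= 6` (f <= 403 Hz) inside the
  simulation kernel so that a transiently overdriven configuration cannot
  overflow `exp(u)` inside the eligibility drive; realized rates are
  refractory-bounded well below this.
* `r_hat` starts at its floor (1e-4), so the first rewards of a run act
  with a very large `r/r_hat`; the update clip bounds the resulting kick.
* Within a 100-ms parameter-update window the weights are constant, making
  the `e`/`g` recursions linear in the window-start state with pair-shared
  drives.  The compiled kernel exploits this: it integrates pair-level
  accumulators per ms and folds them into the per-synapse traces once per
  window, which is algebraically identical to the plain per-synapse
  recursion (checked against a reference integrator to 1e-8 relative).

### Rewiring variants, consolidation

* `exact` (default): `theta <= 0` evolves freely by prior + noise and the
  synapse re-forms when theta crosses zero.
* `approximate`: the SDE is suspended for retracted synapses; each draws
  an exponential waiting time (mean 12 h) and re-enters at
  `theta = 1e-5` with cleared traces.
* `disabled`: sign crossings are forbidden (used for
  rewiring-frozen controls).

Consolidation re-anchors the Gaussian prior at the current parameters
(`mu_i := theta_i`, `sigma := 0.05`) without changing the temperature; the
post-consolidation stationary spread per synapse is `sqrt(T) sigma ~ 0.016`.

## Tasks

**Pattern routing.**  200 Poisson inputs with Gaussian tuning curves
(sigma 0.2, centers uniform in the unit cube) encode two patterns P1/P2 as
jittered points (jitter sigma 0.05); rates are `60 Hz x tuning + 2 Hz`,
presentations last U[750, 1500] ms, separated by U[1000, 2000] ms of 2-Hz
background, pattern identity drawn uniformly per presentation, and segment
durations rounded to the 10-ms reward grid.  20 MSNs split into two pools
of 10 (targets T1/T2) receive Binomial(10, 0.5) potential plastic synapses
per (input, MSN) pair (~20,000) plus fixed lateral inhibition
(Bernoulli(0.5), N(-1, 0.2) truncated at zero).  Pool output rates are
boxcar spike counts over the trailing 500 ms divided by the window
(pool rates in Hz), refreshed every 10 ms; with `I = +1` for P1 and `-1`
for P2 the reward is 0 if `I(nu1 - nu2) < 0` and otherwise
`S((I nu1 - I nu2 - 25)/5)` with the logistic sigmoid `S` (the slope is
configurable).  No reward during background.  Performance is the mean
reward over pattern-presentation time, a fraction of the maximum
achievable (r = 1 during every presentation).

**Lever press.**  A recurrent scaffold of 60 excitatory and 20 inhibitory
neurons; half of the excitatory neurons can receive input synapses, pools
D and U (10 each) are drawn from the other half.  All input->receiving and
excitatory->excitatory potential synapses are plastic (Binomial(10, 0.5)
per pair, ~47,700); excitatory->inhibitory (p=0.575, N(0.5, 0.1)
truncated), inhibitory->excitatory (p=0.6) and inhibitory->inhibitory
(p=0.55) with N(-1, 0.2) truncated are fixed.  "Hidden" denotes the 40
excitatory neurons outside D and U (30 of which are input-receiving).  The
lever position is the pooled U-minus-D spike train filtered with a slow
double-exponential kernel (rise 50 ms, decay 500 ms, peak at ~128 ms).  A
trial succeeds when the lever crosses +5 after first crossing -5 within
10 s of cue onset; success sets r = 1 for 400 ms, then a U[1, 2]-s holding
phase at 2-Hz input; timeouts abort unrewarded.  A task switch negates the
decoding signs and regenerates the cue pattern.  Reward is recomputed
every 1 ms during trials.

**STDP pairing protocol.**  50 independent synapses, postsynaptic
potential clamped at -2.4; 15 pairings, one per 10 s; per pairing 10
presynaptic spikes at 10 Hz, each followed after 10 ms by a 3-spike
100-Hz burst; reward is a 300-ms rectangular pulse of amplitude 1 at a
configurable delay from pairing onset (default 0.6 s, inside the pairing
window).  Conditions (with reward / without reward / without presynaptic
stimulation) are compared at matched seed so the per-synapse Wiener
increments cancel and the comparison isolates the deterministic plasticity
signal.

## Validation of the stationary law

* **OU moments** (`validation.ou_stationary_test`): with `g = 0` and a
  Gaussian prior the SDE is an Ornstein-Uhlenbeck process with stationary
  mean `mu` and variance `T sigma^2`.  The validation default uses
  `beta = 0.01` so the relaxation time `sigma^2/beta = 400 s` is covered
  several times by a 2,000-s run (the synapse-model default `beta = 1e-5`
  has a 4.6-day relaxation, which is the point of the slow prior but not
  testable in a bounded ensemble run), and disables the clip and bounds,
  which are network-run guards that would truncate the diffusion.
  Pass criterion: both moments within 3 ensemble standard errors.
* **Tempered-density sampling** (`validation.toy_posterior_sampling_test`):
  the same integrator with an analytic score `d log p*/dtheta` in place of
  prior + gradient must sample `p*^(1/T)`.  100 chains initialized
  uniformly on the support, effective Langevin step `beta dt = 0.01`, 20%
  burn-in; the empirical histogram (Freedman-Diaconis bins, 1e-12
  smoothing) is compared to the quadrature-normalized tempered density by
  KL(empirical || theory) < 0.05.  Well-occupancy symmetry on the double
  well is judged within 3 standard errors estimated from the between-chain
  spread, since chains decorrelate across wells slowly at low temperature.

## Reproducibility

Each run's master seed fans out (via `numpy.random.SeedSequence`) to named
child streams: parameter initialization, stimulus, spiking, and plasticity
noise.  The plasticity stream is consumed as one draw per potential
synapse per 100-ms update regardless of network activity, so retracted
synapses follow identical trajectories with and without stimulation, and
two runs with the same seed produce byte-identical outputs.  The analysis
functions take their own RNG so subsampling (CI pairs, PCA parameter
subsets) can be re-randomized independently.

## What the simulations do and do not show

The tasks are synthetic environments whose statistics are fully specified
here; passing tests demonstrates the internal consistency of the sampler
(stationary law, condition orderings, independence properties, rewiring
statistics machinery) rather than fidelity to any biological dataset.
Known limitations:

* Point neurons with a single somatic potential; no conductances,
  dendrites, or plastic inhibition.
* The reward-gradient estimator is a REINFORCE-type correlation estimate;
  its per-synapse signal-to-noise is low, and with the reference
  parameters (`beta = 1e-5/s`, `tau_g = 50 s`) closed-loop task learning
  is slow.  Quantitatively: a hand-wired routed configuration holds a
  ~0.92 mean pattern reward stably, but from a naive initialization a
  3-h routing run reaches only ~0.2 -- direct perturbation measurements
  give `d log V / d theta ~ 0.01` per relevant synapse at that stage, so
  the gradient-flow time scale at `beta = 1e-5/s` is of order 100 h.  The
  same `beta` is what makes spontaneous dynamics slow (prior relaxation
  `sigma^2/beta ~ 4.6 days`, matching multi-day memory retention before
  forgetting).  Fast task acquisition and slow forgetting cannot both be
  had at a single `beta` in this estimator family; this package keeps the
  slow-SDE regime, which the stationary-law validation, consolidation and
  turnover analyses rely on.
* `alpha` is a constant reward offset; no learned critic.
* The reduced demixed-PCA separates only reward-dependent from
  reward-independent parameter variance (between-bin vs residual
  covariance); no full task/time demixing.
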