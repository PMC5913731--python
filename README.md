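# synsample

Reward-based **synaptic sampling** in spiking neural networks: a simulator
for stochastic rewiring and reward-modulated plasticity in which a network
does not converge to a fixed wiring but keeps *sampling* network
configurations from a posterior distribution shaped by reward.

## The scientific problem

Synaptic connections in cortex and striatum are volatile: spines appear,
grow, shrink and vanish even without neural activity, and the spontaneous,
synapse-autonomous share of this dynamics is as large as the
activity-dependent share.  How can circuits learn and retain rewarded
behaviour on top of such a restless substrate?  `synsample` implements a
framework in which that volatility *is* the learning algorithm.  Every
potential synaptic connection `i` carries a parameter `θᵢ` with

    wᵢ = exp(θᵢ − θ₀)  if θᵢ > 0,     wᵢ = 0  otherwise,

so a synapse is functional only while `θᵢ > 0`, and the parameters obey
the Langevin dynamics

    dθᵢ = β ( ∂/∂θᵢ log p_S(θ) + ∂/∂θᵢ log V(θ) ) dt + √(2βT) dWᵢ ,

with a structural prior `p_S`, the expected discounted reward `V(θ)`, a
temperature `T`, and Wiener noise `Wᵢ`.  The stationary distribution of
this process is proportional to `(p_S(θ) · V(θ))^{1/T}`: the network
spends most of its time in well-rewarded, prior-compatible configurations
while individual synapses keep turning over — *policy sampling* instead of
policy gradient.  Online, `∂ log V/∂θᵢ` is estimated per synapse by an
eligibility trace `eᵢ` (PSP × postsynaptic spike-minus-rate, time constant
1 s) low-pass filtered against the normalized reward,
`gᵢ ← gᵢ(1 − dt/τ_g) + dt·c_r(r/r̂ + α)·eᵢ`, which yields a
dopamine-gated STDP rule with built-in rewiring.

The package provides, as library modules with a thin CLI on top:

| module | contents |
| --- | --- |
| `synsample.dynamics` | weight map, priors, traces, the parameter SDE, rewiring variants, consolidation |
| `synsample.neurons` | stochastic spike-response neuron: PSP kernel, exponential escape intensity, bias homeostasis |
| `synsample.network` | scaffolds, the 1-ms simulation loop (numba-compiled), recording buffers |
| `synsample.tasks` | cortex→striatum pattern routing, recurrent lever-press task, the STDP pairing protocol |
| `synsample.analysis` | turnover, synapse fates, CI-pair correlations and contribution decomposition, movement onsets, trial-averaged activity, parameter-change amplitude, PCA / reduced demixed PCA |
| `synsample.validation` | Ornstein–Uhlenbeck moments and tempered-density sampling checks of the stationary law |
| `synsample.config` / `recording` / `cli` | YAML configs, TSV/JSON writers, `synsample simulate/analyze/validate` |

## Worked example

The dopamine-gated pairing protocol (`examples/03_stdp_pairing.py`): 15
pre/post pairings, one per 10 s, each 10 presynaptic spikes at 10 Hz
followed 10 ms later by a 100-Hz spike triplet, membrane clamped at −2.4,
and a 300-ms reward pulse per pairing:

```text
reward + pairing   : weight change after 150 s =  +71.87 % +- 0.13 % (SEM, 50 synapses)
pairing, no reward : weight change after 150 s =   +0.04 % +- 0.18 % (SEM, 50 synapses)
no pre-stimulation : weight change after 150 s =   -0.05 % +- 0.18 % (SEM, 50 synapses)
```

Pairing plus reward produces strong potentiation; removing the reward
leaves only the small `α`-driven drift; removing the presynaptic input
eliminates the effect entirely (the residual is the shared diffusion
noise).  The other scripts in `examples/` demonstrate, one capability
each: OU spontaneous spine dynamics (`01`), sampling a tempered double-well
posterior with KL ≈ 0.003–0.008 against quadrature (`02`), the closed-loop
routing task (`04`), lever-press trial mechanics and movement-onset
detection (`05`), and rewiring statistics — synapse fates and CI-pair
correlations (`06`).

Command-line equivalents:

```bash
synsample simulate routing --seed 1 --duration-hours 0.5 --out runs/routing
synsample analyze turnover --snapshots runs/routing/snapshots.tsv --out runs/routing
synsample validate ou --seed 1
```

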