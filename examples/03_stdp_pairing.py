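"""Dopamine-gated STDP: the pairing protocol on 50 model synapses.

Fifteen pre/post pairings (10 pre spikes at 10 Hz, each followed 10 ms
later by a 100-Hz triplet burst), one pairing per 10 s, with the
postsynaptic potential clamped at -2.4.  A 300-ms reward pulse per pairing
gates consolidation of the eligibility trace into the weights.  The three
conditions share the same noise realization, so their ordering reflects
the plasticity signal alone: strong potentiation with reward, a small
residual drift without reward, and nothing without presynaptic input.
"""

from synsample.tasks.stdp import run_stdp_protocol

for label, kwargs in [
    ("reward + pairing   ", dict(with_reward=True, with_pre=True)),
    ("pairing, no reward ", dict(with_reward=False, with_pre=True)),
    ("no pre-stimulation ", dict(with_reward=False, with_pre=False)),
]:
    res = run_stdp_protocol(n_synapses=50, seed=11, **kwargs)
    print(
        f"{label}: weight change after 150 s = "
        f"{res.final_mean_pct:+7.2f} % +- {res.sem_pct[-1]:.2f} % (SEM, 50 synapses)"
    )
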