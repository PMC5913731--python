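"""Rewiring statistics: synapse fates and CI-pair correlations.

Runs the routing network for 20 simulated minutes, classifies every
potential synapse by its fate between start and end (stable functional /
stable nonfunctional / transient), and correlates the weights of synapse
pairs that share both neurons (commonly innervated, CI) against pairs that
share only the postsynaptic neuron (non-CI).  The gap between the two
correlations bounds the activity-specific share of synaptic dynamics; the
decomposition splits the remainder into spontaneous and neuron-wide parts.
"""

import numpy as np

from synsample.analysis import (
    ci_pair_correlations,
    contribution_decomposition,
    fate_fractions,
)
from synsample.tasks.routing import build_routing_scaffold, run_routing_experiment

seed = 3
buf = run_routing_experiment(seed=seed, duration_s=1200.0)
scaffold = build_routing_scaffold(seed)

frac = fate_fractions(buf.theta_init, buf.final_state.theta)
for name, value in frac.items():
    print(f"{name:>22s}: {100*value:5.1f} %")

r_ci, r_nci, n_ci, n_nci = ci_pair_correlations(
    buf.final_state.w, scaffold.pre, scaffold.post, np.random.default_rng(0)
)
act, spont, wide = contribution_decomposition(max(r_ci, 0), max(min(r_nci, r_ci), 0))
print(f"\nCI-pair weight correlation:     r = {r_ci:+.3f} ({n_ci} pairs)")
print(f"non-CI-pair weight correlation: r = {r_nci:+.3f} ({n_nci} pairs)")
print(
    f"contributions -> activity-specific {act:.2f}, spontaneous {spont:.2f}, "
    f"neuron-wide {wide:.2f}"
)
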