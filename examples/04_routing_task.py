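"""Reward-based routing of cortical patterns onto striatal pools.

Builds the 200-input / 20-MSN scaffold with ~20,000 potential plastic
synapses and runs the closed loop for 30 simulated minutes (a few minutes
of compute).  Printed per 10-minute block: the mean reward during pattern
presentations (fraction of the maximum achievable) and the synaptic
turnover, i.e. how many potential synapses appeared or disappeared.
Learning at the reference parameters is slow, so expect a gentle upward
trend over this short run, with rewiring ongoing throughout.
"""

import numpy as np

from synsample.analysis import SnapshotSeries, turnover_series
from synsample.network import RecorderConfig
from synsample.tasks.routing import mean_pattern_reward, run_routing_experiment

buf = run_routing_experiment(
    seed=1,
    duration_s=1800.0,
    recorders=RecorderConfig(snapshot_interval_s=600.0),
)
series = SnapshotSeries(
    np.concatenate([[0.0], buf.snapshot_times_s]),
    np.vstack([buf.theta_init, buf.snapshots]),
)
turnover = turnover_series(series)
for k, t0 in enumerate(range(0, 1800, 600)):
    r = mean_pattern_reward(buf, t0, t0 + 600)
    print(
        f"minutes {t0//60:2d}-{t0//60+10:2d}: mean pattern reward = {r:.3f}, "
        f"synapse turnover = {turnover[k]}"
    )
frac = buf.final_state.functional.mean()
print(f"functional potential synapses at the end: {100*frac:.1f} %")
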