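"""The recurrent lever-press task: trial mechanics and movement onsets.

Builds the 60E/20I recurrent scaffold (~47,700 plastic potential synapses)
and runs five simulated minutes.  At this early stage trials are mostly
chance successes of the stochastic lever; the script prints the trial
statistics, the mean completion time (timeouts censored at 10 s) and the
movement-onset time of the first completed trial estimated from the lever
velocity envelope.
"""

import numpy as np

from synsample.analysis import detect_movement_onset, movement_completion_time
from synsample.tasks.lever import LeverTask, build_lever_scaffold
from synsample.dynamics import LearningConfig
from synsample.network import simulate

scaffold = build_lever_scaffold(seed=2)
task = LeverTask()
buf = simulate(scaffold, task, LearningConfig(), 300.0, seed=2)

trials = buf.trials
n_ok = sum(t["completed"] for t in trials)
print(f"trials: {len(trials)}, completed: {n_ok}")
if trials:
    mean_s, sem_s = movement_completion_time(trials)
    print(f"mean completion time: {mean_s:.2f} +- {sem_s:.2f} s (timeouts at 10 s)")
lever = np.array(task.lever_positions)
done = [t for t in trials if t["completed"]]
if done:
    t0 = done[0]["onset_ms"]
    t1 = t0 + done[0]["duration_ms"]
    onset = detect_movement_onset(lever[t0:t1:5])  # 5-ms samples
    print(f"first completed trial: onset of movement {onset:.2f} s after cue")
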