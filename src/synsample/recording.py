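"""Writers for simulation recordings.

Everything is emitted as headered TSV tables plus a JSON manifest carrying
the configuration hash and master seed, so a run is fully reconstructible
from (config file, seed, code version) and reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import ExperimentConfig, config_hash
from .dynamics import weight_from_theta
from .network import NetworkScaffold, RecordingBuffer


def write_records(
    buffer: RecordingBuffer,
    out_dir,
    scaffold: Optional[NetworkScaffold] = None,
    config: Optional[ExperimentConfig] = None,
) -> Dict[str, str]:
    """Write all recorded series of a run to ``out_dir``; returns the manifest.

    Emits ``spikes.tsv`` (time_ms, neuron_id, population_tag), ``reward.tsv``
    (time_ms, value), ``lever.tsv`` (time_ms, value), ``snapshots.tsv``
    (snapshot_time_s, synapse_id, pre_neuron, post_neuron, theta, w),
    ``trials.tsv`` and ``manifest.json``.  Empty buffers still produce valid
    tables with headers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: Dict[str, str] = {}

    tags = scaffold.tags if scaffold is not None else None
    spikes = pd.DataFrame(
        {
            "time_ms": buffer.spike_times_ms,
            "neuron_id": buffer.spike_neuron,
            "population_tag": (
                [tags[i] for i in buffer.spike_neuron] if tags is not None else ""
            ),
        }
    )
    spikes.to_csv(out / "spikes.tsv", sep="\t", index=False)
    files["spikes"] = "spikes.tsv"

    pd.DataFrame({"time_ms": buffer.reward_t_ms, "value": buffer.reward}).to_csv(
        out / "reward.tsv", sep="\t", index=False
    )
    files["reward"] = "reward.tsv"

    if buffer.lever is not None:
        pd.DataFrame(
            {
                "time_ms": np.arange(buffer.lever.shape[0], dtype=np.int64),
                "value": buffer.lever,
            }
        ).to_csv(out / "lever.tsv", sep="\t", index=False)
        files["lever"] = "lever.tsv"

    theta0 = config.learning.theta0 if config is not None else 3.0
    rows = []
    snap_iter = list(zip(buffer.snapshot_times_s, buffer.snapshots))
    last_t = snap_iter[-1][0] if snap_iter else None
    if buffer.final_state is not None and buffer.duration_s != last_t:
        snap_iter.append((buffer.duration_s, buffer.final_state.theta))
    for t_s, theta in snap_iter:
        w = np.asarray(weight_from_theta(theta, theta0))
        rows.append(
            pd.DataFrame(
                {
                    "snapshot_time_s": t_s,
                    "synapse_id": np.arange(theta.shape[0], dtype=np.int64),
                    "pre_neuron": scaffold.pre if scaffold is not None else -1,
                    "post_neuron": (
                        scaffold.post + scaffold.n_inputs
                        if scaffold is not None
                        else -1
                    ),
                    "theta": theta,
                    "w": w,
                }
            )
        )
    snaps = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "snapshot_time_s",
                "synapse_id",
                "pre_neuron",
                "post_neuron",
                "theta",
                "w",
            ]
        )
    )
    snaps.to_csv(out / "snapshots.tsv", sep="\t", index=False)
    files["snapshots"] = "snapshots.tsv"

    pd.DataFrame(
        buffer.trials, columns=["onset_ms", "completed", "duration_ms"]
    ).to_csv(out / "trials.tsv", sep="\t", index=False)
    files["trials"] = "trials.tsv"

    manifest = {
        "seed": buffer.seed,
        "duration_s": buffer.duration_s,
        "config_hash": config_hash(config) if config is not None else None,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files["manifest"] = "manifest.json"
    return manifest


def read_snapshots(path) -> "pd.DataFrame":
    """Load a snapshot table written by :func:`write_records`."""
    return pd.read_csv(path, sep="\t")
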