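"""Post-hoc analyses of recorded trajectories.

Operates on snapshot series of synaptic parameters (times x synapses), spike
tables, lever traces and trial tables produced by the simulator: task
performance, synaptic turnover and fate classification, commonly-innervated
(CI) pair correlations and their decomposition into activity-specific,
neuron-wide and spontaneous contributions, movement-onset detection,
trial-averaged activity maps, parameter-change amplitudes, and PCA/demixed
PCA of parameter trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert
from scipy.stats import mannwhitneyu, pearsonr
from sklearn.decomposition import PCA

FATE_CLASSES = (
    "stable_nonfunctional",
    "transient_decaying",
    "transient_emerging",
    "stable_functional",
)


@dataclass
class SnapshotSeries:
    """Periodic snapshots of the synaptic parameter vector.

    ``thetas`` has one row per snapshot time; column identity (synapse id) is
    stable across time.
    """

    times_s: np.ndarray
    thetas: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.thetas = np.asarray(self.thetas, dtype=float)
        if self.thetas.shape[0] != self.times_s.shape[0]:
            raise ValueError("one row of thetas per snapshot time required")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("snapshot times must be strictly increasing")

    def weights(self, theta0: float = 3.0) -> np.ndarray:
        return np.where(self.thetas > 0.0, np.exp(self.thetas - theta0), 0.0)


# ---------------------------------------------------------------------------
# performance and rewiring statistics
# ---------------------------------------------------------------------------


def movement_completion_time(trials: Sequence[dict]) -> Tuple[float, float]:
    """Mean +- SEM of cue-onset-to-completion time in seconds.

    Timed-out trials are censored at the 10-s abort limit and enter the mean
    at that value.
    """
    if len(trials) == 0:
        raise ValueError("no trials recorded")
    durs = np.array([t["duration_ms"] for t in trials], dtype=float) / 1000.0
    sem = durs.std(ddof=1) / np.sqrt(len(durs)) if len(durs) > 1 else 0.0
    return float(durs.mean()), float(sem)


def turnover_count(theta_a: np.ndarray, theta_b: np.ndarray) -> Tuple[int, int, int]:
    """Synapses crossing theta = 0 between two snapshots.

    Returns ``(appeared, disappeared, total)`` where a synapse appeared if
    ``theta_a <= 0 < theta_b`` and disappeared if ``theta_a > 0 >= theta_b``.
    """
    theta_a = np.asarray(theta_a)
    theta_b = np.asarray(theta_b)
    if theta_a.shape != theta_b.shape:
        raise ValueError("snapshots must address the same synapses")
    appeared = int(np.sum((theta_a <= 0.0) & (theta_b > 0.0)))
    disappeared = int(np.sum((theta_a > 0.0) & (theta_b <= 0.0)))
    return appeared, disappeared, appeared + disappeared


def turnover_series(series: SnapshotSeries) -> np.ndarray:
    """Total turnover between successive snapshots."""
    return np.array(
        [
            turnover_count(series.thetas[i], series.thetas[i + 1])[2]
            for i in range(series.thetas.shape[0] - 1)
        ]
    )


def classify_synapse_fate(theta_t1: np.ndarray, theta_t2: np.ndarray) -> np.ndarray:
    """Four-way fate classification between two times.

    ``stable_nonfunctional`` (off/off), ``transient_decaying`` (on/off),
    ``transient_emerging`` (off/on), ``stable_functional`` (on/on); returns
    an array of class labels.
    """
    on1 = np.asarray(theta_t1) > 0.0
    on2 = np.asarray(theta_t2) > 0.0
    idx = on1.astype(int) * 1 + on2.astype(int) * 2
    # idx: 0 -> off/off, 1 -> on/off, 2 -> off/on, 3 -> on/on
    lut = np.array(FATE_CLASSES, dtype=object)[[0, 1, 2, 3]]
    return lut[idx]


def fate_fractions(theta_t1, theta_t2) -> Dict[str, float]:
    labels = classify_synapse_fate(theta_t1, theta_t2)
    n = labels.shape[0]
    return {c: float(np.sum(labels == c)) / n for c in FATE_CLASSES}


# ---------------------------------------------------------------------------
# CI / non-CI synapse-pair correlations
# ---------------------------------------------------------------------------


def _pairs_from_groups(groups: Dict, rng: np.random.Generator, max_pairs: int):
    """Sample synapse index pairs from within each group."""
    pairs: List[Tuple[int, int]] = []
    for members in groups.values():
        m = len(members)
        if m < 2:
            continue
        for i in range(m - 1):
            for j in range(i + 1, m):
                pairs.append((members[i], members[j]))
    if len(pairs) > max_pairs:
        sel = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sel]
    return pairs


def ci_pair_correlations(
    weights: np.ndarray,
    pre: np.ndarray,
    post: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    max_pairs: int = 5000,
    functional_only: bool = True,
) -> Tuple[float, float, int, int]:
    """Pearson correlation of weights across CI and non-CI synapse pairs.

    CI (commonly innervated) pairs share both the pre- and postsynaptic
    neuron; non-CI pairs share the postsynaptic neuron but have different
    presynaptic neurons.  Pairs are subsampled to at most ``max_pairs`` per
    class.  Returns ``(r_ci, r_non_ci, n_ci_pairs, n_non_ci_pairs)``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    weights = np.asarray(weights, dtype=float)
    keep = weights > 0.0 if functional_only else np.ones_like(weights, bool)
    idx = np.nonzero(keep)[0]
    if idx.size < 4:
        raise ValueError("need at least two functional pairs per class")

    ci_groups: Dict[Tuple[int, int], List[int]] = {}
    post_groups: Dict[int, List[int]] = {}
    for i in idx:
        ci_groups.setdefault((int(pre[i]), int(post[i])), []).append(int(i))
        post_groups.setdefault(int(post[i]), []).append(int(i))

    ci_pairs = _pairs_from_groups(ci_groups, rng, max_pairs)
    # non-CI: same post, different pre; sample randomly within post groups
    non_ci: List[Tuple[int, int]] = []
    posts = [g for g in post_groups.values() if len(g) >= 2]
    attempts = 0
    while len(non_ci) < max_pairs and attempts < 50 * max_pairs and posts:
        attempts += 1
        g = posts[int(rng.integers(len(posts)))]
        i, j = rng.choice(len(g), size=2, replace=False)
        a, b = g[int(i)], g[int(j)]
        if pre[a] != pre[b]:
            non_ci.append((a, b))

    if len(ci_pairs) < 2 or len(non_ci) < 2:
        raise ValueError("fewer than two pairs in a class")
    ci_arr = np.array(ci_pairs)
    nci_arr = np.array(non_ci)
    r_ci = pearsonr(weights[ci_arr[:, 0]], weights[ci_arr[:, 1]]).statistic
    r_nci = pearsonr(weights[nci_arr[:, 0]], weights[nci_arr[:, 1]]).statistic
    return float(r_ci), float(r_nci), len(ci_pairs), len(non_ci)


def ci_correlation_significance(
    r_ci_trials: Sequence[float], r_non_ci_trials: Sequence[float]
) -> float:
    """Two-tailed Mann-Whitney U p-value comparing CI vs non-CI correlations
    across independent trials."""
    return float(
        mannwhitneyu(r_ci_trials, r_non_ci_trials, alternative="two-sided").pvalue
    )


def contribution_decomposition(
    r_ci: float, r_non_ci: float
) -> Tuple[float, float, float]:
    """Split synaptic dynamics into process contributions.

    ``activity_specific = r_ci - r_non_ci`` (specific pre/post activity
    histories), ``spontaneous = 1 - r_ci`` (synapse-autonomous), and
    ``neuron_wide = r_non_ci`` (postsynaptic-neuron-wide); the three sum to 1.
    Ordering violations (r_non_ci > r_ci or values outside [0, 1]) are
    reported via a warning but still computed.
    """
    import warnings

    if not (0.0 <= r_non_ci <= r_ci <= 1.0):
        warnings.warn(
            "correlation ordering 0 <= r_nonCI <= r_CI <= 1 violated; "
            "decomposition may be uninterpretable",
            stacklevel=2,
        )
    return r_ci - r_non_ci, 1.0 - r_ci, r_non_ci


# ---------------------------------------------------------------------------
# movement onsets and trial-averaged activity
# ---------------------------------------------------------------------------


def detect_movement_onset(
    lever: np.ndarray,
    sample_ms: float = 5.0,
    threshold: float = 1.5,
    smooth_taps: int = 5,
) -> float:
    """Movement onset time (s) from a lever trace sampled every 5 ms.

    Velocity is the first difference smoothed with a 5-tap moving average;
    its envelope is the magnitude of the analytic signal (Hilbert transform).
    The onset is the first sample where the envelope exceeds the threshold
    in the upward direction (positive velocity); if the threshold is never
    reached, the time of maximum velocity is used.
    """
    lever = np.asarray(lever, dtype=float)
    if lever.size < smooth_taps + 2:
        return 0.0
    vel = np.diff(lever)
    vel = np.convolve(vel, np.ones(smooth_taps) / smooth_taps, mode="same")
    env = np.abs(hilbert(vel))
    above = (env > threshold) & (vel > 0.0)
    if np.any(above):
        onset_idx = int(np.argmax(above))
    else:
        onset_idx = int(np.argmax(vel))
    return (onset_idx + 1) * sample_ms / 1000.0


def trial_averaged_activity(
    spike_times_ms: np.ndarray,
    spike_neuron: np.ndarray,
    onsets_ms: Sequence[float],
    n_neurons: int,
    window_ms: Tuple[int, int] = (-500, 1500),
    kernel_sigma_ms: float = 75.0,
    min_trials: int = 1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized trial-averaged activity map and peak-time ordering.

    Per-ms spike trains are smoothed with a Gaussian kernel (sigma 75 ms),
    aligned to movement onsets and averaged across trials.  Each neuron's
    trace is normalized by its mean (sub-mean values clipped) and rescaled to
    [0, 1]; silent neurons map to all-zero rows.  Returns the (n_neurons,
    n_bins) matrix and the neuron ordering by peak time.
    """
    onsets_ms = np.asarray(onsets_ms, dtype=float)
    if onsets_ms.size < min_trials:
        raise ValueError(f"need at least {min_trials} trials with onsets")
    t_lo, t_hi = window_ms
    n_bins = t_hi - t_lo
    acc = np.zeros((n_neurons, n_bins))
    dur = int(spike_times_ms.max()) + 1 if spike_times_ms.size else 1
    dense = np.zeros((n_neurons, dur))
    valid = spike_neuron < n_neurons
    np.add.at(dense, (spike_neuron[valid], spike_times_ms[valid]), 1.0)
    smooth = gaussian_filter1d(dense, kernel_sigma_ms, axis=1)
    n_used = 0
    for onset in onsets_ms:
        a = int(onset) + t_lo
        b = int(onset) + t_hi
        if a < 0 or b > dur:
            continue
        acc += smooth[:, a:b]
        n_used += 1
    if n_used == 0:
        raise ValueError("no onset window fits inside the recording")
    acc /= n_used

    out = np.zeros_like(acc)
    for k in range(n_neurons):
        m = acc[k].mean()
        if m <= 0.0:
            continue  # silent neuron -> all-zero row
        row = np.clip(acc[k], m, None)
        lo, hi = row.min(), row.max()
        if hi > lo:
            out[k] = (row - lo) / (hi - lo)
    order = np.argsort(np.argmax(out, axis=1), kind="stable")
    return out, order


# ---------------------------------------------------------------------------
# parameter-trajectory analyses
# ---------------------------------------------------------------------------


def parameter_change_amplitude(
    series: SnapshotSeries, normalize: bool = False
) -> np.ndarray:
    """Euclidean norm of successive snapshot differences.

    With ``normalize=True`` the series is scaled by its maximum (so the
    largest step is 1).
    """
    steps = np.linalg.norm(np.diff(series.thetas, axis=0), axis=1)
    if normalize and steps.size and steps.max() > 0:
        steps = steps / steps.max()
    return steps


def pca_parameter_trajectory(
    series: SnapshotSeries,
    fraction: float = 0.05,
    n_components: int = 3,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """PCA of a random subset of parameter trajectories.

    A random ``fraction`` of the synaptic parameters is selected, each time
    sample treated as one observation, and the trajectory projected onto the
    first ``n_components`` principal components.  Returns ``(projection,
    explained_variance_ratio)``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n_t, n_syn = series.thetas.shape
    if n_t <= n_components:
        raise ValueError("fewer snapshots than requested components")
    k = max(n_components, int(round(fraction * n_syn)))
    sel = rng.choice(n_syn, size=min(k, n_syn), replace=False)
    x = series.thetas[:, sel]
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(x)
    return proj, pca.explained_variance_ratio_


def dpca_reward_projection(
    series: SnapshotSeries,
    reward_per_snapshot: np.ndarray,
    n_params: int = 500,
    n_bins: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, np.ndarray]:
    """Reduced demixed PCA separating reward-dependent parameter variance.

    Snapshots are binned by their windowed average reward into ``n_bins``
    equally spaced bins (empty bins are merged with their lower neighbour);
    the reward-dependent axes are the principal axes of the bin means
    (between-bin covariance), the remaining axes come from the residual
    within-bin covariance.  Returns the 2-D projection of the trajectory
    onto (dpc1, dpc2), the fraction of reward variance explained per reward
    axis, and a ``degenerate`` flag when the reward signal carries no
    variance (constant reward).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    reward = np.asarray(reward_per_snapshot, dtype=float)
    n_t, n_syn = series.thetas.shape
    if reward.shape[0] != n_t:
        raise ValueError("need one reward average per snapshot")
    sel = rng.choice(n_syn, size=min(n_params, n_syn), replace=False)
    x = series.thetas[:, sel]
    x = x - x.mean(axis=0, keepdims=True)

    if np.ptp(reward) <= 0.0:
        return {
            "projection": np.zeros((n_t, 2)),
            "reward_variance_fraction": np.zeros(2),
            "degenerate": np.array(True),
        }

    edges = np.linspace(reward.min(), reward.max(), n_bins + 1)
    which = np.clip(np.digitize(reward, edges[1:-1]), 0, n_bins - 1)
    means, sizes = [], []
    for b in range(n_bins):
        m = which == b
        if not np.any(m):
            continue  # empty bin: merged by omission into its neighbours
        means.append(x[m].mean(axis=0))
        sizes.append(int(m.sum()))
    means = np.vstack(means)
    sizes = np.asarray(sizes, dtype=float)

    # between-bin (reward-marginal) covariance, bins weighted by occupancy
    mw = means * np.sqrt(sizes[:, None] / sizes.sum())
    u, s, vt = np.linalg.svd(mw, full_matrices=False)
    evals = s**2
    frac = evals / evals.sum()
    reward_axes = vt[:2] if vt.shape[0] >= 2 else np.vstack([vt, vt])
    proj = x @ reward_axes.T
    return {
        "projection": proj,
        "reward_variance_fraction": frac[:2] if frac.size >= 2 else frac,
        "degenerate": np.array(False),
    }
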