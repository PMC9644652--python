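"""Nonparametric statistics shared by the source- and sensor-level analyses.

The central test asks, per voxel (or sensor/time sample), whether beta
power in the active window differs from baseline across trials. The paired
t statistic is oriented so that a power *decrease* yields positive t. The
family-wise error over elements is controlled by a cluster-based Monte
Carlo permutation test: suprathreshold elements (t > t_crit, default 1.65
one-tailed at p = 0.05) are grouped into connected clusters, each cluster
is scored by its mass (sum of t), and the observed masses are compared
against the distribution of the maximum cluster mass under random
within-trial condition swaps (sign flips of the paired differences). If no
cluster survives, a fallback uncorrected threshold (default t = 1.97,
p = 0.025 one-tailed) is available.

Permutation p-values include the observed draw, (b + 1) / (n_perm + 1), so
the smallest attainable p is 1 / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import (
    InvalidInputError,
    InvalidParameterError,
    SensorEpochs,
    SourceGrid,
    SourceStatMap,
)

#: face / face+edge / face+edge+corner neighbourhoods on a cubic lattice
_CONNECTIVITY_OFFSETS = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class Adjacency:
    """Symmetric neighbour relation over ``n_elem`` elements, stored as a
    deduplicated undirected edge list (no self loops)."""

    n_elem: int
    edges: np.ndarray  # (n_edges, 2) int, each row i < j

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, int).reshape(-1, 2)
        if e.size and (e.min() < 0 or e.max() >= self.n_elem):
            raise InvalidInputError("edge endpoints out of range")
        if np.any(e[:, 0] == e[:, 1]):
            raise InvalidInputError("self loops are not allowed")
        e = np.unique(np.sort(e, axis=1), axis=0) if e.size else e
        object.__setattr__(self, "edges", e)


def lattice_offsets(connectivity: int) -> np.ndarray:
    """Neighbour offsets (half-space) for 6/18/26-connectivity."""
    if connectivity not in _CONNECTIVITY_OFFSETS:
        raise InvalidParameterError("connectivity must be 6, 18 or 26")
    max_norm = _CONNECTIVITY_OFFSETS[connectivity]
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if dx * dx + dy * dy + dz * dz <= max_norm:
                    offs.append((dx, dy, dz))
    offs = np.array(offs)
    # keep one direction per pair (undirected edges)
    keep = (offs[:, 0] > 0) | ((offs[:, 0] == 0) & (offs[:, 1] > 0)) | (
        (offs[:, 0] == 0) & (offs[:, 1] == 0) & (offs[:, 2] > 0))
    return offs[keep]


def grid_adjacency(grid: SourceGrid, indices: np.ndarray | None = None,
                   connectivity: int = 6) -> Adjacency:
    """Adjacency between the given grid points (defaults to inside voxels)."""
    if indices is None:
        indices = grid.inside_indices
    indices = np.asarray(indices, int)
    ijk = np.column_stack(np.unravel_index(indices, grid.shape))
    lookup = {tuple(v): i for i, v in enumerate(ijk)}
    edges = []
    for off in lattice_offsets(connectivity):
        for i, v in enumerate(ijk):
            j = lookup.get((v[0] + off[0], v[1] + off[1], v[2] + off[2]))
            if j is not None:
                edges.append((i, j))
    edges = np.array(edges, int) if edges else np.empty((0, 2), int)
    return Adjacency(n_elem=indices.size, edges=edges)


def knn_adjacency(positions: np.ndarray, k: int = 4) -> Adjacency:
    """Mutualised k-nearest-neighbour adjacency for sensor layouts."""
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1)[:, :k]
    edges = [(i, j) for i in range(n) for j in nn[i]]
    return Adjacency(n_elem=n, edges=np.array(edges))


def extend_adjacency_over_time(adj: Adjacency, n_times: int) -> Adjacency:
    """Sensor x time adjacency: spatial neighbours at the same sample plus
    each element's +-1 time-sample neighbours."""
    n = adj.n_elem
    edges = []
    for t in range(n_times):
        edges.append(adj.edges + t * n)
    base = np.arange(n)
    for t in range(n_times - 1):
        edges.append(np.column_stack([base + t * n, base + (t + 1) * n]))
    return Adjacency(n_elem=n * n_times, edges=np.concatenate(edges, axis=0))


def paired_t_map(active_power: np.ndarray, baseline_power: np.ndarray) -> np.ndarray:
    """Per-element paired t of (baseline - active): a power decrease in the
    active condition gives positive t; df = n_trials - 1.

    Elements with zero difference variance get ``sign(mean) * inf`` (0 for a
    zero mean).
    """
    active_power = np.asarray(active_power, float)
    baseline_power = np.asarray(baseline_power, float)
    if active_power.shape != baseline_power.shape:
        raise InvalidInputError("condition arrays must have identical shapes")
    n = active_power.shape[0]
    if n < 2:
        raise InvalidInputError("need at least 2 trials")
    d = baseline_power - active_power
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    with np.errstate(invalid="ignore"):
        t[~ok] = np.sign(mean[~ok]) * np.inf
    t[~ok & (mean == 0)] = 0.0
    return t


def _cluster_labels(mask: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Union-find connected components of the True elements; -1 elsewhere."""
    n = mask.size
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if edges.size:
        both = mask[edges[:, 0]] & mask[edges[:, 1]]
        for i, j in edges[both]:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    labels = np.full(n, -1)
    nxt = 0
    roots: dict[int, int] = {}
    for i in np.flatnonzero(mask):
        r = find(i)
        if r not in roots:
            roots[r] = nxt
            nxt += 1
        labels[i] = roots[r]
    return labels


def _max_cluster_mass(t: np.ndarray, mask: np.ndarray, edges: np.ndarray) -> float:
    if not mask.any():
        return 0.0
    labels = _cluster_labels(mask, edges)
    k = labels.max() + 1
    masses = np.zeros(k)
    np.add.at(masses, labels[mask], t[mask])
    return float(masses.max())


@dataclass
class ClusterTestResult:
    """Outcome of the cluster permutation test on a set of elements."""

    tvals: np.ndarray
    surviving: np.ndarray  # bool, elements inside significant clusters
    clusters: list[dict[str, Any]] = field(default_factory=list)
    status: str = "ok"  # ok | no-cluster | no-survivor
    info: dict[str, Any] = field(default_factory=dict)

    @property
    def thresholded(self) -> np.ndarray:
        out = np.zeros_like(self.tvals)
        out[self.surviving] = self.tvals[self.surviving]
        return out


def cluster_permutation_test(
    active_power: np.ndarray,
    baseline_power: np.ndarray,
    adjacency: Adjacency,
    n_perm: int = 10_000,
    t_crit: float = 1.65,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-mass permutation test of a paired power decrease.

    ``active_power`` and ``baseline_power`` are (n_trials, n_elem). The null
    distribution is the maximum suprathreshold cluster mass over ``n_perm``
    random sign flips of the per-trial differences (the paired-design
    condition swap); cluster p-values use the (b + 1)/(n_perm + 1)
    convention.
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    active_power = np.asarray(active_power, float)
    baseline_power = np.asarray(baseline_power, float)
    if active_power.shape != baseline_power.shape:
        raise InvalidInputError("condition arrays must have identical shapes")
    n_trials, n_elem = active_power.shape
    if n_elem != adjacency.n_elem:
        raise InvalidInputError("adjacency size does not match data")
    d = baseline_power - active_power
    t_obs = paired_t_map(active_power, baseline_power)
    info = {"n_perm": n_perm, "t_crit": t_crit, "alpha": alpha, "seed": seed,
            "statistic": "cluster-mass", "tail": "positive"}
    mask_obs = t_obs > t_crit
    if not mask_obs.any():
        return ClusterTestResult(tvals=t_obs, surviving=np.zeros(n_elem, bool),
                                 clusters=[], status="no-cluster", info=info)
    labels = _cluster_labels(mask_obs, adjacency.edges)
    n_clusters = labels.max() + 1
    masses = np.zeros(n_clusters)
    np.add.at(masses, labels[mask_obs], t_obs[mask_obs])

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_trials))
    sumsq = np.sum(d * d, axis=0)
    mean_p = signs @ d / n_trials
    with np.errstate(invalid="ignore", divide="ignore"):
        var_p = (sumsq - n_trials * mean_p**2) / (n_trials - 1)
        t_p = mean_p / np.sqrt(var_p / n_trials)
    t_p = np.nan_to_num(t_p, nan=0.0, posinf=np.inf, neginf=-np.inf)
    null_max = np.empty(n_perm)
    edges = adjacency.edges
    for b in range(n_perm):
        null_max[b] = _max_cluster_mass(t_p[b], t_p[b] > t_crit, edges)

    clusters = []
    surviving = np.zeros(n_elem, bool)
    for c in range(n_clusters):
        mass = masses[c]
        p = (1.0 + np.sum(null_max >= mass)) / (n_perm + 1.0)
        members = np.flatnonzero(labels == c)
        clusters.append({"members": members, "mass": float(mass), "p": float(p)})
        if p <= alpha:
            surviving[members] = True
    status = "ok" if surviving.any() else "no-survivor"
    return ClusterTestResult(tvals=t_obs, surviving=surviving, clusters=clusters,
                             status=status, info=info)


def fallback_threshold(tmap: SourceStatMap, t_uncorrected: float = 1.97) -> SourceStatMap:
    """Uncorrected thresholding used when no cluster survives: keep
    evaluated voxels with t > t_uncorrected and mark the map uncorrected."""
    values = np.where(tmap.mask & (tmap.values > t_uncorrected), tmap.values, 0.0)
    return tmap.copy_with(values, critical_t=t_uncorrected, corrected=False,
                          rule="uncorrected")


def rms_timecourse(epochs: SensorEpochs, sensor_set: np.ndarray) -> np.ndarray:
    """RMS over a sensor set of the trial-averaged evoked response after
    z-scoring each channel to its pre-stimulus interval."""
    sensor_set = np.asarray(sensor_set, int)
    if sensor_set.size == 0:
        raise InvalidParameterError("sensor set must not be empty")
    evoked = epochs.data.mean(axis=0)  # (n_chan, n_t)
    pre = epochs.times < 0
    if not pre.any():
        raise InvalidInputError("epochs contain no pre-stimulus samples")
    mu = evoked[:, pre].mean(axis=1, keepdims=True)
    sd = evoked[:, pre].std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (evoked - mu) / sd
    return np.sqrt(np.mean(z[sensor_set] ** 2, axis=0))


def pointwise_fdr_test(
    left: np.ndarray,
    right: np.ndarray,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise hemisphere-difference randomization test with BH-FDR.

    ``left``/``right`` are paired (n_obs, n_times) amplitude measures (e.g.
    per-subject RMS time courses). Per time sample a two-sided sign-flip
    randomization p-value of the mean left-right difference is computed,
    then thresholded with the Benjamini-Hochberg step-up procedure at level
    ``q``. Returns ``(significant_mask, p_values)``.
    """
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    if left.shape != right.shape:
        raise InvalidInputError("left/right arrays must have identical shapes")
    d = left - right
    n_obs = d.shape[0]
    obs = np.abs(d.mean(axis=0))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_obs))
    null = np.abs(signs @ d / n_obs)  # (n_perm, n_times)
    p = (1.0 + np.sum(null >= obs[None, :] - 1e-12, axis=0)) / (n_perm + 1.0)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p
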