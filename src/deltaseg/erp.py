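"""Condition-level ERP contrasts with spatio-temporal cluster-based
permutation inference.

The paired design is handled by participant-level sign flips of the
FAST−SLOW difference maps.  Clusters are connected components over the
channel x time lattice: two supra-threshold samples touch iff they share a
channel and are one sample apart in time, or share a time point and are
neighbours in the sensor adjacency graph.  Cluster mass is the sum of member
t-values; inference compares each observed cluster's mass against the
permutation distribution of the per-sign maximum mass, doubling the
within-sign p for two-sided control.

A sign-flip permutation changes only the mean of the difference maps, not
their sum of squares, so the whole permutation t-map stack reduces to one
matrix product — this is what makes 10 000 permutations cheap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

from .containers import EpochSet, SensorLayout

__all__ = [
    "SensorAdjacency",
    "TStatMap",
    "Cluster",
    "ClusterTestResult",
    "build_adjacency",
    "paired_t_map",
    "find_clusters",
    "cluster_permutation_test",
    "extract_peak",
    "extract_single_trial_amplitude",
]


@dataclass(frozen=True)
class SensorAdjacency:
    """Symmetric, irreflexive channel neighbour graph."""

    names: tuple[str, ...]
    matrix: np.ndarray  # (n, n) bool

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=bool)
        if m.shape != (len(self.names), len(self.names)):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if m.diagonal().any():
            raise ValueError("adjacency must have no self-edges")
        object.__setattr__(self, "matrix", m)

    @property
    def n_channels(self) -> int:
        return len(self.names)


@dataclass
class TStatMap:
    t: np.ndarray  # (n_channels, n_times)
    df: int
    times: np.ndarray  # s
    ch_names: tuple[str, ...]
    degenerate: np.ndarray | None = None  # bool mask of zero-variance cells


@dataclass
class Cluster:
    members: np.ndarray  # (k, 2) int array of (channel, time-sample) pairs
    sign: int  # +1 or -1
    mass: float
    p: float = np.nan

    @property
    def channels(self) -> np.ndarray:
        return np.unique(self.members[:, 0])


@dataclass
class ClusterTestResult:
    tmap: TStatMap
    clusters: list[Cluster]
    n_perm: int
    alpha: float
    window: tuple[float, float]
    seed: int | None
    threshold: float
    exhaustive: bool = False

    def significant(self, sign: int | None = None) -> list[Cluster]:
        out = [c for c in self.clusters if c.p <= self.alpha]
        if sign is not None:
            out = [c for c in out if c.sign == sign]
        return out


# ----------------------------------------------------------------------


def build_adjacency(
    layout: SensorLayout,
    method: str = "triangulation",
    threshold: float | None = None,
) -> SensorAdjacency:
    """Neighbour graph from 2-D sensor positions.

    ``triangulation`` links channels sharing a Delaunay edge (falls back to
    the complete graph below 4 channels); ``distance`` links channels closer
    than ``threshold`` (default: 1.5x the median nearest-neighbour
    distance).  Deterministic for a given layout.
    """
    pos = layout.positions
    n = layout.n_channels
    if n < 2:
        raise ValueError("need at least 2 channels")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    if np.any(d[~np.eye(n, dtype=bool)] == 0):
        raise ValueError("duplicate sensor positions")
    mat = np.zeros((n, n), dtype=bool)
    if method == "triangulation":
        if n < 4:
            mat[:] = True
        else:
            tri = Delaunay(pos)
            for simplex in tri.simplices:
                for a, b in itertools.combinations(simplex, 2):
                    mat[a, b] = mat[b, a] = True
    elif method == "distance":
        if threshold is None:
            nn = np.sort(d, axis=1)[:, 1]  # nearest non-self neighbour
            threshold = 1.5 * float(np.median(nn))
        mat = d <= threshold
    else:
        raise ValueError("method must be 'triangulation' or 'distance'")
    np.fill_diagonal(mat, False)
    return SensorAdjacency(names=layout.names, matrix=mat)


def paired_t_map(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times: np.ndarray,
    ch_names: tuple[str, ...],
) -> TStatMap:
    """Samplewise paired t-statistic map, d = A − B per participant.

    Zero-variance cells are flagged: d identically zero gives t = 0, a
    nonzero constant difference gives ±inf; both are marked in
    ``degenerate`` and skipped by cluster formation.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have the same shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    d = a - b
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degen = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t[degen & (m == 0)] = 0.0
    t[degen & (m > 0)] = np.inf
    t[degen & (m < 0)] = -np.inf
    if degen.any():
        warnings.warn(
            f"{int(degen.sum())} zero-variance cells excluded from clustering",
            RuntimeWarning,
            stacklevel=2,
        )
    return TStatMap(
        t=t, df=n - 1, times=np.asarray(times), ch_names=tuple(ch_names),
        degenerate=degen,
    )


def _lattice(adjacency: SensorAdjacency, n_times: int) -> sparse.csr_matrix:
    """Sparse channel x time lattice graph, nodes flattened as c * n_times + t."""
    n_ch = adjacency.n_channels
    rows, cols = [], []
    # temporal edges within channel
    base = np.arange(n_times - 1)
    for c in range(n_ch):
        rows.append(c * n_times + base)
        cols.append(c * n_times + base + 1)
    # spatial edges within time point
    ci, cj = np.nonzero(np.triu(adjacency.matrix))
    tt = np.arange(n_times)
    for a, b in zip(ci, cj):
        rows.append(a * n_times + tt)
        cols.append(b * n_times + tt)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    n = n_ch * n_times
    m = sparse.coo_matrix(
        (np.ones(len(r), dtype=np.int8), (r, c)), shape=(n, n)
    )
    m = m + m.T
    return m.tocsr()


def _cluster_masses(
    flat_vals: np.ndarray,
    mask: np.ndarray,
    lattice: sparse.csr_matrix,
    n_times: int,
    min_channels: int,
):
    """Connected components of the masked lattice -> (list of index arrays, masses)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return [], np.empty(0)
    sub = lattice[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    masses = np.bincount(labels, weights=flat_vals[idx], minlength=n_comp)
    chans = idx // n_times
    pair = np.unique(labels.astype(np.int64) * (chans.max() + 1) + chans)
    n_ch_per = np.bincount(pair // (chans.max() + 1), minlength=n_comp)
    keep = n_ch_per >= min_channels
    members = [idx[labels == k] for k in range(n_comp) if keep[k]]
    return members, masses[keep]


def find_clusters(
    tmap: TStatMap,
    threshold: float,
    adjacency: SensorAdjacency,
    min_channels: int = 1,
) -> list[Cluster]:
    """Supra-threshold connected clusters, per sign, without p-values.

    Clusters spanning fewer than ``min_channels`` distinct channels are
    discarded.  Output is sorted by |mass| descending; ties break on the
    lowest channel index then earliest time of the first member.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if tuple(adjacency.names) != tuple(tmap.ch_names):
        raise ValueError("adjacency and t-map channel names disagree")
    n_times = tmap.t.shape[1]
    lat = _lattice(adjacency, n_times)
    flat = tmap.t.ravel()
    finite = np.isfinite(flat)
    out: list[Cluster] = []
    for sign in (+1, -1):
        mask = finite & (sign * flat > threshold)
        members, masses = _cluster_masses(flat, mask, lat, n_times, min_channels)
        for mem, mass in zip(members, masses):
            pairs = np.column_stack([mem // n_times, mem % n_times])
            out.append(Cluster(members=pairs, sign=sign, mass=float(mass)))
    out.sort(key=lambda c: (-abs(c.mass), c.members[0, 0], c.members[0, 1]))
    return out


def _perm_t(diffs_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for a block of sign-flip permutations.

    diffs_flat: (n_subj, n_cells); signs: (P, n_subj) of ±1.
    Uses the identity that sign flips leave sum(d²) untouched.
    """
    n = diffs_flat.shape[0]
    s2 = (diffs_flat**2).sum(axis=0)  # (cells,)
    m = signs @ diffs_flat / n  # (P, cells)
    var = (s2 - n * m**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times: np.ndarray,
    ch_names: tuple[str, ...],
    adjacency: SensorAdjacency,
    window: tuple[float, float] = (0.15, 1.0),
    alpha: float = 0.05,
    n_perm: int = 10_000,
    min_channels: int = 3,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> ClusterTestResult:
    """Spatio-temporal cluster-based permutation test, paired design.

    ``cond_a``/``cond_b`` are per-participant mean maps of shape
    (n_participants, n_channels, n_times).  The cluster-forming threshold is
    the two-tailed samplewise t quantile t_{1-0.025}(n-1); the null is built
    from random sign flips of the participant difference maps, recording the
    per-sign maximum |cluster mass| of each permutation; each observed
    cluster's Monte-Carlo p is (1 + #{null >= observed}) / (1 + n_perm),
    doubled (capped at 1) for two-sided control.  ``exhaustive`` enumerates
    all 2^n sign patterns (n <= 16) and returns the exact p instead.
    """
    times = np.asarray(times)
    n = cond_a.shape[0]
    if exhaustive and n > 16:
        raise ValueError("exhaustive enumeration limited to n <= 16 participants")
    if not exhaustive and n < 5:
        raise ValueError("need >= 5 participants for Monte-Carlo permutation")
    if not exhaustive and n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", RuntimeWarning,
                      stacklevel=2)
    sel = (times >= window[0]) & (times <= window[1])
    if not sel.any():
        raise ValueError("analysis window outside the epoch time axis")
    a = np.asarray(cond_a, dtype=float)[:, :, sel]
    b = np.asarray(cond_b, dtype=float)[:, :, sel]
    wtimes = times[sel]
    n_times = wtimes.size

    threshold = float(stats.t.ppf(1 - 0.025, n - 1))
    tmap = paired_t_map(a, b, wtimes, ch_names)
    clusters = find_clusters(tmap, threshold, adjacency, min_channels)

    lat = _lattice(adjacency, n_times)
    diffs = (a - b).reshape(n, -1)

    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    n_draws = signs.shape[0]

    max_pos = np.zeros(n_draws)
    max_neg = np.zeros(n_draws)
    block = 2000
    for lo in range(0, n_draws, block):
        tb = _perm_t(diffs, signs[lo : lo + block])
        for j in range(tb.shape[0]):
            flat = tb[j]
            _, masses = _cluster_masses(
                flat, flat > threshold, lat, n_times, min_channels
            )
            if masses.size:
                max_pos[lo + j] = masses.max()
            _, masses = _cluster_masses(
                flat, flat < -threshold, lat, n_times, min_channels
            )
            if masses.size:
                max_neg[lo + j] = masses.min()

    for c in clusters:
        if c.sign > 0:
            count = int((max_pos >= c.mass).sum())
        else:
            count = int((max_neg <= c.mass).sum())
        if exhaustive:
            p_one = count / n_draws
        else:
            p_one = (1 + count) / (1 + n_draws)
        c.p = min(1.0, 2 * p_one)

    return ClusterTestResult(
        tmap=tmap,
        clusters=clusters,
        n_perm=n_draws,
        alpha=alpha,
        window=tuple(window),
        seed=seed,
        threshold=threshold,
        exhaustive=exhaustive,
    )


@dataclass(frozen=True)
class Peak:
    channel: str
    channel_index: int
    time: float
    time_index: int
    t_value: float


def extract_peak(result: ClusterTestResult, sign: int = +1) -> Peak | None:
    """(channel, time) of maximal |t| within the largest significant cluster.

    Returns ``None`` (an explicit no-peak outcome) when no cluster of the
    requested sign reaches significance.  Ties break on the lowest channel
    index, then the earliest time.
    """
    sig = result.significant(sign)
    if not sig:
        return None
    best = max(sig, key=lambda c: abs(c.mass))
    t = result.tmap.t
    vals = np.abs(t[best.members[:, 0], best.members[:, 1]])
    order = np.lexsort((best.members[:, 1], best.members[:, 0], -vals))
    ch, ti = best.members[order[0]]
    return Peak(
        channel=result.tmap.ch_names[ch],
        channel_index=int(ch),
        time=float(result.tmap.times[ti]),
        time_index=int(ti),
        t_value=float(t[ch, ti]),
    )


def extract_single_trial_amplitude(
    epochs: EpochSet, channel: str, time: float, half_width: float = 0.0
) -> np.ndarray:
    """Per-trial voltage at (channel, time), optionally a window mean.

    ``half_width = 0`` returns the voltage at the nearest sample, matching
    an amplitude "masked for the time point and electrode" of an ERP peak;
    otherwise the mean over ``time ± half_width``.
    """
    ci = tuple(epochs.ch_names).index(channel) if channel in epochs.ch_names else None
    if ci is None:
        raise KeyError(f"unknown channel {channel!r}")
    if half_width == 0:
        return epochs.data[:, ci, epochs.time_index(time)].copy()
    i0 = epochs.time_index(time - half_width)
    i1 = epochs.time_index(time + half_width)
    return epochs.data[:, ci, i0 : i1 + 1].mean(axis=-1)
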