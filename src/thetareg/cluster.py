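"""Sensor-level nonparametric cluster-mass permutation test.

Per-channel two-sided independent-samples t statistics (pooled
variance) are thresholded at alpha; supra-threshold channels of equal
sign are grouped into connected clusters on a channel neighbourhood
graph, the cluster mass being the sum of t values.  The null
distribution is the per-permutation maximum absolute cluster mass after
full re-computation, and p-values use the add-one rule
p = (1 + #{null >= |mass|}) / (1 + n_perm) for family-wise control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import Delaunay

from .containers import DataError

__all__ = [
    "NeighborGraph",
    "ClusterResult",
    "t_map",
    "build_neighbors",
    "form_clusters",
    "cluster_permutation_test",
]


@dataclass
class NeighborGraph:
    """Symmetric, irreflexive channel adjacency."""

    labels: list[str]
    adjacency: np.ndarray  # (n, n) bool
    method: str = ""
    param: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, bool)
        if a.shape != (len(self.labels),) * 2:
            raise DataError("adjacency shape does not match labels")
        if not np.array_equal(a, a.T):
            raise DataError("adjacency must be symmetric")
        if a.diagonal().any():
            raise DataError("adjacency must have no self-edges")
        self.adjacency = a

    def neighbor_lists(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.adjacency]


@dataclass
class Cluster:
    members: list[int]
    mass: float
    p_value: float = np.nan


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    labels: list[str]
    n_permutations: int
    seed: int | None = None

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=np.nan)

    def best_cluster(self) -> Cluster | None:
        """Smallest-p cluster (ties broken by larger absolute mass)."""
        return min(self.clusters, key=lambda c: (c.p_value, -abs(c.mass)),
                   default=None)

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "t_values": dict(zip(self.labels, map(float, self.t_values))),
            "clusters": [
                {"channels": [self.labels[i] for i in c.members],
                 "mass": float(c.mass), "p_value": float(c.p_value)}
                for c in self.clusters
            ],
        }


def t_map(group_a: np.ndarray, group_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel pooled-variance independent-samples t (a minus b) and
    two-sided p, with n_a + n_b - 2 degrees of freedom."""
    a = np.atleast_2d(np.asarray(group_a, float))  # (n_a, n_channels)
    b = np.atleast_2d(np.asarray(group_b, float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise DataError("need at least 2 participants per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero_var = denom == 0
    if zero_var.any():
        warnings.warn(f"zero pooled variance at {int(zero_var.sum())} channel(s); "
                      "t reported as ±inf")
        t[zero_var] = np.where(diff[zero_var] > 0, np.inf,
                               np.where(diff[zero_var] < 0, -np.inf, 0.0))
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


def _azimuthal_projection(pos: np.ndarray) -> np.ndarray:
    unit = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    theta = np.arccos(np.clip(unit[:, 2], -1, 1))
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def build_neighbors(
    labels: list[str],
    positions: np.ndarray,
    method: str = "delaunay",
    param: float | None = None,
) -> NeighborGraph:
    """Channel neighbourhood graph.

    ``"delaunay"``: edges of the Delaunay triangulation of the 2-D
    azimuthal projection.  ``"distance"``: channels within ``param``
    (same units as positions) are neighbours.
    """
    pos = np.asarray(positions, float)
    if len(labels) < 3:
        raise DataError("need at least 3 channels")
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    if (d[~np.eye(len(labels), dtype=bool)] == 0).any():
        raise DataError("duplicate channel positions")
    n = len(labels)
    adj = np.zeros((n, n), bool)
    if method == "delaunay":
        pts = _azimuthal_projection(pos)
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for i in range(3):
                a, b = simplex[i], simplex[(i + 1) % 3]
                adj[a, b] = adj[b, a] = True
    elif method == "distance":
        if param is None:
            raise DataError("distance method requires a threshold param")
        adj = d <= param
        np.fill_diagonal(adj, False)
    else:
        raise DataError(f"unknown neighbour method {method!r}")
    return NeighborGraph(list(labels), adj, method, param)


def _connected_components(members: np.ndarray, neigh: list[np.ndarray]) -> list[list[int]]:
    member_set = set(int(m) for m in members)
    seen, comps = set(), []
    for start in members:
        start = int(start)
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in neigh[u]:
                v = int(v)
                if v in member_set and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def form_clusters(
    t_values: np.ndarray,
    p_values: np.ndarray,
    graph: NeighborGraph,
    alpha: float = 0.05,
) -> list[Cluster]:
    """Connected components of supra-threshold channels, split by t sign."""
    if len(t_values) != len(graph.labels):
        raise DataError("t map does not align with the neighbour graph")
    neigh = graph.neighbor_lists()
    clusters = []
    for sign in (1, -1):
        members = np.flatnonzero((p_values < alpha) & (sign * t_values > 0))
        for comp in _connected_components(members, neigh):
            clusters.append(Cluster(comp, float(t_values[comp].sum())))
    return clusters


def _max_cluster_mass(t, p, neigh, alpha):
    best = 0.0
    for sign in (1, -1):
        members = np.flatnonzero((p < alpha) & (sign * t > 0))
        if members.size == 0:
            continue
        for comp in _connected_components(members, neigh):
            best = max(best, abs(t[comp].sum()))
    return best


def cluster_permutation_test(
    summaries_a: np.ndarray,
    summaries_b: np.ndarray,
    graph: NeighborGraph,
    n_perm: int = 10_000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> ClusterResult:
    """Cluster-mass permutation test between two groups of per-channel
    summaries (participants × channels).

    The null statistic is the maximum absolute cluster mass per
    permutation; observed-cluster p-values use (b + 1)/(N + 1).
    """
    a = np.atleast_2d(np.asarray(summaries_a, float))
    b = np.atleast_2d(np.asarray(summaries_b, float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise DataError("need at least 2 participants per group for permutation")
    if n_perm < 100:
        raise DataError("n_perm must be at least 100")

    t_obs, p_obs = t_map(a, b)
    neigh = graph.neighbor_lists()
    clusters = form_clusters(t_obs, p_obs, graph, alpha)

    pooled = np.vstack([a, b])
    n_tot = na + nb
    df = n_tot - 2
    t_crit = stats.t.isf(alpha / 2, df)
    rng = np.random.default_rng(seed)

    # vectorised permutation t maps via group-mean matrix products
    null_max = np.empty(n_perm)
    block = 256
    ssq_tot = (pooled**2).sum(axis=0)
    sum_tot = pooled.sum(axis=0)
    for start in range(0, n_perm, block):
        nb_perm = min(block, n_perm - start)
        sel = np.empty((nb_perm, n_tot), bool)
        for i in range(nb_perm):
            idx = rng.permutation(n_tot)[:na]
            row = np.zeros(n_tot, bool)
            row[idx] = True
            sel[i] = row
        sum_a = sel.astype(float) @ pooled           # (perm, ch)
        ssq_a = sel.astype(float) @ (pooled**2)
        sum_b = sum_tot - sum_a
        ssq_b = ssq_tot - ssq_a
        var_a = (ssq_a - sum_a**2 / na) / (na - 1)
        var_b = (ssq_b - sum_b**2 / nb) / (nb - 1)
        sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / df
        denom = np.sqrt(np.maximum(sp2, 0) * (1 / na + 1 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all = (sum_a / na - sum_b / nb) / denom
        t_all = np.nan_to_num(t_all, nan=0.0, posinf=np.inf, neginf=-np.inf)
        for i in range(nb_perm):
            t = t_all[i]
            null_max[start + i] = _max_cluster_mass(
                t, np.where(np.abs(t) > t_crit, 0.0, 1.0), neigh, alpha)

    for c in clusters:
        # count ties with a relative tolerance so summation order cannot
        # flip an "as extreme or more extreme" comparison
        thresh = abs(c.mass) * (1 - 1e-9)
        c.p_value = (1 + np.sum(null_max >= thresh)) / (1 + n_perm)
    return ClusterResult(clusters, t_obs, list(graph.labels), n_perm, seed)
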