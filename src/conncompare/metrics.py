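"""Binary and weighted graph metrics with random-network normalization.

Path-based metrics convert weights to lengths as 1/w (stronger connections
are shorter). Clustering of weighted graphs uses the Onnela geometric-mean
triangle formula on max-normalized weights. Characteristic path length L and
clustering C are normalized by the mean of 20 Maslov-Sneppen
degree-preserving rewired null networks, giving lambda = L / <L_null>,
gamma = C / <C_null>, and the small-worldness index sigma = gamma / lambda;
sigma > 1 marks small-world organization.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .density import threshold_at_density
from .io import Connectome, MetricCurve, ValidationError

logger = logging.getLogger("conncompare")

NORMALIZED_METRICS = ("lambda", "gamma", "sigma")
ALL_GRID_METRICS = ("lambda", "gamma", "sigma", "Q", "Eglob", "Eloc")


def weight_to_length(matrix: np.ndarray) -> np.ndarray:
    """Map connection weights to path lengths, length = 1/weight."""
    with np.errstate(divide="ignore"):
        lengths = np.where(matrix > 0, 1.0 / matrix, 0.0)
    return lengths


def shortest_paths(matrix: np.ndarray, weighted: bool = True) -> np.ndarray:
    """All-pairs shortest path lengths; unreachable pairs are inf."""
    if weighted:
        graph = csr_matrix(weight_to_length(matrix))
        return _csgraph_sp(graph, method="D", directed=False)
    graph = csr_matrix((matrix != 0).astype(np.int8))
    return _csgraph_sp(graph, method="D", directed=False, unweighted=True)


def characteristic_path_length(matrix: np.ndarray, weighted: bool = True) -> float:
    """Mean shortest path length over reachable node pairs.

    Disconnected pairs are excluded with a warning; analyses at or above the
    minimum connection density never hit that branch.
    """
    d = shortest_paths(matrix, weighted)
    n = matrix.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValidationError("fully disconnected graph: path length undefined")
    if not finite.all():
        logger.warning(
            "graph disconnected: %d/%d pairs unreachable excluded from L",
            int((~finite).sum()), vals.size,
        )
    return float(vals[finite].mean())


def clustering_coefficient(matrix: np.ndarray, weighted: bool = True) -> float:
    """Mean nodal clustering; nodes with degree < 2 contribute 0.

    Binary: triangles around a node over possible neighbor pairs. Weighted:
    Onnela et al. geometric mean of triangle weights (weights first divided
    by the maximum weight).
    """
    a = (matrix != 0).astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    if weighted and not np.array_equal(matrix, a):
        top = matrix.max()
        cube = np.cbrt(matrix / top) if top > 0 else matrix
        tri = np.diag(cube @ cube @ cube)
    else:
        tri = np.diag(a @ a @ a)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_i = np.where(denom > 0, tri / denom, 0.0)
    return float(c_i.mean())


def global_efficiency(matrix: np.ndarray, weighted: bool = True) -> float:
    """Mean inverse shortest path length; unreachable pairs contribute 0."""
    n = matrix.shape[0]
    if n < 2:
        return 0.0
    d = shortest_paths(matrix, weighted)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def local_efficiency(matrix: np.ndarray, weighted: bool = True) -> float:
    """Mean over nodes of the global efficiency of each neighbor subgraph."""
    n = matrix.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nb = np.nonzero(matrix[i])[0]
        if nb.size < 2:
            continue
        sub = matrix[np.ix_(nb, nb)]
        eff[i] = global_efficiency(sub, weighted)
    return float(eff.mean())


def degrees(matrix: np.ndarray) -> np.ndarray:
    return (matrix != 0).sum(axis=1).astype(float)


def strengths(matrix: np.ndarray) -> np.ndarray:
    return matrix.sum(axis=1)


@dataclass
class ModulePartition:
    """A non-overlapping decomposition of nodes into modules."""

    membership: np.ndarray
    q: float
    seed: int | None = None

    def modules(self) -> list[list[int]]:
        return [np.nonzero(self.membership == m)[0].tolist()
                for m in np.unique(self.membership)]


def modularity(
    matrix: np.ndarray, seed: int = 0, n_restarts: int = 100,
) -> ModulePartition:
    """Best-of-``n_restarts`` Louvain partition (Newman modularity Q).

    Louvain is greedy and order-dependent; restarting from distinct seeds
    and keeping the maximum-Q partition tames that stochasticity.
    """
    if not np.any(matrix):
        raise ValidationError("modularity undefined for an empty graph")
    g = nx.from_numpy_array(matrix)
    rng = np.random.default_rng(seed)
    best_q, best_part = -np.inf, None
    for _ in range(n_restarts):
        s = int(rng.integers(2**31))
        comms = nx.community.louvain_communities(g, weight="weight", seed=s)
        q = nx.community.modularity(g, comms, weight="weight")
        if q > best_q:
            best_q, best_part = q, comms
    membership = np.empty(matrix.shape[0], dtype=int)
    for m, nodes in enumerate(best_part):
        membership[list(nodes)] = m
    return ModulePartition(membership, float(best_q), seed)


def random_reference(
    matrix: np.ndarray,
    n_random: int = 20,
    seed: int = 0,
    n_swaps_per_edge: int = 10,
) -> list[np.ndarray]:
    """Maslov-Sneppen degree-preserving rewired null networks.

    Topology is randomized by attempted double-edge swaps (10 per edge);
    for weighted graphs the original weight multiset is then reassigned to
    the rewired edges in random order, preserving both the degree sequence
    and the weight distribution.
    """
    n = matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = matrix[iu, ju]
    present = w > 0
    edges = list(zip(iu[present].tolist(), ju[present].tolist()))
    weights = w[present]
    n_edges = len(edges)
    if n_edges < 2:
        raise ValidationError("need at least 2 edges to build null networks")
    if n_edges >= n * (n - 1) // 2 - 1:
        logger.warning("graph (near-)complete: rewiring impossible, "
                       "returning copies of the original")
        return [matrix.copy() for _ in range(n_random)]
    rng = np.random.default_rng(seed)
    pyrng = _pyrandom.Random(int(rng.integers(2**31)))
    ig.set_random_number_generator(pyrng)
    try:
        nulls = []
        for _ in range(n_random):
            g = ig.Graph(n=n, edges=edges)
            g.rewire(n=n_swaps_per_edge * n_edges)
            new_edges = np.array(g.get_edgelist())
            perm = rng.permutation(n_edges)
            null = np.zeros_like(matrix)
            null[new_edges[:, 0], new_edges[:, 1]] = weights[perm]
            null[new_edges[:, 1], new_edges[:, 0]] = weights[perm]
            nulls.append(null)
    finally:
        ig.set_random_number_generator(_pyrandom)
    return nulls


def normalized_metrics(
    matrix: np.ndarray,
    nulls: list[np.ndarray],
    weighted: bool = True,
) -> tuple[float, float, float]:
    """lambda = L/<L_null>, gamma = C/<C_null>, sigma = gamma/lambda."""
    if not nulls:
        raise ValidationError("need at least one null network")
    l_obs = characteristic_path_length(matrix, weighted)
    c_obs = clustering_coefficient(matrix, weighted)
    l_null = np.mean([characteristic_path_length(m, weighted) for m in nulls])
    c_null = np.mean([clustering_coefficient(m, weighted) for m in nulls])
    if l_null == 0 or c_null == 0:
        raise ValidationError("null metric is zero: normalization undefined")
    lam = l_obs / l_null
    gam = c_obs / c_null
    return float(lam), float(gam), float(gam / lam)


@dataclass
class MetricSet:
    """Full metric panel for one network."""

    lambda_norm: float
    gamma_norm: float
    sigma: float
    e_glob: float
    e_loc: float
    q: float
    degree: np.ndarray = field(repr=False)
    strength: np.ndarray = field(repr=False)
    l_raw: float = np.nan
    c_raw: float = np.nan


def compute_metric_set(
    matrix: np.ndarray,
    weighted: bool = True,
    n_random: int = 20,
    seed: int = 0,
    n_restarts: int = 100,
) -> MetricSet:
    nulls = random_reference(matrix, n_random=n_random, seed=seed)
    lam, gam, sig = normalized_metrics(matrix, nulls, weighted)
    return MetricSet(
        lambda_norm=lam,
        gamma_norm=gam,
        sigma=sig,
        e_glob=global_efficiency(matrix, weighted),
        e_loc=local_efficiency(matrix, weighted),
        q=modularity(matrix, seed=seed, n_restarts=n_restarts).q,
        degree=degrees(matrix),
        strength=strengths(matrix),
        l_raw=characteristic_path_length(matrix, weighted),
        c_raw=clustering_coefficient(matrix, weighted),
    )


def metrics_over_grid(
    conn: Connectome,
    grid: np.ndarray,
    metrics: tuple[str, ...] = ALL_GRID_METRICS,
    binarize: bool = True,
    n_random: int = 20,
    seed: int = 0,
    n_restarts: int = 100,
) -> dict[str, MetricCurve]:
    """Trace metrics for one subject across the density grid.

    Null networks for the normalized metrics are seeded deterministically
    per (subject seed, density index) so results reproduce exactly.
    """
    grid = np.asarray(grid, dtype=float)
    need_norm = any(m in NORMALIZED_METRICS for m in metrics)
    out: dict[str, list[float]] = {m: [] for m in metrics}
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(grid.size)]
    for idx, d in enumerate(grid):
        thr = threshold_at_density(conn, float(d), binarize=binarize)
        w = thr.matrix
        weighted = not binarize
        if need_norm:
            nulls = random_reference(w, n_random=n_random, seed=child_seeds[idx])
            lam, gam, sig = normalized_metrics(w, nulls, weighted)
            vals = {"lambda": lam, "gamma": gam, "sigma": sig}
        else:
            vals = {}
        for m in metrics:
            if m in vals:
                out[m].append(vals[m])
            elif m == "Q":
                out[m].append(modularity(w, seed=child_seeds[idx],
                                         n_restarts=n_restarts).q)
            elif m == "Eglob":
                out[m].append(global_efficiency(w, weighted))
            elif m == "Eloc":
                out[m].append(local_efficiency(w, weighted))
            elif m == "L":
                out[m].append(characteristic_path_length(w, weighted))
            elif m == "C":
                out[m].append(clustering_coefficient(w, weighted))
            else:
                raise ValidationError(f"unknown metric {m!r}")
    return {
        m: MetricCurve(m, grid, np.array(v), conn.subject_id)
        for m, v in out.items()
    }
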