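"""Weighted graph-theory metrics for structural covariance networks.

All functions operate on a symmetric non-negative weight matrix ``w``
(zero diagonal, weights in [0, 1] for |Pearson| networks) and follow the
conventions of the Brain Connectivity Toolbox:

* nodal strength: sum of incident edge weights;
* clustering coefficient: Onnela weighted form, with edge weights
  normalized by the network-wide maximum weight;
* path lengths: Dijkstra shortest paths on edge lengths 1/w (a weight of
  exactly 0 means "no edge");
* characteristic path length L: mean shortest path over ordered pairs;
* global efficiency: mean inverse shortest path over ordered pairs;
* local efficiency of node i: global efficiency of the subgraph induced
  by i's neighbours, with paths confined to that subgraph;
* modularity: Newman weighted modularity Q maximized by seeded Louvain
  with restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "NetworkMetricSet",
    "nodal_strengths",
    "clustering_coefficients",
    "path_length_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiencies",
    "modularity_coefficient",
    "summarize_network",
    "METRIC_NAMES",
]

#: Network-level metric names, in reporting order: two connectivity
#: metrics, three integration metrics, one organisation metric.
METRIC_NAMES = (
    "mean_strength",
    "mean_clustering",
    "char_path_length",
    "global_efficiency",
    "local_efficiency",
    "modularity",
)


def _as_weights(net) -> np.ndarray:
    w = getattr(net, "weights", net)
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return w


def nodal_strengths(net) -> tuple[np.ndarray, float]:
    """Per-node strength s_i = sum_j w_ij, and its mean over nodes."""
    w = _as_weights(net)
    s = w.sum(axis=1)
    return s, float(s.mean())


def clustering_coefficients(net, *, weighted: bool = True) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficient and its mean over nodes.

    The weighted (default) form is Onnela's: with w_hat = w / max(w),
    C_i = sum_{j,h} (w_hat_ij w_hat_ih w_hat_jh)^(1/3) / (k_i (k_i - 1))
    over ordered neighbour pairs, where k_i counts neighbours with w > 0.
    With ``weighted=False`` the binary form is used: the fraction of a
    node's neighbour pairs that are themselves connected.

    C_i = 0 for nodes with fewer than two neighbours.
    """
    w = _as_weights(net)
    n = w.shape[0]
    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    if weighted:
        wmax = w.max()
        if wmax == 0:
            return np.zeros(n), 0.0
        cw = np.cbrt(w / wmax)
        triangles = np.diag(cw @ cw @ cw)  # ordered (j, h) pairs
    else:
        triangles = np.diag(a @ a @ a)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return c, float(c.mean())


def path_length_matrix(net) -> np.ndarray:
    """Shortest-path length matrix l_ij on edge lengths 1/w_ij.

    A weight of 0 is no edge; disconnected pairs get +inf; l_ii = 0.
    """
    w = _as_weights(net)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    # csgraph dense convention: zero entries are absent edges
    return shortest_path(lengths, method="D", directed=False)


def characteristic_path_length(lmat: np.ndarray) -> float:
    """L = mean of l_ij over ordered pairs i != j.

    Raises for disconnected graphs, where L is undefined (report global
    efficiency instead).
    """
    lmat = np.asarray(lmat, dtype=float)
    n = lmat.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.isinf(lmat[off]).any():
        raise ValueError(
            "characteristic path length is undefined for disconnected "
            "graphs; report global efficiency instead"
        )
    return float(lmat[off].sum() / (n * (n - 1)))


def global_efficiency(lmat: np.ndarray) -> float:
    """E_glob = mean of 1/l_ij over ordered pairs (1/inf counted as 0)."""
    lmat = np.asarray(lmat, dtype=float)
    n = lmat.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(lmat[off]) & (lmat[off] > 0), 1.0 / lmat[off], 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiencies(net) -> tuple[np.ndarray, float]:
    """Per-node local efficiency E_loc(i) and its mean over nodes.

    E_loc(i) is the global efficiency of the subgraph G_i induced by the
    neighbours of i, with shortest paths confined to G_i. Nodes with
    fewer than two neighbours get E_loc = 0.
    """
    w = _as_weights(net)
    n = w.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        eloc[i] = global_efficiency(path_length_matrix(sub))
    return eloc, float(eloc.mean())


def modularity_coefficient(
    net, *, seed: int = 0, restarts: int = 100, resolution: float = 1.0
) -> tuple[float, list[set[int]]]:
    """Best Newman weighted modularity Q over seeded Louvain restarts.

    Returns ``(Q, partition)`` where the partition is a list of node-index
    sets. Deterministic given ``seed``. Raises on all-zero networks.
    """
    w = _as_weights(net)
    if w.sum() == 0:
        raise ValueError("modularity is undefined for a network with no edges")
    g = nx.from_numpy_array(w)
    best_q, best_part = -np.inf, None
    child_seeds = np.random.SeedSequence(seed).generate_state(restarts)
    for s in child_seeds:
        part = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=int(s % (2**31))
        )
        q = nx.community.modularity(g, part, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_part = q, part
    return float(best_q), [set(c) for c in best_part]


@dataclass
class NetworkMetricSet:
    """The six network-level metrics of one network, with nodal vectors."""

    n_nodes: int
    strength: np.ndarray
    mean_strength: float
    clustering: np.ndarray
    mean_clustering: float
    path_lengths: np.ndarray
    char_path_length: float
    global_efficiency: float
    local_efficiency_nodal: np.ndarray
    local_efficiency: float
    modularity: float
    partition: list[set[int]] = field(default_factory=list)

    def network_level(self) -> dict[str, float]:
        """The six network-level values keyed by metric name."""
        return {name: float(getattr(self, name)) for name in METRIC_NAMES}

    def nodal(self) -> dict[str, np.ndarray]:
        """The three node-level metric vectors."""
        return {
            "strength": self.strength,
            "clustering": self.clustering,
            "local_efficiency": self.local_efficiency_nodal,
        }


def summarize_network(net, *, seed: int = 0, restarts: int = 100) -> NetworkMetricSet:
    """Compute all six metrics (plus nodal vectors) for one network.

    The network must be connected, since the characteristic path length
    is undefined otherwise.
    """
    w = _as_weights(net)
    s, s_mean = nodal_strengths(w)
    c, c_mean = clustering_coefficients(w)
    lmat = path_length_matrix(w)
    cpl = characteristic_path_length(lmat)
    eg = global_efficiency(lmat)
    el, el_mean = local_efficiencies(w)
    q, part = modularity_coefficient(w, seed=seed, restarts=restarts)
    return NetworkMetricSet(
        n_nodes=w.shape[0],
        strength=s,
        mean_strength=s_mean,
        clustering=c,
        mean_clustering=c_mean,
        path_lengths=lmat,
        char_path_length=cpl,
        global_efficiency=eg,
        local_efficiency_nodal=el,
        local_efficiency=el_mean,
        modularity=q,
        partition=part,
    )
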