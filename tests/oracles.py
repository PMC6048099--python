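"""Independent brute-force oracles used to validate the fast implementations."""

import itertools

import networkx as nx
import numpy as np


def floyd_warshall(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on edge lengths 1/w via the triple loop."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def set_partitions(items):
    """All set partitions of a sequence (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def exhaustive_best_modularity(w: np.ndarray):
    """Maximum Newman weighted modularity over ALL partitions (N <= 8)."""
    g = nx.from_numpy_array(w)
    best_q, best_part = -np.inf, None
    for part in set_partitions(range(w.shape[0])):
        q = nx.community.modularity(g, [set(p) for p in part], weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r from covariance and standard deviations."""
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def ols_line(x: np.ndarray, y: np.ndarray):
    """Closed-form simple-regression slope and intercept."""
    xb, yb = x.mean(), y.mean()
    slope = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
    return slope, yb - slope * xb


def onnela_clustering(w: np.ndarray) -> np.ndarray:
    """Direct per-node evaluation of the Onnela weighted clustering sum."""
    n = w.shape[0]
    wn = w / w.max()
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for j, h in itertools.permutations(nbrs, 2):
            s += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out
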