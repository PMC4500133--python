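"""Topology of the co-expression graph: components, four centrality
measures, the combined score, and the topological-importance (TI) call.

All measures are defined directly on the binary adjacency matrix and are
well behaved on disconnected graphs:

* degree — row sums of A;
* eigenvector — the dominant eigenpair of A; mass concentrates on the
  component with the largest spectral radius, all other nodes score 0;
* betweenness — geodesic path-count centrality over unordered node pairs,
  endpoints excluded, unnormalized;
* closeness — harmonic form, the sum of reciprocal geodesic distances,
  with unreachable pairs contributing 0 (finite on disconnected graphs).

The combined score divides each measure by its maximum over genes and
averages; genes in the top half of the combined score are TI, while
isolated genes are never TI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

EIG_TOL = 1e-10
_EIG_MAX_ITER = 100_000


def _as_adjacency(net) -> tuple[list[str], np.ndarray]:
    """Accept a CoexpressionNetwork, (labels, matrix) pair, or bare matrix."""
    if hasattr(net, "adjacency") and hasattr(net, "genes"):
        return list(net.genes), np.asarray(net.adjacency, dtype=float)
    if isinstance(net, tuple) and len(net) == 2:
        labels, adj = net
        return list(labels), np.asarray(adj, dtype=float)
    adj = np.asarray(net, dtype=float)
    return [str(i) for i in range(adj.shape[0])], adj


def _check_adjacency(adj: np.ndarray) -> None:
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency diagonal must be zero")


@dataclass
class ComponentDecomposition:
    membership: dict[str, int]
    sizes: list[int]  # descending


def components(net) -> ComponentDecomposition:
    """Connected components via BFS; sizes reported in descending order."""
    labels, adj = _as_adjacency(net)
    _check_adjacency(adj)
    n = adj.shape[0]
    neighbors = [np.nonzero(adj[i])[0] for i in range(n)]
    comp = -np.ones(n, dtype=int)
    cid = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = cid
        while stack:
            u = stack.pop()
            for v in neighbors[u]:
                if comp[v] < 0:
                    comp[v] = cid
                    stack.append(v)
        cid += 1
    sizes = np.bincount(comp, minlength=cid)
    order = np.argsort(-sizes, kind="stable")
    relabel = {int(old): rank for rank, old in enumerate(order)}
    return ComponentDecomposition(
        membership={labels[i]: relabel[int(comp[i])] for i in range(n)},
        sizes=sorted((int(s) for s in sizes), reverse=True),
    )


def degree_centrality(net) -> np.ndarray:
    _, adj = _as_adjacency(net)
    _check_adjacency(adj)
    return adj.sum(axis=1).astype(int)


def eigenvector_centrality(net, tol: float = EIG_TOL) -> np.ndarray:
    """Dominant eigenvector of A: non-negative, unit Euclidean norm.

    On a disconnected graph the dominant eigenvalue belongs to a single
    component; nodes outside it (including all isolated nodes) score
    exactly zero.  An edgeless graph returns all zeros.
    """
    labels, adj = _as_adjacency(net)
    _check_adjacency(adj)
    n = adj.shape[0]
    if adj.sum() == 0:
        return np.zeros(n)
    comp = components((labels, adj))
    memb = np.array([comp.membership[g] for g in labels])
    best_val, best_vec, best_nodes = -np.inf, None, None
    for cid in range(len(comp.sizes)):
        nodes = np.nonzero(memb == cid)[0]
        if len(nodes) < 2:
            continue
        sub = adj[np.ix_(nodes, nodes)]
        val, vec = _power_iteration(sub, tol)
        if val > best_val + 1e-12:
            best_val, best_vec, best_nodes = val, vec, nodes
    e = np.zeros(n)
    if best_vec is not None:
        e[best_nodes] = best_vec
    return e


def _power_iteration(adj: np.ndarray, tol: float) -> tuple[float, np.ndarray]:
    # shift by +I so bipartite components (eigenvalues +/- r) still converge
    k = adj.shape[0]
    shifted = adj + np.eye(k)
    v = np.full(k, 1.0 / np.sqrt(k))
    lam = 0.0
    for _ in range(_EIG_MAX_ITER):
        w = shifted @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0, v * 0.0
        w /= norm
        lam = float(w @ (adj @ w))
        if np.max(np.abs(lam * w - adj @ w)) <= tol:
            v = w
            break
        v = w
    v = np.abs(v)
    nv = np.linalg.norm(v)
    return lam, v / nv if nv > 0 else v


def _bfs_distances(neighbors: list[np.ndarray], source: int, n: int) -> np.ndarray:
    dist = np.full(n, -1, dtype=int)
    dist[source] = 0
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in neighbors[u]:
                if dist[v] < 0:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def betweenness_centrality(net) -> np.ndarray:
    """Geodesic betweenness: sum over unordered pairs {j, k} (j, k != i) of
    the fraction of j-k shortest paths passing through i.  Unnormalized;
    disconnected pairs contribute nothing.  Brandes accumulation.
    """
    _, adj = _as_adjacency(net)
    _check_adjacency(adj)
    n = adj.shape[0]
    neighbors = [np.nonzero(adj[i])[0] for i in range(n)]
    b = np.zeros(n)
    for s in range(n):
        # single-source shortest-path counts
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1, dtype=int)
        dist[s] = 0
        order: list[int] = []
        frontier = [s]
        while frontier:
            nxt: list[int] = []
            for u in frontier:
                order.append(u)
                for v in neighbors[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
                    if dist[v] == dist[u] + 1:
                        sigma[v] += sigma[u]
            frontier = nxt
        delta = np.zeros(n)
        for u in reversed(order):
            for v in neighbors[u]:
                if dist[v] == dist[u] + 1:
                    delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if u != s:
                b[u] += delta[u]
    return b / 2.0  # each unordered pair counted from both endpoints


def closeness_centrality(net) -> np.ndarray:
    """Harmonic closeness: c_i = sum_{j != i} 1 / g_ij, zero terms for
    unreachable j.  Strictly positive for any non-isolated node."""
    _, adj = _as_adjacency(net)
    _check_adjacency(adj)
    n = adj.shape[0]
    neighbors = [np.nonzero(adj[i])[0] for i in range(n)]
    c = np.zeros(n)
    for i in range(n):
        dist = _bfs_distances(neighbors, i, n)
        reach = dist > 0
        c[i] = np.sum(1.0 / dist[reach]) if reach.any() else 0.0
    return c


def combined_centrality(measures: Sequence[np.ndarray]) -> np.ndarray:
    """Average of per-measure max-normalized scores.

    Each measure is divided by its maximum over genes; a measure that is
    identically zero carries no information and is dropped from the
    average.  Isolated genes (all-zero measures) end up at 0.
    """
    kept = []
    for m in measures:
        m = np.asarray(m, dtype=float)
        top = m.max() if m.size else 0.0
        if top > 0:
            kept.append(m / top)
    if not kept:
        return np.zeros_like(np.asarray(measures[0], dtype=float))
    return np.mean(kept, axis=0)


def classify_TI(
    combined: np.ndarray, isolated: np.ndarray, top_fraction: float = 0.5
) -> np.ndarray:
    """Flag the top ``top_fraction`` of non-isolated genes by combined score.

    The cut is the linear-interpolation (1 - top_fraction) quantile of the
    non-isolated scores, with ties at the threshold included.  Isolated
    genes are never TI.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    combined = np.asarray(combined, dtype=float)
    isolated = np.asarray(isolated, dtype=bool)
    ti = np.zeros(combined.shape, dtype=bool)
    pool = combined[~isolated]
    if pool.size == 0:
        return ti
    cut = np.quantile(pool, 1.0 - top_fraction)
    ti[~isolated] = combined[~isolated] >= cut
    return ti


def centrality_table(net, top_fraction: float = 0.5) -> pd.DataFrame:
    """Full per-gene centrality table with combined score and TI flag."""
    labels, adj = _as_adjacency(net)
    _check_adjacency(adj)
    degree = degree_centrality((labels, adj))
    eigen = eigenvector_centrality((labels, adj))
    between = betweenness_centrality((labels, adj))
    close = closeness_centrality((labels, adj))
    isolated = degree == 0
    combined = combined_centrality([degree, eigen, between, close])
    ti = classify_TI(combined, isolated, top_fraction)
    return pd.DataFrame(
        {
            "gene": labels,
            "degree": degree,
            "eigenvector": eigen,
            "betweenness": between,
            "closeness": close,
            "combined": combined,
            "is_isolated": isolated,
            "is_TI": ti,
        }
    )


def per_measure_TI(table: pd.DataFrame, top_fraction: float = 0.5) -> pd.DataFrame:
    """Alternative TI mode: a flag per individual centrality measure."""
    out = table[["gene"]].copy()
    isolated = table["is_isolated"].to_numpy()
    for measure in ("degree", "eigenvector", "betweenness", "closeness"):
        out[f"TI_{measure}"] = classify_TI(
            table[measure].to_numpy(float), isolated, top_fraction
        )
    return out


def degree_distribution_fit(net) -> dict:
    """Log-log least-squares fit of the degree histogram (k >= 1).

    Returns exponent (so count ~ k^-exponent), r_squared, and the number
    of distinct positive degrees used.  With fewer than 3 distinct
    positive degrees the diagnostic is unavailable.
    """
    degree = degree_centrality(net)
    ks, counts = np.unique(degree[degree > 0], return_counts=True)
    return fit_power_law(ks, counts)


def fit_power_law(ks, counts) -> dict:
    """Fit log10(count) ~ log10(k) by least squares over positive degrees."""
    ks = np.asarray(ks, dtype=float)
    counts = np.asarray(counts, dtype=float)
    keep = ks > 0
    ks, counts = ks[keep], counts[keep]
    if len(ks) < 3:
        return {"available": False, "reason": "fewer than 3 distinct positive degrees"}
    x = np.log10(ks.astype(float))
    y = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {
        "available": True,
        "exponent": float(-slope),
        "r_squared": r2,
        "n_degrees": int(len(ks)),
    }
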