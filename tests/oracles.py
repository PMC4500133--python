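"""Independent oracles used by the test suite.

Everything here is deliberately coded along a different route from the
package: Floyd-Warshall distances plus recursive geodesic enumeration
instead of Brandes/BFS, dense eigendecomposition instead of power
iteration, split-variable LPs instead of slack-variable LPs, and direct
binomial-coefficient enumeration instead of scipy's hypergeometric tail.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import linprog


# --- graph oracles ---------------------------------------------------------


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


def geodesic_paths(adj: np.ndarray, dist: np.ndarray, j: int, k: int) -> list[list[int]]:
    if j == k:
        return [[k]]
    paths = []
    for v in np.nonzero(adj[j])[0]:
        if dist[v, k] == dist[j, k] - 1:
            for tail in geodesic_paths(adj, dist, int(v), k):
                paths.append([j] + tail)
    return paths


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by explicit enumeration of every geodesic path."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    b = np.zeros(n)
    for j, k in combinations(range(n), 2):
        if not np.isfinite(dist[j, k]) or dist[j, k] == 0:
            continue
        paths = geodesic_paths(adj, dist, j, k)
        for i in range(n):
            if i == j or i == k:
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            b[i] += through / len(paths)
    return b


def brute_harmonic_closeness(adj: np.ndarray) -> np.ndarray:
    dist = floyd_warshall(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        d = dist[i]
        mask = np.isfinite(d) & (d > 0)
        out[i] = np.sum(1.0 / d[mask])
    return out


def dominant_eigenvalue(adj: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvalsh(adj))) if adj.size else 0.0


# --- LP oracles ------------------------------------------------------------


def efmin_oracle(model, weights: dict, growth_floor: float) -> float:
    """Weighted |flux| minimization via forward/reverse variable splitting."""
    n = model.n_reactions
    S = model.internal_S
    w = np.array([weights[r] for r in model.reactions], dtype=float)
    lb, ub = model.lb.copy(), model.ub.copy()
    lb[model.biomass_index] = max(lb[model.biomass_index], growth_floor)
    ident = np.eye(n)
    A_eq = np.hstack([S, -S])
    A_ub = np.vstack([np.hstack([ident, -ident]), np.hstack([-ident, ident])])
    b_ub = np.concatenate([ub, -lb])
    bounds = [(0.0, max(u, 0.0)) for u in ub] + [(0.0, max(-l, 0.0)) for l in lb]
    res = linprog(
        np.concatenate([w, w]),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    assert res.status == 0, f"oracle LP failed: {res.message}"
    return float(res.fun)


def moma_oracle(model, anchor: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> float:
    """L1 distance minimization via explicit positive/negative deviations."""
    n = model.n_reactions
    S = model.internal_S
    m = S.shape[0]
    # variables [v, d_plus, d_minus]; v - d_plus + d_minus = anchor
    A_eq = np.vstack(
        [
            np.hstack([S, np.zeros((m, 2 * n))]),
            np.hstack([np.eye(n), -np.eye(n), np.eye(n)]),
        ]
    )
    b_eq = np.concatenate([np.zeros(m), anchor])
    big = float(np.max(np.abs(anchor)) + np.max(np.abs(ub)) + np.max(np.abs(lb)) + 1.0)
    bounds = list(zip(lb, ub)) + [(0.0, big)] * (2 * n)
    c = np.concatenate([np.zeros(n), np.ones(2 * n)])
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    assert res.status == 0, f"oracle LP failed: {res.message}"
    return float(res.fun)


def fba_max_biomass(model, lb: np.ndarray, ub: np.ndarray) -> float:
    """Independent lethality oracle: plain biomass maximization."""
    n = model.n_reactions
    c = np.zeros(n)
    c[model.biomass_index] = -1.0
    res = linprog(
        c,
        A_eq=np.asarray(model.internal_S),
        b_eq=np.zeros(model.internal_S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return float(res.x[model.biomass_index]) if res.status == 0 else 0.0


# --- counting oracles ------------------------------------------------------


def hypergeom_tail_enum(M: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X = category members in a size-n draw, by enumeration."""
    total = comb(M, n)
    return sum(comb(K, x) * comb(M - K, n - x) for x in range(k, min(K, n) + 1)) / total


def all_graphs(n: int):
    """Every labelled undirected graph on n nodes, as adjacency matrices."""
    pairs = list(combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        adj = np.zeros((n, n))
        for idx, (i, j) in enumerate(pairs):
            if bits >> idx & 1:
                adj[i, j] = adj[j, i] = 1.0
        yield adj


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    adj = np.triu((rng.random((n, n)) < p).astype(float), k=1)
    return adj + adj.T
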