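"""Co-expression network inference: mutual information, background
Z-scoring, and a leave-k-conditions-out bootstrap.

The pipeline is: log2(x+1) transform, equal-frequency binning, plug-in
mutual information for every gene pair, per-gene background
standardization of the MI row (mean/SD over the other genes), and a
symmetric pair score.  Edges are called when the pair score clears the
threshold in enough bootstrap iterations, each of which drops a small
random subset of conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from netflux.expression import ExpressionMatrix

DEFAULT_Z = 4.5
DEFAULT_BOOT = 500
DEFAULT_SUPPORT = 375
DEFAULT_DROP = 2


@dataclass
class CoexpressionNetwork:
    """Undirected binary co-expression graph with bootstrap edge support."""

    genes: list[str]
    adjacency: np.ndarray = field(repr=False)  # symmetric 0/1, zero diagonal
    support: np.ndarray = field(repr=False)  # bootstrap hit counts per pair
    params: dict = field(default_factory=dict)
    mean_z: np.ndarray | None = field(default=None, repr=False)  # mean pair Z over iterations

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        n = len(self.genes)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square over the gene list")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [(self.genes[i], self.genes[j]) for i, j in zip(ii, jj)]

    def to_edge_tsv(self, path) -> None:
        import pandas as pd

        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        frame = pd.DataFrame(
            {
                "gene_a": [self.genes[i] for i in ii],
                "gene_b": [self.genes[j] for j in jj],
                "support": [int(self.support[i, j]) for i, j in zip(ii, jj)],
            }
        )
        if self.mean_z is not None:
            frame["mean_Z"] = [round(float(self.mean_z[i, j]), 6) for i, j in zip(ii, jj)]
        frame.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for (a, b) in self.edge_list():
            g.add_edge(a, b, support=int(self.support[self.genes.index(a), self.genes.index(b)]))
        nx.write_graphml(g, path)


def default_bins(n_conditions: int) -> int:
    """Equal-frequency bin count: max(2, floor(sqrt(m)))."""
    return max(2, int(np.floor(np.sqrt(n_conditions))))


def _bin_rows(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning of each row of log2(x+1) values.

    Returns integer bin labels in [0, n_bins).  Ties share a bin, so fewer
    than ``n_bins`` distinct labels can occur for low-cardinality rows; a
    constant row lands entirely in bin 0 and carries zero entropy.
    """
    x = np.log2(values + 1.0)
    n, m = x.shape
    quantiles = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1], axis=1).T  # (n, B-1)
    binned = np.zeros((n, m), dtype=np.int64)
    for k in range(n_bins - 1):
        binned += (x > quantiles[:, [k]]).astype(np.int64)
    return binned


def mutual_information_matrix(
    expr: ExpressionMatrix | np.ndarray, n_bins: int | None = None
) -> np.ndarray:
    """Pairwise plug-in mutual information (bits) between gene rows.

    Rows are log2(x+1)-transformed and discretized into equal-frequency
    bins before the joint distribution of each pair is tabulated.  The
    result is symmetric and non-negative; the diagonal holds each row's
    binned entropy (MI of a row with itself).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, float)
    n, m = values.shape
    if m < 3:
        raise ValueError("need at least 3 conditions")
    if n_bins is None:
        n_bins = default_bins(m)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    binned = _bin_rows(values, n_bins)
    return _mi_from_binned(binned, n_bins)


def _mi_from_binned(binned: np.ndarray, n_bins: int) -> np.ndarray:
    n, m = binned.shape
    onehot = np.zeros((n, m, n_bins))
    rows = np.repeat(np.arange(n), m)
    cols = np.tile(np.arange(m), n)
    onehot[rows, cols, binned.ravel()] = 1.0
    # joint[i, j, a, b] = #conditions with gene i in bin a and gene j in bin b
    joint = np.einsum("ima,jmb->ijab", onehot, onehot)
    p = joint / m
    marg = onehot.sum(axis=1) / m  # (n, B)
    outer = marg[:, None, :, None] * marg[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / outer)
    term[~np.isfinite(term)] = 0.0
    mi = term.sum(axis=(2, 3))
    np.maximum(mi, 0.0, out=mi)
    return (mi + mi.T) / 2.0


def clr_zscores(mi: np.ndarray, combine: str = "min") -> np.ndarray:
    """Background-standardized pair scores from an MI matrix.

    For each gene the off-diagonal MI row defines a background mean and SD;
    z_i(j) standardizes MI_ij against gene i's background (0 if the SD is
    zero).  Pair combiners:

    * ``"min"`` (default) — Z_ij = min(z_i(j), z_j(i)); an edge must be
      exceptional from both endpoints' perspectives.
    * ``"clr"`` — sqrt(max(0, z_i)^2 + max(0, z_j)^2), the classic score.
    """
    mi = np.asarray(mi, dtype=float)
    n = mi.shape[0]
    if mi.shape != (n, n):
        raise ValueError("MI matrix must be square")
    off = ~np.eye(n, dtype=bool)
    mu = np.array([mi[i, off[i]].mean() for i in range(n)]) if n > 1 else np.zeros(n)
    sd = np.array([mi[i, off[i]].std(ddof=0) for i in range(n)]) if n > 1 else np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_rows = (mi - mu[:, None]) / sd[:, None]
    z_rows[sd == 0, :] = 0.0
    z_rows[~np.isfinite(z_rows)] = 0.0
    if combine == "min":
        z = np.minimum(z_rows, z_rows.T)
    elif combine == "clr":
        zp = np.maximum(z_rows, 0.0)
        z = np.sqrt(zp**2 + zp.T**2)
    else:
        raise ValueError(f"unknown combiner {combine!r}")
    np.fill_diagonal(z, 0.0)
    return z


def bootstrap_network(
    expr: ExpressionMatrix,
    z_threshold: float = DEFAULT_Z,
    n_boot: int = DEFAULT_BOOT,
    support_min: int = DEFAULT_SUPPORT,
    drop_per_iter: int = DEFAULT_DROP,
    seed: int = 0,
    n_bins: int | None = None,
    combine: str = "min",
    genes: list[str] | None = None,
) -> CoexpressionNetwork:
    """Bootstrap edge calling over random leave-``drop_per_iter``-out runs.

    Per iteration, ``drop_per_iter`` distinct conditions are removed
    uniformly at random, MI and pair Z-scores recomputed on the remainder,
    and every pair with Z >= ``z_threshold`` (closed boundary) gains one
    support count.  The final adjacency keeps pairs with support >=
    ``support_min``.

    ``genes`` optionally restricts inference to a gene subset (the matrix
    is subset before inference, not the resulting network).
    """
    if support_min > n_boot:
        raise ValueError(f"support_min ({support_min}) exceeds n_boot ({n_boot})")
    if genes is not None:
        expr = expr.subset_genes([g for g in genes if g in expr.genes])
    m = expr.n_conditions
    if m <= drop_per_iter + 2:
        raise ValueError("too few conditions for the requested drop count")
    rng = np.random.default_rng(seed)
    n = expr.n_genes
    support = np.zeros((n, n), dtype=np.int32)
    z_sum = np.zeros((n, n))
    for _ in range(n_boot):
        keep = np.sort(rng.choice(m, size=m - drop_per_iter, replace=False))
        sub = expr.values[:, keep]
        bins = n_bins if n_bins is not None else default_bins(sub.shape[1])
        z = clr_zscores(_mi_from_binned(_bin_rows(sub, bins), bins), combine=combine)
        support += (z >= z_threshold).astype(np.int32)
        z_sum += z
    np.fill_diagonal(support, 0)
    # support_min = 0 still requires at least one bootstrap hit, so an
    # unreachable threshold yields an empty graph rather than a complete one
    adjacency = (support >= max(support_min, 1)).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return CoexpressionNetwork(
        genes=list(expr.genes),
        adjacency=adjacency,
        support=support,
        mean_z=z_sum / n_boot,
        params={
            "z_threshold": z_threshold,
            "n_boot": n_boot,
            "support_min": support_min,
            "drop_per_iter": drop_per_iter,
            "seed": seed,
            "combine": combine,
        },
    )
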