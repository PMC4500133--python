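"""Cross-classification of topological vs functional importance, Fisher
enrichment of functional categories, and gene-set randomization tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

CATEGORY_TF = "TF"  # topologically and functionally important
CATEGORY_Tf = "Tf"  # topologically but not functionally important
CATEGORY_Ft = "Ft"  # functionally but not topologically important
CATEGORY_NEITHER = "neither"


def cross_classify(
    ti_flags: pd.Series | dict,
    fi_groups: pd.Series | dict,
    isolated_flags: pd.Series | dict,
) -> tuple[pd.DataFrame, dict]:
    """Assign each gene to TF / Tf / Ft / neither.

    FI means knockout group 2 or 3.  TI flags come from the centrality
    analysis (isolated genes are never TI there; this is re-asserted
    here).  All three inputs must cover the same gene universe.
    """
    ti = pd.Series(ti_flags).astype(bool)
    groups = pd.Series(fi_groups).astype(int)
    isolated = pd.Series(isolated_flags).astype(bool)
    universes = [set(ti.index), set(groups.index), set(isolated.index)]
    if not (universes[0] == universes[1] == universes[2]):
        raise ValueError("gene universes of TI, FI and isolation inputs differ")
    genes = list(ti.index)
    groups = groups.reindex(genes)
    isolated = isolated.reindex(genes)
    if bool((ti & isolated).any()):
        raise ValueError("isolated genes cannot be TI")
    fi = groups.isin([2, 3])
    category = np.where(
        ti & fi, CATEGORY_TF, np.where(ti, CATEGORY_Tf, np.where(fi, CATEGORY_Ft, CATEGORY_NEITHER))
    )
    df = pd.DataFrame(
        {
            "gene": genes,
            "group": groups.to_numpy(),
            "is_TI": ti.to_numpy(),
            "is_FI": fi.to_numpy(),
            "is_isolated": isolated.to_numpy(),
            "category": category,
        }
    )
    summary = {
        "n_genes": len(genes),
        "n_TI": int(ti.sum()),
        "n_FI": int(fi.sum()),
        "n_isolated": int(isolated.sum()),
        "TF": int((df["category"] == CATEGORY_TF).sum()),
        "Tf": int((df["category"] == CATEGORY_Tf).sum()),
        "Ft": int((df["category"] == CATEGORY_Ft).sum()),
        "neither": int((df["category"] == CATEGORY_NEITHER).sum()),
    }
    return df, summary


def fisher_enrichment(
    gene_set: set[str] | list[str],
    categories: pd.DataFrame | dict[str, list[str]],
    universe: set[str] | list[str],
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher test per functional category.

    ``categories`` maps gene -> list of category labels (multi-membership
    allowed), or is a two-column (gene, category) frame.  For each
    category with K members in the universe and k members in the n-gene
    set over an M-gene universe, the p-value is the hypergeometric upper
    tail P(X >= k).  Raw p-values are reported (Benjamini-Hochberg
    adjusted values added when ``fdr`` is set).
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if isinstance(categories, pd.DataFrame):
        pairs = categories.iloc[:, :2].itertuples(index=False)
        mapping: dict[str, list[str]] = {}
        for gene, cat in pairs:
            mapping.setdefault(str(gene), []).append(str(cat))
    else:
        mapping = {g: list(cats) for g, cats in categories.items()}
    members: dict[str, set[str]] = {}
    for gene, cats in mapping.items():
        if gene not in universe:
            continue
        for cat in cats:
            members.setdefault(cat, set()).add(gene)
    M, n = len(universe), len(gene_set)
    rows = []
    for cat, genes_in_cat in sorted(members.items()):
        K = len(genes_in_cat)
        k = len(genes_in_cat & gene_set)
        p = float(hypergeom.sf(k - 1, M, K, n))
        a, b, c, d = k, n - k, K - k, M - n - K + k
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "category": cat,
                "k": k,
                "set_size": n,
                "K": K,
                "universe_size": M,
                "odds_ratio": odds,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    if fdr and len(df):
        m = len(df)
        ranked = df["p_value"].to_numpy() * m / np.arange(1, m + 1)
        df["p_adjusted"] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = df["p_value"] < alpha
    return df


def centrality_randomization(
    group: set[str] | list[str],
    centrality: pd.Series | dict[str, float],
    n_draws: int = 5000,
    seed: int = 0,
    stat: str = "mean",
) -> dict:
    """Empirical test of a group's centrality against same-size random sets.

    Draws ``n_draws`` gene sets of the group's size uniformly without
    replacement from the universe, computes the chosen statistic of each,
    and reports add-one-corrected upper-tail (enrichment) and lower-tail
    (depletion) p-values for the observed group statistic.
    """
    values = pd.Series(centrality).astype(float)
    group = list(dict.fromkeys(group))
    if not group:
        raise ValueError("empty group")
    missing = [g for g in group if g not in values.index]
    if missing:
        raise ValueError(f"group genes missing from universe: {missing[:5]}")
    if len(group) > len(values):
        raise ValueError("group larger than universe")
    stat_fn = {"mean": np.mean, "median": np.median}[stat]
    observed = float(stat_fn(values.loc[group].to_numpy()))
    pool = values.to_numpy()
    rng = np.random.default_rng(seed)
    size = len(group)
    null = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(len(pool), size=size, replace=False)
        null[i] = stat_fn(pool[idx])
    p_upper = float((1 + np.sum(null >= observed)) / (n_draws + 1))
    p_lower = float((1 + np.sum(null <= observed)) / (n_draws + 1))
    return {
        "observed": observed,
        "null_means": null,
        "p_upper": p_upper,
        "p_lower": p_lower,
        "n_draws": n_draws,
        "group_size": size,
        "stat": stat,
    }
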