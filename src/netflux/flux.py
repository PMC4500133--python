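"""Expression-guided flux estimation, in-silico knockouts, and the
three-tier functional-importance classification.

The parent flux state of each condition minimizes a sum of weighted flux
magnitudes subject to steady state, bounds, and a biomass floor; the
weight of a reaction is a decreasing linear function (1 - scaled
expression) of its gene-rule expression proxy, so poorly expressed
reactions are suppressed.  Each single-gene knockout is then scored by an
L1-linearized minimal-adjustment problem anchored to the parent vector,
with lethality decided by a separate biomass-maximization LP.

Genes are tiered per knockout phenotype across conditions:
Group 3 — no growth in at least one condition; Group 2 — growth but an
altered relative (biomass-normalized) flux distribution somewhere;
Group 1 — no effect anywhere.  Groups 2 and 3 are the functionally
important (FI) genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import bmat, eye_array, csr_array

from netflux.expression import ExpressionMatrix
from netflux.gpr import eval_gpr_bool, eval_gpr_numeric, gpr_genes
from netflux.metabolic import MetabolicModel

logger = logging.getLogger(__name__)

GROWTH_FLOOR = 1.0
GROWTH_TOL = 1e-6
FLUX_TOL = 1e-6
_BIG = 1e9


class InfeasibleModelError(RuntimeError):
    """Raised when a flux LP that must be solvable has no feasible point."""


@dataclass
class FluxState:
    condition: str
    fluxes: np.ndarray = field(repr=False)
    objective: float
    status: str = "optimal"

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class KnockoutOutcome:
    gene: str
    condition: str
    lethal: bool
    flux_changed: bool
    moma_distance: float
    fluxes: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# expression -> reaction mapping
# ---------------------------------------------------------------------------


def map_expression_to_reactions(
    expr: ExpressionMatrix, model: MetabolicModel, condition: str
) -> dict[str, float | None]:
    """Reaction-level expression proxy: AND -> min, OR -> max over genes.

    Reactions with an empty gene rule map to ``None`` (unmapped).  Gene
    rules referencing genes absent from the matrix are evaluated with the
    condition-median expression imputed for those genes (logged).
    """
    levels = expr.condition_column(condition)
    median = float(np.median(expr.values[:, expr.conditions.index(condition)]))
    out: dict[str, float | None] = {}
    imputed: set[str] = set()
    for rxn in model.reactions:
        ast = model.gpr_ast(rxn)
        if ast is None:
            out[rxn] = None
            continue
        missing = gpr_genes(ast) - levels.keys()
        if missing:
            imputed |= missing
            full = {**levels, **{g: median for g in missing}}
        else:
            full = levels
        out[rxn] = eval_gpr_numeric(ast, full)
    if imputed:
        logger.warning(
            "condition %s: imputed median expression (%.3g) for %d gene(s): %s",
            condition, median, len(imputed), sorted(imputed),
        )
    return out


def efmin_weights(reaction_expression: dict[str, float | None]) -> dict[str, float]:
    """Weights w = 1 - e_hat with e_hat min-max scaled over mapped reactions.

    Unmapped reactions get weight 1.  If all mapped levels coincide the
    scaling is degenerate and every weight is 1 (uniform minimization).
    """
    mapped = {r: v for r, v in reaction_expression.items() if v is not None}
    if not mapped:
        return {r: 1.0 for r in reaction_expression}
    lo, hi = min(mapped.values()), max(mapped.values())
    span = hi - lo
    weights = {}
    for rxn, v in reaction_expression.items():
        if v is None or span == 0:
            weights[rxn] = 1.0
        else:
            weights[rxn] = float(np.clip(1.0 - (v - lo) / span, 0.0, 1.0))
    return weights


# ---------------------------------------------------------------------------
# LP cores
# ---------------------------------------------------------------------------


def _solve_weighted_l1(
    model: MetabolicModel,
    weights: np.ndarray,
    anchor: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
) -> tuple[np.ndarray | None, float, str]:
    """Minimize sum_r weights_r * |v_r - anchor_r| s.t. S_int v = 0, bounds.

    Variables are [v; t] with t >= |v - anchor| enforced by two inequality
    blocks.  Returns (v, objective, status).
    """
    n = model.n_reactions
    S_int = csr_array(model.internal_S)
    ident = eye_array(n)
    A_ub = bmat([[ident, -ident], [-ident, -ident]], format="csr")
    b_ub = np.concatenate([anchor, -anchor])
    A_eq = bmat([[S_int, csr_array((S_int.shape[0], n))]], format="csr")
    b_eq = np.zeros(S_int.shape[0])
    t_cap = np.empty(n)
    for j in range(n):
        span = max(abs(lb[j]), abs(ub[j]), np.max(np.abs(anchor)) if n else 0.0)
        t_cap[j] = span + abs(anchor[j]) if np.isfinite(span) else _BIG
    bounds = [(lb[j], ub[j]) for j in range(n)] + [(0.0, float(t_cap[j])) for j in range(n)]
    c = np.concatenate([np.zeros(n), np.asarray(weights, float)])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        return None, np.inf, "infeasible" if res.status == 2 else f"solver_status_{res.status}"
    return res.x[:n], float(res.fun), "optimal"


def _maximize_biomass(model: MetabolicModel, lb: np.ndarray, ub: np.ndarray) -> float:
    """Maximum attainable biomass flux under the given bounds (FBA LP)."""
    n = model.n_reactions
    c = np.zeros(n)
    c[model.biomass_index] = -1.0
    res = linprog(
        c,
        A_eq=csr_array(model.internal_S),
        b_eq=np.zeros(model.internal_S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status != 0:
        return 0.0
    return float(res.x[model.biomass_index])


# ---------------------------------------------------------------------------
# E-Fmin and MOMA
# ---------------------------------------------------------------------------


def efmin_fluxes(
    model: MetabolicModel,
    reaction_expression: dict[str, float | None],
    growth_floor: float = GROWTH_FLOOR,
    condition: str = "",
) -> FluxState:
    """Expression-weighted flux minimization with a biomass floor.

    Solves min sum_r w_r |v_r| subject to steady state, bounds, and
    v_biomass >= growth_floor.  Raises InfeasibleModelError if the model
    cannot reach the floor (never silently returns zeros).
    """
    if growth_floor <= 0:
        raise ValueError("growth_floor must be positive")
    weights = efmin_weights(reaction_expression)
    w = np.array([weights[r] for r in model.reactions])
    lb, ub = model.lb.copy(), model.ub.copy()
    j_bio = model.biomass_index
    lb[j_bio] = max(lb[j_bio], growth_floor)
    if lb[j_bio] > ub[j_bio]:
        raise InfeasibleModelError("growth floor exceeds biomass upper bound")
    v, obj, status = _solve_weighted_l1(model, w, np.zeros(model.n_reactions), lb, ub)
    if status != "optimal":
        raise InfeasibleModelError(
            f"expression-weighted minimization infeasible (condition {condition!r})"
        )
    return FluxState(condition=condition, fluxes=v, objective=obj, status=status)


def knockout_bounds(model: MetabolicModel, gene: str) -> tuple[np.ndarray, np.ndarray]:
    """Bounds with every reaction whose gene rule fails without ``gene``
    clamped to zero."""
    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model")
    lb, ub = model.lb.copy(), model.ub.copy()
    for j, rxn in enumerate(model.reactions):
        ast = model.gpr_ast(rxn)
        if ast is not None and not eval_gpr_bool(ast, (gene,)):
            lb[j] = ub[j] = 0.0
    return lb, ub


def moma_knockout(
    model: MetabolicModel,
    parent: FluxState,
    gene: str,
    growth_tol: float = GROWTH_TOL,
    flux_tol: float = FLUX_TOL,
) -> KnockoutOutcome:
    """Single-gene knockout scored by L1 minimal adjustment to the parent.

    The mutant flux vector minimizes sum_r |v_r - v_parent_r| under the
    knockout bounds (no growth requirement).  Lethality is decided by a
    separate biomass maximization: the knockout is lethal when the best
    attainable biomass falls below ``growth_tol`` times the parent's.
    Flux change is judged on biomass-normalized (relative) distributions.
    """
    if not parent.ok:
        raise ValueError("parent flux state is not optimal")
    lb, ub = knockout_bounds(model, gene)
    if np.array_equal(lb, model.lb) and np.array_equal(ub, model.ub):
        # gene disables nothing: the parent vector remains optimal
        return KnockoutOutcome(gene, parent.condition, False, False, 0.0, parent.fluxes.copy())
    j_bio = model.biomass_index
    parent_bio = parent.fluxes[j_bio]
    max_bio = _maximize_biomass(model, lb, ub)
    lethal = max_bio < growth_tol * parent_bio
    v, distance, status = _solve_weighted_l1(
        model, np.ones(model.n_reactions), parent.fluxes, lb, ub
    )
    if status != "optimal":
        # knockout bounds admit no steady state at all
        return KnockoutOutcome(gene, parent.condition, True, True, np.inf, None)
    if lethal:
        changed = True
    else:
        mut_bio = v[j_bio]
        if mut_bio <= growth_tol * parent_bio:
            changed = True
        else:
            rel_parent = parent.fluxes / parent_bio
            rel_mut = v / mut_bio
            changed = bool(np.max(np.abs(rel_mut - rel_parent)) > flux_tol)
    if distance <= flux_tol and not lethal:
        # the parent vector itself (or an equivalent) survived the knockout
        changed = False
    return KnockoutOutcome(gene, parent.condition, bool(lethal), changed, distance, v)


# ---------------------------------------------------------------------------
# screen + classification
# ---------------------------------------------------------------------------


def knockout_screen(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    growth_floor: float = GROWTH_FLOOR,
    growth_tol: float = GROWTH_TOL,
    flux_tol: float = FLUX_TOL,
) -> tuple[dict[str, FluxState], list[KnockoutOutcome]]:
    """Parent flux state per condition plus every gene x condition knockout."""
    parents: dict[str, FluxState] = {}
    outcomes: list[KnockoutOutcome] = []
    for condition in expr.conditions:
        mapping = map_expression_to_reactions(expr, model, condition)
        parent = efmin_fluxes(model, mapping, growth_floor, condition)
        parents[condition] = parent
        for gene in model.genes:
            outcomes.append(moma_knockout(model, parent, gene, growth_tol, flux_tol))
    return parents, outcomes


def classify_groups(
    outcomes: list[KnockoutOutcome], genes: list[str], conditions: list[str]
) -> tuple[pd.DataFrame, dict]:
    """Tier genes by knockout phenotype across the full outcome grid.

    Returns a per-gene table (group, lethal/flux-changed condition counts)
    and a summary with group sizes and the number of genes lethal in every
    condition.
    """
    seen = {(o.gene, o.condition) for o in outcomes}
    expected = {(g, c) for g in genes for c in conditions}
    if seen != expected:
        missing = sorted(expected - seen)[:5]
        raise ValueError(f"incomplete knockout grid; missing {missing} ...")
    rows = []
    for gene in genes:
        mine = [o for o in outcomes if o.gene == gene]
        lethal_n = sum(o.lethal for o in mine)
        changed_n = sum(o.flux_changed and not o.lethal for o in mine)
        if lethal_n >= 1:
            group = 3
        elif changed_n >= 1:
            group = 2
        else:
            group = 1
        rows.append(
            {
                "gene": gene,
                "group": group,
                "lethal_conditions": lethal_n,
                "flux_changed_conditions": changed_n,
                "is_FI": group in (2, 3),
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "group_sizes": {g: int((df["group"] == g).sum()) for g in (1, 2, 3)},
        "lethal_in_all_conditions": int(
            ((df["group"] == 3) & (df["lethal_conditions"] == len(conditions))).sum()
        ),
        "n_conditions": len(conditions),
    }
    return df, summary


def flux_pca(
    states: list[FluxState], biomass_index: int, cluster_tol: float = 1e-6
) -> dict:
    """PCA of the condition x reaction flux matrix plus a count of distinct
    flux profiles (equivalence classes under small pairwise distance of
    biomass-normalized vectors)."""
    if len(states) < 2:
        raise ValueError("need at least 2 conditions")
    X = np.vstack([s.fluxes for s in states])
    bio = X[:, biomass_index]
    if np.any(bio <= 0):
        raise ValueError("all parent states must carry positive biomass flux")
    rel = X / bio[:, None]

    # distinct profiles: union-find over near-identical normalized vectors
    k = len(states)
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            if np.linalg.norm(rel[i] - rel[j]) < cluster_tol:
                parent[find(i)] = find(j)
    n_profiles = len({find(i) for i in range(k)})

    centered = X - X.mean(axis=0)
    total_var = float(np.sum(centered**2))
    if total_var <= 1e-12:
        return {
            "degenerate": True,
            "explained_variance_ratio": None,
            "scores": np.zeros((k, 1)),
            "n_profiles": n_profiles,
        }
    from sklearn.decomposition import PCA

    n_comp = min(k, X.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    return {
        "degenerate": False,
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        "scores": scores,
        "n_profiles": n_profiles,
    }
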