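"""Synthetic inputs with known ground truth.

Three generators back the test-bench for the whole pipeline:

* expression compendia with planted co-expressed modules (shared latent
  condition factor per module, gene-specific loadings, additive noise,
  floored at zero) plus independent background genes;
* small metabolic models (linear chain, parallel-redundant, or branched
  topologies) whose per-gene knockout phenotype — lethal, flux-altering,
  or silent — is recorded at generation time and independently checkable
  by stoichiometric reachability;
* the fixed 8-node mock graph used for worked centrality examples.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from netflux.expression import ExpressionMatrix
from netflux.gcn import CoexpressionNetwork
from netflux.gpr import eval_gpr_bool
from netflux.metabolic import MetabolicModel

# ---------------------------------------------------------------------------
# expression compendium
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Parameters of a planted-module expression compendium.

    ``modules`` lists (size, within-module correlation) pairs; module genes
    occupy the leading rows in order, background genes fill the rest.
    """

    n_genes: int
    n_conditions: int
    modules: tuple[tuple[int, float], ...] = ()
    noise_sd: float = 0.5
    baseline_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(tuple(m) for m in self.modules))
        if self.n_genes <= 0 or self.n_conditions <= 0:
            raise ValueError("n_genes and n_conditions must be positive")
        if self.noise_sd < 0 or self.baseline_mean <= 0:
            raise ValueError("noise_sd must be >= 0 and baseline_mean > 0")
        for size, rho in self.modules:
            if size <= 0:
                raise ValueError("module sizes must be positive")
            if not (0.0 <= rho <= 1.0):
                raise ValueError("module correlation must lie in [0, 1]")
        if sum(size for size, _ in self.modules) > self.n_genes:
            raise ValueError(
                "sum of module sizes exceeds n_genes "
                f"({sum(s for s, _ in self.modules)} > {self.n_genes})"
            )

    def module_members(self) -> list[list[int]]:
        """Row indices of each planted module."""
        out, start = [], 0
        for size, _ in self.modules:
            out.append(list(range(start, start + size)))
            start += size
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def generate_expression(spec: SyntheticExpressionSpec) -> ExpressionMatrix:
    """Draw a non-negative expression matrix with planted co-expression.

    Module gene g gets ``b_g + a_g * (sqrt(rho) * f + sqrt(1-rho) * h_g)``
    where ``f`` is the module's shared condition factor and ``h_g`` is
    private standard noise, so the pre-truncation pairwise correlation
    within a module is ``rho``.  Background genes use private factors only.
    Measurement noise (sd ``noise_sd``) is added and values are floored
    at zero.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, spec.n_conditions
    scale = rng.uniform(0.5, 1.5, size=n)
    baseline = spec.baseline_mean * scale
    amplitude = baseline / 3.0
    private = rng.standard_normal((n, m))
    signal = private.copy()
    for members, (_, rho) in zip(spec.module_members(), spec.modules):
        factor = rng.standard_normal(m)
        rows = np.array(members)
        signal[rows] = np.sqrt(rho) * factor[None, :] + np.sqrt(1.0 - rho) * private[rows]
    values = baseline[:, None] + amplitude[:, None] * signal
    values += spec.noise_sd * rng.standard_normal((n, m))
    np.maximum(values, 0.0, out=values)
    width = max(4, len(str(n)))
    genes = [f"g{i:0{width}d}" for i in range(n)]
    conditions = [f"c{j:03d}" for j in range(m)]
    return ExpressionMatrix(genes, conditions, values)


# ---------------------------------------------------------------------------
# metabolic models with known knockout phenotypes
# ---------------------------------------------------------------------------

LETHAL = "lethal"
FLUX_ALTERING = "flux_altering"
SILENT = "silent"

TOPOLOGIES = ("linear", "parallel", "branched")


@dataclass(frozen=True)
class SyntheticModelSpec:
    """Parameters of a small metabolic model with labelled genes.

    ``n_reactions`` is the number of gene-bearing chain steps between the
    medium metabolite and biomass.  ``gpr`` optionally overrides the
    default one-gene-per-reaction wiring with custom boolean rules.
    """

    topology: str = "linear"
    n_reactions: int = 4
    gpr: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}")
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be positive")
        if self.topology == "parallel" and self.n_reactions < 2:
            raise ValueError("parallel topology needs at least 2 chain steps")
        object.__setattr__(self, "gpr", tuple(tuple(p) for p in self.gpr))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SyntheticModel:
    """A generated model plus its per-gene ground truth.

    ``labels`` maps gene -> lethal / flux_altering / silent;
    ``expression`` holds per-gene abundance levels chosen so that the
    intended route is the transcriptionally preferred one.
    """

    model: MetabolicModel
    labels: dict[str, str]
    expression: dict[str, float]
    spec: SyntheticModelSpec = field(default=None)

    def to_expression(self, n_conditions: int = 3) -> ExpressionMatrix:
        """Constant-across-conditions matrix matching the model's genes."""
        genes = list(self.model.genes)
        values = np.tile(
            np.array([self.expression[g] for g in genes])[:, None], (1, n_conditions)
        )
        return ExpressionMatrix(genes, [f"c{j:03d}" for j in range(n_conditions)], values)


def generate_model(spec: SyntheticModelSpec) -> SyntheticModel:
    """Build a chain/parallel/branched toy model with labelled genes.

    Chain genes are lethal (sole stoichiometric route to biomass); in the
    parallel topology one chain step is duplicated into two redundant
    routes whose genes are non-lethal — the highly expressed route's gene
    is flux-altering, the lowly expressed one silent; the branched
    topology adds a zero-bounded appendix branch whose gene is silent.
    Lethal labels are cross-checked by stoichiometric reachability before
    returning; an unreachable wild-type biomass is rejected.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_reactions
    mets = ["MED"] + [f"M{i}" for i in range(1, L + 1)]
    external = {"MED"}
    reactions, gpr, genes = [], {}, []
    S_cols: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    expression: dict[str, float] = {}

    split = int(rng.integers(1, L + 1)) if spec.topology == "parallel" else -1
    for step in range(1, L + 1):
        sub = "MED" if step == 1 else f"M{step - 1}"
        prod = f"M{step}"
        if step == split:
            for route, tag in (("a", FLUX_ALTERING), ("b", SILENT)):
                rid, gid = f"R{step}{route}", f"g{step}{route}"
                reactions.append(rid)
                S_cols[rid] = {sub: -1.0, prod: 1.0}
                gpr[rid] = gid
                genes.append(gid)
                labels[gid] = tag
                expression[gid] = (
                    float(rng.uniform(8, 12)) if tag == FLUX_ALTERING else float(rng.uniform(0.5, 2))
                )
        else:
            rid, gid = f"R{step}", f"g{step}"
            reactions.append(rid)
            S_cols[rid] = {sub: -1.0, prod: 1.0}
            gpr[rid] = gid
            genes.append(gid)
            labels[gid] = LETHAL
            expression[gid] = float(rng.uniform(4, 8))

    lb = {r: 0.0 for r in reactions}
    ub = {r: 1000.0 for r in reactions}

    if spec.topology == "branched":
        attach = f"M{int(rng.integers(1, L + 1))}"
        mets.append("XAPP")
        external.add("XAPP")
        reactions.append("RAPP")
        S_cols["RAPP"] = {attach: -1.0, "XAPP": 1.0}
        gpr["RAPP"] = "gapp"
        genes.append("gapp")
        labels["gapp"] = SILENT
        expression["gapp"] = float(rng.uniform(4, 8))
        lb["RAPP"] = 0.0
        ub["RAPP"] = 0.0  # appendix never carries flux

    reactions.append("BIOMASS")
    S_cols["BIOMASS"] = {f"M{L}": -1.0}
    lb["BIOMASS"], ub["BIOMASS"] = 0.0, 1000.0

    if spec.gpr:
        for rid, rule in spec.gpr:
            if rid not in S_cols:
                raise ValueError(f"gpr override for unknown reaction {rid!r}")
            gpr[rid] = rule
        from netflux.gpr import gpr_genes, parse_gpr

        genes = sorted(set().union(*(gpr_genes(parse_gpr(r)) for r in gpr.values())))
        labels = {}  # custom wiring: labels recomputed below from reachability
        for g in genes:
            expression.setdefault(g, float(rng.uniform(4, 8)))

    S = np.zeros((len(mets), len(reactions)))
    met_index = {m: i for i, m in enumerate(mets)}
    for j, rid in enumerate(reactions):
        for met, coef in S_cols[rid].items():
            S[met_index[met], j] = coef
    model = MetabolicModel(
        metabolites=mets,
        external=external,
        reactions=reactions,
        S=S,
        lb=np.array([lb[r] for r in reactions]),
        ub=np.array([ub[r] for r in reactions]),
        gpr=gpr,
        biomass="BIOMASS",
        genes=genes,
    )

    if not biomass_reachable(model, inactive=()):
        raise ValueError("generated model has unreachable biomass in the wild type")

    # reachability is the authority on lethality; structural labels fill in
    # the non-lethal tiers (or default to silent under custom gpr wiring)
    for g in genes:
        if not biomass_reachable(model, inactive=(g,)):
            labels[g] = LETHAL
        elif g not in labels:
            labels[g] = SILENT
        elif labels[g] == LETHAL:
            labels[g] = SILENT  # structural guess overruled by reachability
    return SyntheticModel(model=model, labels=labels, expression=expression, spec=spec)


def biomass_reachable(model: MetabolicModel, inactive=()) -> bool:
    """Can the biomass reaction fire, by iterative scope expansion?

    Starting from the external pool, a reaction can fire forward if its
    upper bound is positive and all substrates are producible (reverse
    symmetric for a negative lower bound); products of firing reactions
    become producible.  Genes in ``inactive`` disable reactions via the
    boolean gene rules.
    """
    enabled = [
        model.gpr_ast(r) is None or eval_gpr_bool(model.gpr_ast(r), inactive)
        for r in model.reactions
    ]
    producible = set(model.external)
    changed = True
    while changed:
        changed = False
        for j, rid in enumerate(model.reactions):
            if not enabled[j]:
                continue
            subs = {model.metabolites[i] for i in np.nonzero(model.S[:, j] < 0)[0]}
            prods = {model.metabolites[i] for i in np.nonzero(model.S[:, j] > 0)[0]}
            if model.ub[j] > 0 and subs <= producible and not prods <= producible:
                producible |= prods
                changed = True
            if model.lb[j] < 0 and prods <= producible and not subs <= producible:
                producible |= subs
                changed = True
    j = model.biomass_index
    if not enabled[j] or model.ub[j] <= 0:
        return False
    subs = {model.metabolites[i] for i in np.nonzero(model.S[:, j] < 0)[0]}
    return subs <= producible


# ---------------------------------------------------------------------------
# fixed mock graph
# ---------------------------------------------------------------------------

MOCK_EDGES = frozenset({frozenset(e) for e in [(1, 2), (1, 3), (2, 3), (2, 4), (5, 6)]})


@dataclass(frozen=True)
class MockGraphFixture:
    """The fixed 8-node worked-example graph: a 4-node component containing
    the only high-betweenness node, a 2-node component, and two isolated
    nodes (7 and 8)."""

    nodes: tuple[int, ...] = tuple(range(1, 9))
    edges: frozenset = MOCK_EDGES

    def adjacency(self) -> np.ndarray:
        n = len(self.nodes)
        adj = np.zeros((n, n), dtype=np.int8)
        for edge in self.edges:
            a, b = tuple(edge)
            adj[a - 1, b - 1] = adj[b - 1, a - 1] = 1
        return adj

    def to_network(self) -> CoexpressionNetwork:
        adj = self.adjacency()
        return CoexpressionNetwork(
            genes=[str(i) for i in self.nodes],
            adjacency=adj,
            support=adj.astype(np.int32),
            params={"fixture": "mock8"},
        )


def mock_graph() -> MockGraphFixture:
    return MockGraphFixture()


# ---------------------------------------------------------------------------
# bundled end-to-end demo
# ---------------------------------------------------------------------------


def write_demo_inputs(
    directory,
    seed: int = 0,
    n_background: int = 16,
    n_conditions: int = 12,
) -> dict[str, str]:
    """Write a small self-consistent input set for a full pipeline run.

    A parallel-redundant metabolic model provides the gene universe with
    known knockout phenotypes; the expression matrix covers the model
    genes (multiplicative jitter around their route-preference levels, so
    the preferred route stays preferred in every condition) plus
    independent background genes.  The phenotype labels double as the
    functional-category map.  Returns the written paths.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sm = generate_model(SyntheticModelSpec(topology="parallel", n_reactions=3, seed=seed))
    model_genes = list(sm.model.genes)
    levels = np.array([sm.expression[g] for g in model_genes])
    values = levels[:, None] * (1.0 + 0.05 * rng.standard_normal((len(model_genes), n_conditions)))
    bg = rng.lognormal(mean=3.0, sigma=0.5, size=(n_background, n_conditions))
    genes = model_genes + [f"bg{i:03d}" for i in range(n_background)]
    expr = ExpressionMatrix(
        genes,
        [f"c{j:03d}" for j in range(n_conditions)],
        np.clip(np.vstack([values, bg]), 0.0, None),
    )
    expr.to_tsv(directory / "expression.tsv")
    sm.model.to_tsv(directory / "model", gene_categories=sm.labels)
    with open(directory / "categories.tsv", "w") as fh:
        fh.write("gene\tcategory\n")
        for g in genes:
            fh.write(f"{g}\t{sm.labels.get(g, 'background')}\n")
    (directory / "demo_spec.json").write_text(
        json.dumps({"seed": seed, "model_spec": asdict(sm.spec), "labels": sm.labels}, indent=2)
    )
    return {
        "expression": str(directory / "expression.tsv"),
        "model": str(directory / "model"),
        "categories": str(directory / "categories.tsv"),
    }
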