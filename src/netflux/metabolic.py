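"""Stoichiometric metabolic models: in-memory form, TSV dialect, SBML I/O.

A model is a metabolites x reactions stoichiometric matrix with per-reaction
flux bounds, boolean gene association rules, and one designated biomass
reaction.  Metabolites flagged external are exempt from the steady-state
balance (they represent the medium / sink pools).

Two interchange formats are supported:

* a three-file tab-separated dialect (``reactions.tsv`` with columns
  id/equation/lb/ub/gpr, ``metabolites.tsv`` with id/external,
  ``genes.tsv`` with id/category) using ``2 A + B -> C`` equation syntax;
* SBML Level 3 with FBC bounds and gene associations, delegated to COBRApy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from netflux.gpr import gpr_genes, parse_gpr

_ARROW = re.compile(r"<->|<=>|-->|->")


@dataclass
class MetabolicModel:
    """Constraint-based metabolic model.

    Attributes
    ----------
    metabolites
        Metabolite IDs (rows of ``S``).
    external
        Metabolite IDs exempt from the steady-state mass balance.
    reactions
        Reaction IDs (columns of ``S``).
    S
        Dense stoichiometric matrix, shape ``(n_metabolites, n_reactions)``.
    lb, ub
        Per-reaction flux bounds.
    gpr
        Reaction ID -> rule string (may be empty for spontaneous/exchange).
    biomass
        ID of the designated biomass reaction.
    genes
        All gene IDs associated with the model.
    """

    metabolites: list[str]
    external: set[str]
    reactions: list[str]
    S: np.ndarray = field(repr=False)
    lb: np.ndarray = field(repr=False)
    ub: np.ndarray = field(repr=False)
    gpr: dict[str, str]
    biomass: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        n_met, n_rxn = len(self.metabolites), len(self.reactions)
        if self.S.shape != (n_met, n_rxn):
            raise ValueError(f"S shape {self.S.shape} != ({n_met}, {n_rxn})")
        if self.lb.shape != (n_rxn,) or self.ub.shape != (n_rxn,):
            raise ValueError("bounds must have one entry per reaction")
        if np.any(self.lb > self.ub):
            bad = [self.reactions[i] for i in np.nonzero(self.lb > self.ub)[0]]
            raise ValueError(f"lb > ub for reactions {bad}")
        if self.biomass not in self.reactions:
            raise ValueError(f"biomass reaction {self.biomass!r} not in model")
        if self.ub[self.reactions.index(self.biomass)] <= 0:
            raise ValueError("biomass reaction has non-positive upper bound")
        unknown = self.external - set(self.metabolites)
        if unknown:
            raise ValueError(f"external flags for unknown metabolites: {unknown}")
        gene_set = set(self.genes)
        for rxn, rule in self.gpr.items():
            extra = gpr_genes(parse_gpr(rule)) - gene_set
            if extra:
                raise ValueError(f"GPR of {rxn} references unknown genes {extra}")
        self._ast = {r: parse_gpr(self.gpr.get(r, "")) for r in self.reactions}

    # -- derived views -----------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def biomass_index(self) -> int:
        return self.reactions.index(self.biomass)

    @property
    def internal_S(self) -> np.ndarray:
        """Rows of S for balanced (non-external) metabolites."""
        keep = [i for i, m in enumerate(self.metabolites) if m not in self.external]
        return self.S[keep]

    def gpr_ast(self, reaction: str):
        return self._ast[reaction]

    def reactions_of_gene(self, gene: str) -> list[str]:
        return [r for r in self.reactions if gene in gpr_genes(self._ast[r])]

    # -- TSV dialect -------------------------------------------------------

    def to_tsv(self, directory, gene_categories: dict[str, str] | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for j, rxn in enumerate(self.reactions):
            rows.append(
                {
                    "id": rxn,
                    "equation": self._format_equation(j),
                    "lb": self.lb[j],
                    "ub": self.ub[j],
                    "gpr": self.gpr.get(rxn, ""),
                    "biomass": int(rxn == self.biomass),
                }
            )
        pd.DataFrame(rows).to_csv(directory / "reactions.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"id": self.metabolites, "external": [int(m in self.external) for m in self.metabolites]}
        ).to_csv(directory / "metabolites.tsv", sep="\t", index=False)
        cats = gene_categories or {}
        pd.DataFrame(
            {"id": self.genes, "category": [cats.get(g, "") for g in self.genes]}
        ).to_csv(directory / "genes.tsv", sep="\t", index=False)

    def _format_equation(self, j: int) -> str:
        def side(sign: float) -> str:
            terms = []
            for i, met in enumerate(self.metabolites):
                coef = self.S[i, j]
                if sign * coef > 0:
                    c = abs(coef)
                    terms.append(met if c == 1 else f"{c:g} {met}")
            return " + ".join(terms)

        return f"{side(-1)} -> {side(+1)}"

    @classmethod
    def from_tsv(cls, directory) -> "MetabolicModel":
        directory = Path(directory)
        rxn_df = pd.read_csv(directory / "reactions.tsv", sep="\t").fillna({"gpr": ""})
        met_df = pd.read_csv(directory / "metabolites.tsv", sep="\t")
        gene_df = pd.read_csv(directory / "genes.tsv", sep="\t")
        metabolites = [str(m) for m in met_df["id"]]
        external = {str(m) for m, e in zip(met_df["id"], met_df["external"]) if int(e)}
        reactions = [str(r) for r in rxn_df["id"]]
        met_index = {m: i for i, m in enumerate(metabolites)}
        S = np.zeros((len(metabolites), len(reactions)))
        for j, eq in enumerate(rxn_df["equation"]):
            for met, coef in _parse_equation(str(eq)).items():
                S[met_index[met], j] = coef
        biomass_flags = rxn_df.get("biomass")
        if biomass_flags is None or int(biomass_flags.sum()) != 1:
            raise ValueError("reactions.tsv must flag exactly one biomass reaction")
        biomass = str(rxn_df.loc[biomass_flags.astype(int) == 1, "id"].iloc[0])
        return cls(
            metabolites=metabolites,
            external=external,
            reactions=reactions,
            S=S,
            lb=rxn_df["lb"].to_numpy(float),
            ub=rxn_df["ub"].to_numpy(float),
            gpr={r: str(g) for r, g in zip(reactions, rxn_df["gpr"]) if str(g)},
            biomass=biomass,
            genes=[str(g) for g in gene_df["id"]],
        )

    # -- SBML via COBRApy --------------------------------------------------

    def to_cobra(self):
        import cobra

        model = cobra.Model("netflux_model")
        mets = {}
        for m in self.metabolites:
            met = cobra.Metabolite(m, compartment="e" if m in self.external else "c")
            mets[m] = met
        # external pools are modelled as boundary metabolites; cobra handles
        # them via compartment "e" plus explicit removal from the balance,
        # so we instead keep them and add a free exchange for each.
        for j, rxn_id in enumerate(self.reactions):
            rxn = cobra.Reaction(rxn_id, lower_bound=float(self.lb[j]), upper_bound=float(self.ub[j]))
            model.add_reactions([rxn])
            rxn.add_metabolites(
                {mets[m]: float(self.S[i, j]) for i, m in enumerate(self.metabolites) if self.S[i, j] != 0}
            )
            rule = self.gpr.get(rxn_id, "")
            if rule:
                rxn.gene_reaction_rule = rule
        for m in self.external:
            ex = cobra.Reaction(f"EX_{m}_free", lower_bound=-1e6, upper_bound=1e6)
            model.add_reactions([ex])
            ex.add_metabolites({mets[m]: -1.0})
        model.objective = self.biomass
        return model

    def to_sbml(self, path) -> None:
        from cobra.io import write_sbml_model

        write_sbml_model(self.to_cobra(), str(path))

    @classmethod
    def from_sbml(cls, path, biomass: str | None = None) -> "MetabolicModel":
        from cobra.io import read_sbml_model

        cm = read_sbml_model(str(path))
        reactions = [r.id for r in cm.reactions if not r.id.endswith("_free")]
        metabolites = [m.id for m in cm.metabolites]
        met_index = {m: i for i, m in enumerate(metabolites)}
        # metabolites served by a free exchange were external pools
        external = {
            next(iter(r.metabolites)).id for r in cm.reactions if r.id.endswith("_free")
        }
        S = np.zeros((len(metabolites), len(reactions)))
        lb, ub, gpr = [], [], {}
        for j, rid in enumerate(reactions):
            r = cm.reactions.get_by_id(rid)
            for met, coef in r.metabolites.items():
                S[met_index[met.id], j] = coef
            lb.append(r.lower_bound)
            ub.append(r.upper_bound)
            if r.gene_reaction_rule:
                gpr[rid] = r.gene_reaction_rule
        if biomass is None:
            obj = [v.name for v in cm.objective.variables]
            candidates = [r for r in reactions if r in obj]
            if not candidates:
                raise ValueError("cannot infer biomass reaction; pass biomass=")
            biomass = candidates[0]
        return cls(
            metabolites=metabolites,
            external=external,
            reactions=reactions,
            S=S,
            lb=np.array(lb),
            ub=np.array(ub),
            gpr=gpr,
            biomass=biomass,
            genes=sorted({g.id for g in cm.genes}),
        )


def _parse_equation(equation: str) -> dict[str, float]:
    """Parse ``2 A + B -> C`` into metabolite -> signed coefficient."""
    parts = _ARROW.split(equation)
    if len(parts) != 2:
        raise ValueError(f"equation needs exactly one arrow: {equation!r}")
    coefs: dict[str, float] = {}
    for sign, side in ((-1.0, parts[0]), (+1.0, parts[1])):
        side = side.strip()
        if not side:
            continue
        for term in side.split("+"):
            tokens = term.split()
            if not tokens:
                raise ValueError(f"empty term in equation: {equation!r}")
            if len(tokens) == 2:
                coef, met = float(tokens[0]), tokens[1]
            elif len(tokens) == 1:
                coef, met = 1.0, tokens[0]
            else:
                raise ValueError(f"cannot parse term {term!r} in {equation!r}")
            coefs[met] = coefs.get(met, 0.0) + sign * coef
    return coefs
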