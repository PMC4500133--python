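# netflux

Integrative analysis of gene **co-expression network topology** and
**metabolic-network gene essentiality**. The package links two networks
built independently over a shared gene universe:

1. an undirected gene co-expression network (GCN) inferred from a
   condition-spanning expression compendium by mutual information with
   per-gene background Z-scoring and a leave-2-conditions-out bootstrap;
2. a stoichiometric metabolic model used for expression-guided flux
   estimation (weighted flux minimization), exhaustive in-silico
   single-gene knockouts (L1-linearized minimal metabolic adjustment),
   and a three-tier functional-importance classification.

Downstream, genes are cross-classified by topological importance (top
half of a combined centrality score; isolated genes are never TI) and
functional importance (knockout is lethal or alters the relative flux
distribution), with Fisher-exact category enrichment and a same-size
random-gene-set Monte Carlo test of group centrality.

## Layout

| module                | contents                                                             |
| --------------------- | -------------------------------------------------------------------- |
| `netflux.expression`  | gene × condition matrix type and TSV I/O                              |
| `netflux.synthetic`   | planted-module expression generator, labelled toy metabolic models, the fixed 8-node mock graph, demo inputs |
| `netflux.gcn`         | mutual information, background Z-scores, bootstrap edge calling       |
| `netflux.topology`    | components, degree/eigenvector/betweenness/harmonic-closeness, combined score, TI call, power-law fit |
| `netflux.metabolic`   | stoichiometric model type, gene-rule parser front-end, TSV dialect and SBML (via COBRApy) I/O |
| `netflux.gpr`         | boolean gene-reaction rule parsing and evaluation                     |
| `netflux.flux`        | weighted flux minimization, knockout simulation, Group 1/2/3 tiers, flux PCA |
| `netflux.integrate`   | TF/Tf/Ft cross-classification, Fisher enrichment, randomization test  |
| `netflux.cli`         | `netflux` command-line interface and full-pipeline orchestration      |

## Command line

```sh
netflux simulate-data --out demo --seed 1          # synthetic inputs
netflux gcn --expr expr.tsv --z 4.5 --boot 500 --support 375 --drop 2 --seed 1
netflux topology --graph gcn_edges.tsv --top 0.5
netflux flux --model modeldir/ --expr expr.tsv --growth-floor 1.0
netflux integrate --centrality centrality.tsv --groups gene_groups.tsv \
    --categories categories.tsv --draws 5000 --seed 1
netflux run-all --config config.yaml               # whole chain + manifest
```

`run-all` reads a YAML config (unknown keys rejected), executes
gcn → topology → flux → integrate on the intersection of expression and
model genes, and writes every intermediate artifact plus a
`manifest.json` with parameters, seeds, and output checksums; a rerun
with the same config is byte-identical.

Metabolic models are accepted either as SBML Level 3 files or as a
three-file TSV dialect (`reactions.tsv` with `2 A + B -> C` equations,
bounds, and boolean gene rules; `metabolites.tsv` with external flags;
`genes.tsv`).

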