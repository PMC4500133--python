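import numpy as np
import pytest

from netflux.expression import ExpressionMatrix
from netflux.flux import (
    FluxState,
    InfeasibleModelError,
    classify_groups,
    efmin_fluxes,
    efmin_weights,
    flux_pca,
    knockout_bounds,
    knockout_screen,
    map_expression_to_reactions,
    moma_knockout,
)
from netflux.metabolic import MetabolicModel
from netflux.synthetic import (
    FLUX_ALTERING,
    LETHAL,
    SILENT,
    SyntheticModelSpec,
    generate_model,
)

from tests.oracles import efmin_oracle, moma_oracle


def _expr_for(model_sm, n_conditions=2):
    return model_sm.to_expression(n_conditions)


def _route_genes(sm):
    active = next(g for g, l in sm.labels.items() if l == FLUX_ALTERING)
    silent = next(g for g, l in sm.labels.items() if l == SILENT)
    return active, silent


def _parent(sm, condition=None):
    expr = _expr_for(sm)
    condition = condition or expr.conditions[0]
    mapping = map_expression_to_reactions(expr, sm.model, condition)
    return efmin_fluxes(sm.model, mapping, growth_floor=1.0, condition=condition)


class TestExpressionMapping:
    def test_examples(self, parallel_model):
        model = parallel_model.model
        genes = model.genes
        expr = ExpressionMatrix(
            genes, ["c0"], np.arange(1.0, len(genes) + 1.0)[:, None]
        )
        mapping = map_expression_to_reactions(expr, model, "c0")
        levels = expr.condition_column("c0")
        for rxn in model.reactions:
            rule = model.gpr.get(rxn)
            if rule is None:
                assert mapping[rxn] is None
            else:
                assert mapping[rxn] == levels[rule]  # single-gene rules

    def test_missing_gene_imputed_with_median(self, parallel_model, caplog):
        model = parallel_model.model
        present = model.genes[:-1]
        expr = ExpressionMatrix(present, ["c0"], np.full((len(present), 1), 7.0))
        with caplog.at_level("WARNING"):
            mapping = map_expression_to_reactions(expr, model, "c0")
        missing_rxns = model.reactions_of_gene(model.genes[-1])
        assert mapping[missing_rxns[0]] == 7.0  # median of all-7 column
        assert "imputed" in caplog.text

    def test_weights_decreasing_in_expression(self):
        weights = efmin_weights({"r1": 0.0, "r2": 5.0, "r3": 10.0, "rx": None})
        assert weights["r1"] == 1.0
        assert weights["r2"] == 0.5
        assert weights["r3"] == 0.0
        assert weights["rx"] == 1.0

    def test_degenerate_scaling_uniform_weights(self):
        weights = efmin_weights({"r1": 3.0, "r2": 3.0, "rx": None})
        assert weights == {"r1": 1.0, "r2": 1.0, "rx": 1.0}


class TestEfmin:
    def test_single_path_fluxes_forced(self, linear_model):
        state = _parent(linear_model)
        assert state.ok
        # every chain reaction must carry exactly the biomass demand
        assert np.allclose(state.fluxes, 1.0, atol=1e-9)

    def test_steady_state_and_bounds(self, parallel_model):
        state = _parent(parallel_model)
        model = parallel_model.model
        assert np.max(np.abs(model.internal_S @ state.fluxes)) <= 1e-9
        assert np.all(state.fluxes >= model.lb - 1e-9)
        assert np.all(state.fluxes <= model.ub + 1e-9)

    def test_parallel_flux_follows_expression(self, parallel_model):
        state = _parent(parallel_model)
        model = parallel_model.model
        active, silent = _route_genes(parallel_model)
        v_active = state.fluxes[model.reactions.index(model.reactions_of_gene(active)[0])]
        v_silent = state.fluxes[model.reactions.index(model.reactions_of_gene(silent)[0])]
        assert v_active == pytest.approx(1.0, abs=1e-9)
        assert v_silent == pytest.approx(0.0, abs=1e-9)

    def test_uniform_expression_matches_parsimonious(self, parallel_model):
        model = parallel_model.model
        uniform = {r: (5.0 if model.gpr.get(r) else None) for r in model.reactions}
        state = efmin_fluxes(model, uniform, growth_floor=1.0)
        # all weights are 1: objective equals the plain sum of |fluxes|
        assert state.objective == pytest.approx(np.sum(np.abs(state.fluxes)), abs=1e-9)
        parsimonious = efmin_oracle(model, {r: 1.0 for r in model.reactions}, 1.0)
        assert state.objective == pytest.approx(parsimonious, abs=1e-6)

    def test_infeasible_growth_floor_raises(self, linear_model):
        model = linear_model.model
        mapping = {r: None for r in model.reactions}
        with pytest.raises(InfeasibleModelError):
            efmin_fluxes(model, mapping, growth_floor=2000.0)

    def test_objective_matches_independent_oracle(self):
        for seed in range(6):
            topology = ("linear", "parallel", "branched")[seed % 3]
            sm = generate_model(SyntheticModelSpec(topology=topology, n_reactions=5, seed=seed))
            expr = _expr_for(sm)
            mapping = map_expression_to_reactions(expr, sm.model, expr.conditions[0])
            weights = efmin_weights(mapping)
            state = efmin_fluxes(sm.model, mapping, growth_floor=1.0)
            assert state.objective == pytest.approx(
                efmin_oracle(sm.model, weights, 1.0), abs=1e-6
            )


class TestMoma:
    def test_gene_outside_all_gprs_is_inert(self, linear_model):
        m = linear_model.model
        model = MetabolicModel(
            m.metabolites, m.external, m.reactions, m.S, m.lb, m.ub,
            m.gpr, m.biomass, m.genes + ["ghost"],
        )
        parent = _parent(linear_model)
        out = moma_knockout(model, parent, "ghost")
        assert out.moma_distance == 0.0
        assert not out.lethal and not out.flux_changed

    def test_single_path_knockouts_lethal(self, linear_model):
        parent = _parent(linear_model)
        for gene in linear_model.model.genes:
            out = moma_knockout(linear_model.model, parent, gene)
            assert out.lethal and out.flux_changed

    def test_parallel_reroute(self, parallel_model):
        model = parallel_model.model
        parent = _parent(parallel_model)
        active, silent = _route_genes(parallel_model)
        out = moma_knockout(model, parent, active)
        assert not out.lethal
        assert out.flux_changed
        # the backup route must now carry the full biomass demand
        j = model.reactions.index(model.reactions_of_gene(silent)[0])
        assert out.fluxes[j] == pytest.approx(parent.fluxes[model.biomass_index], abs=1e-6)

    def test_silent_route_knockout_no_effect(self, parallel_model):
        parent = _parent(parallel_model)
        _, silent = _route_genes(parallel_model)
        out = moma_knockout(parallel_model.model, parent, silent)
        assert out.moma_distance == pytest.approx(0.0, abs=1e-9)
        assert not out.lethal and not out.flux_changed

    def test_unknown_gene_rejected(self, linear_model):
        with pytest.raises(KeyError, match="ghost"):
            moma_knockout(linear_model.model, _parent(linear_model), "ghost")

    def test_moma_against_parent_with_empty_knockout_is_zero(self, parallel_model):
        # self-consistency: distance of the parent vector to itself
        model = parallel_model.model
        parent = _parent(parallel_model)
        assert moma_oracle(model, parent.fluxes, model.lb, model.ub) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_distance_matches_independent_oracle(self):
        for seed in range(6):
            sm = generate_model(SyntheticModelSpec(topology="parallel", n_reactions=4, seed=seed))
            parent = _parent(sm)
            for gene in sm.model.genes:
                out = moma_knockout(sm.model, parent, gene)
                lb, ub = knockout_bounds(sm.model, gene)
                expected = moma_oracle(sm.model, parent.fluxes, lb, ub)
                assert out.moma_distance == pytest.approx(expected, abs=1e-6)

    def test_knockout_never_decreases_efmin_optimum(self):
        # adding the knockout constraint can only tighten the LP
        for seed in range(4):
            sm = generate_model(SyntheticModelSpec(topology="parallel", n_reactions=4, seed=seed))
            expr = _expr_for(sm)
            mapping = map_expression_to_reactions(expr, sm.model, expr.conditions[0])
            weights = efmin_weights(mapping)
            base = efmin_oracle(sm.model, weights, 1.0)
            for gene, label in sm.labels.items():
                if label == LETHAL:
                    continue
                lb, ub = knockout_bounds(sm.model, gene)
                ko_model = MetabolicModel(
                    sm.model.metabolites, sm.model.external, sm.model.reactions,
                    sm.model.S, lb, ub, sm.model.gpr, sm.model.biomass, sm.model.genes,
                )
                assert efmin_oracle(ko_model, weights, 1.0) >= base - 1e-9


class TestClassification:
    def test_groups_match_generator_labels(self, linear_model, parallel_model, branched_model):
        label_to_group = {LETHAL: 3, FLUX_ALTERING: 2, SILENT: 1}
        for sm in (linear_model, parallel_model, branched_model):
            expr = _expr_for(sm, n_conditions=3)
            _, outcomes = knockout_screen(sm.model, expr)
            df, summary = classify_groups(outcomes, sm.model.genes, expr.conditions)
            got = dict(zip(df.gene, df.group))
            assert got == {g: label_to_group[l] for g, l in sm.labels.items()}
            assert summary["lethal_in_all_conditions"] == sum(
                1 for l in sm.labels.values() if l == LETHAL
            )

    def test_incomplete_grid_rejected(self, linear_model):
        expr = _expr_for(linear_model)
        _, outcomes = knockout_screen(linear_model.model, expr)
        with pytest.raises(ValueError, match="incomplete"):
            classify_groups(outcomes[:-1], linear_model.model.genes, expr.conditions)

    def test_fi_flag(self, parallel_model):
        expr = _expr_for(parallel_model)
        _, outcomes = knockout_screen(parallel_model.model, expr)
        df, _ = classify_groups(outcomes, parallel_model.model.genes, expr.conditions)
        assert (df.is_FI == df.group.isin([2, 3])).all()


class TestFluxPca:
    def _states(self, vectors):
        return [
            FluxState(condition=f"c{i}", fluxes=np.asarray(v, float), objective=0.0)
            for i, v in enumerate(vectors)
        ]

    def test_identical_conditions_degenerate(self):
        states = self._states([[1.0, 2.0, 1.0]] * 4)
        res = flux_pca(states, biomass_index=2)
        assert res["degenerate"]
        assert res["n_profiles"] == 1

    def test_two_regimes(self, rng):
        a = np.array([10.0, 0.0, 1.0])
        b = np.array([0.0, 10.0, 1.0])
        vectors = [a + 1e-9 * rng.standard_normal(3) for _ in range(3)]
        vectors += [b + 1e-9 * rng.standard_normal(3) for _ in range(3)]
        res = flux_pca(self._states(vectors), biomass_index=2, cluster_tol=1e-6)
        assert res["n_profiles"] == 2
        assert res["explained_variance_ratio"][0] > 0.99

    def test_ratios_sum_to_one(self, rng):
        vectors = rng.random((5, 4)) + 1.0
        res = flux_pca(self._states(vectors), biomass_index=0)
        assert np.sum(res["explained_variance_ratio"]) == pytest.approx(1.0, abs=1e-12)

    def test_needs_two_conditions(self):
        with pytest.raises(ValueError):
            flux_pca(self._states([[1.0, 1.0]]), biomass_index=0)
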