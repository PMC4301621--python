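import math

import numpy as np
import pytest

from oracles import dykstra_moma, model_lp_data

from oleaflux.fba import FluxDistribution, solve_fba, solve_fba_fixed_growth
from oleaflux.moma import (
    count_changed_reactions,
    knockout_gene,
    knockout_reactions,
    solve_moma,
    solve_moma_l1,
)


class TestKnockout:
    def test_single_gene_blocks_reaction(self, parallel_model):
        ko = knockout_gene(parallel_model, ["gP"])
        assert ko.reaction("P1").bounds == (0.0, 0.0)
        assert ko.reaction("Q1").bounds == (0.0, 1000.0)

    def test_or_isozyme_unaffected(self, mini_model):
        ko = knockout_gene(mini_model, ["g_d9a"])  # one of three isozymes
        assert ko.reaction("D9").upper_bound > 0

    def test_me_gene_blocks_me_reaction(self, mini_model, mini_truth):
        ko = knockout_gene(mini_model, [mini_truth.me_gene])
        assert ko.reaction(mini_truth.me_reaction).bounds == (0.0, 0.0)

    def test_unknown_gene_raises(self, mini_model):
        with pytest.raises(KeyError):
            knockout_gene(mini_model, ["not_a_gene"])

    def test_reaction_knockout(self, mini_model):
        ko = knockout_reactions(mini_model, ["ME"])
        assert ko.reaction("ME").bounds == (0.0, 0.0)
        # original untouched
        assert mini_model.reaction("ME").upper_bound > 0


class TestSolveMoma:
    def test_empty_knockout_distance_zero(self, parallel_model):
        reference = solve_fba(parallel_model)
        sol = solve_moma(parallel_model, reference)
        assert sol.optimal
        assert sol.distance == pytest.approx(0.0, abs=1e-6)

    def test_parallel_branch_rerouting_distance(self, parallel_model):
        # wild type pushed through P; with the chain throughput pinned at 1,
        # knocking out gP leaves only P1 and Q1 free: the unit of flux moves
        # to Q, changing each branch by 1 -> distance sqrt(2). The pinning
        # makes this the hand-solvable 2-variable QP; without it the
        # projection would also shrink the overall throughput.
        parallel_model.reaction("EX_s").bounds = (-1.0, -1.0)
        parallel_model.reaction("T_s").bounds = (1.0, 1.0)
        parallel_model.reaction("BIO").bounds = (1.0, 1.0)
        reference = FluxDistribution(
            {"EX_s": -1.0, "T_s": 1.0, "P1": 1.0, "Q1": 0.0, "BIO": 1.0},
            1.0,
            "optimal",
        )
        sol = solve_moma(parallel_model, reference, knockout_genes=["gP"])
        assert sol.optimal
        assert sol.distance == pytest.approx(math.sqrt(2.0), abs=1e-6)
        assert sol.fluxes["Q1"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_dykstra_oracle_small(self, branched_model):
        reference = solve_fba(branched_model)
        ko = knockout_reactions(branched_model, ["HIGH"])
        sol = solve_moma(branched_model, reference,
                         knockout_reaction_ids=["HIGH"])
        S, lb, ub = model_lp_data(ko)
        w = np.array([reference.fluxes[r.id] for r in ko.reactions])
        expected = dykstra_moma(S, lb, ub, w)
        got = np.array([sol.fluxes[r.id] for r in ko.reactions])
        assert np.max(np.abs(got - expected)) <= 1e-6

    def test_infeasible_knockout_status(self, chain_model):
        reference = solve_fba(chain_model)
        chain_model.reaction("BIO").bounds = (0.5, 1000.0)  # forced growth
        sol = solve_moma(chain_model, reference,
                         knockout_reaction_ids=["T_a"])
        assert sol.status == "infeasible"

    def test_distance_zero_iff_reference_feasible(self, parallel_model):
        reference = FluxDistribution(
            {"EX_s": -1.0, "T_s": 1.0, "P1": 0.5, "Q1": 0.5, "BIO": 1.0},
            1.0,
            "optimal",
        )
        feasible = solve_moma(parallel_model, reference)
        assert feasible.distance == pytest.approx(0.0, abs=1e-8)
        infeasible_ref = solve_moma(parallel_model, reference,
                                    knockout_genes=["gP"])
        assert infeasible_ref.distance > 1e-3

    def test_moma_growth_below_knockout_fba_optimum(
        self, mg_conditioned, me_moma_solution, mini_truth
    ):
        sol = me_moma_solution
        ko = knockout_gene(mg_conditioned, [mini_truth.me_gene])
        fba_opt = solve_fba(ko, "BIOMASS")
        assert sol.fluxes["BIOMASS"] <= fba_opt.objective_value + 1e-6

    def test_invariant_under_reaction_reordering(self, branched_model):
        reference = solve_fba(branched_model)
        base = solve_moma(branched_model, reference,
                          knockout_reaction_ids=["HIGH"]).distance
        shuffled = branched_model.copy()
        shuffled.reactions = shuffled.reactions[::-1]
        shuffled._rxn_index = {r.id: i for i, r in enumerate(shuffled.reactions)}
        again = solve_moma(shuffled, reference,
                           knockout_reaction_ids=["HIGH"]).distance
        assert again == pytest.approx(base, abs=1e-6)

    def test_me_knockout_lowers_ara(
        self, production_reference, me_moma_solution, mini_truth
    ):
        sol = me_moma_solution
        before = production_reference.fluxes[mini_truth.ara_exchange]
        after = sol.fluxes[mini_truth.ara_exchange]
        assert after < before - 1e-6

    def test_l1_variant_labelled_alternative(self, parallel_model):
        reference = FluxDistribution(
            {"EX_s": -1.0, "T_s": 1.0, "P1": 1.0, "Q1": 0.0, "BIO": 1.0},
            1.0,
            "optimal",
        )
        sol = solve_moma_l1(parallel_model, reference, knockout_genes=["gP"])
        assert sol.optimal
        assert sol.fluxes["Q1"] == pytest.approx(1.0, abs=1e-6)


class TestCountChanged:
    def test_identical_vectors_zero(self, production_reference):
        n, ids = count_changed_reactions(
            production_reference, production_reference, threshold=0.0
        )
        assert n == 0 and ids == []

    def test_threshold_zero_counts_all_diffs(self):
        a = FluxDistribution({"r1": 1.0, "r2": 2.0, "r3": 3.0}, 1.0, "optimal")
        b = FluxDistribution({"r1": 1.0, "r2": 2.5, "r3": 2.0}, 1.0, "optimal")
        n, ids = count_changed_reactions(a, b, threshold=0.0)
        assert n == 2 and ids == ["r2", "r3"]

    def test_mismatched_universes_raise(self):
        a = FluxDistribution({"r1": 1.0}, 1.0, "optimal")
        b = FluxDistribution({"r2": 1.0}, 1.0, "optimal")
        with pytest.raises(ValueError):
            count_changed_reactions(a, b)

    def test_mini_me_knockout_matches_brute_force(
        self, production_reference, me_moma_solution, mini_truth
    ):
        sol = me_moma_solution
        n, ids = count_changed_reactions(production_reference, sol, 1e-6)
        brute = [
            rid
            for rid in sorted(production_reference.fluxes)
            if abs(sol.fluxes[rid] - production_reference.fluxes[rid]) > 1e-6
        ]
        assert ids == brute
        assert n == len(brute) > 0
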