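import numpy as np
import pytest

from oracles import fva_oracle, lp_oracle_max, model_lp_data

from oleaflux.core import build_stoichiometric_matrix
from oleaflux.fba import (
    FbaError,
    Medium,
    apply_medium,
    fva,
    load_carbon_screen_list,
    load_medium_preset,
    robustness_scan,
    solve_fba,
    solve_fba_fixed_growth,
    substrate_utilization_screen,
)


class TestSolveFba:
    def test_chain_model_objective(self, chain_model):
        sol = solve_fba(chain_model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)

    def test_branched_matches_vertex_oracle(self, branched_model):
        sol = solve_fba(branched_model)
        S, lb, ub = model_lp_data(branched_model)
        c = np.zeros(branched_model.n_rxn)
        c[branched_model.reaction_index("BIO")] = 1.0
        assert sol.objective_value == pytest.approx(
            lp_oracle_max(S, lb, ub, c), abs=1e-9
        )

    def test_no_objective_refused(self, chain_model):
        chain_model.objective_id = None
        with pytest.raises(FbaError, match="objective"):
            solve_fba(chain_model)

    def test_infeasible_reported_not_zeroed(self, chain_model):
        sol = solve_fba(
            chain_model, extra_constraints=[("BIO", 5.0, 10.0)]
        )
        assert sol.status == "infeasible"
        assert sol.objective_value is None
        assert sol.fluxes == {}

    def test_minimize_direction(self, chain_model):
        sol = solve_fba(chain_model, direction="min")
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_and_bounds(self, mg_conditioned):
        sol = solve_fba(mg_conditioned)
        S = build_stoichiometric_matrix(mg_conditioned)
        v = np.array([sol.fluxes[r.id] for r in mg_conditioned.reactions])
        assert np.max(np.abs(S @ v)) <= 1e-6
        for rxn in mg_conditioned.reactions:
            assert rxn.lower_bound - 1e-9 <= sol.fluxes[rxn.id] <= rxn.upper_bound + 1e-9

    def test_objective_reproducible(self, mg_conditioned):
        a = solve_fba(mg_conditioned).objective_value
        b = solve_fba(mg_conditioned).objective_value
        assert abs(a - b) <= 1e-9

    def test_objective_invariant_under_reordering(self, mg_conditioned):
        base = solve_fba(mg_conditioned).objective_value
        shuffled = mg_conditioned.copy()
        order = list(range(shuffled.n_rxn))
        rng = np.random.default_rng(7)
        rng.shuffle(order)
        shuffled.reactions = [shuffled.reactions[k] for k in order]
        shuffled._rxn_index = {r.id: i for i, r in enumerate(shuffled.reactions)}
        rng.shuffle(shuffled.metabolites)
        shuffled._met_index = {m.id: i for i, m in enumerate(shuffled.metabolites)}
        assert solve_fba(shuffled).objective_value == pytest.approx(base, abs=1e-9)


class TestFixedGrowth:
    def test_pin_zero_equals_no_biomass_drain(self, mg_conditioned):
        pinned = solve_fba_fixed_growth(mg_conditioned, 0.0, "EX_ara")
        blocked = mg_conditioned.copy()
        blocked.reaction("BIOMASS").bounds = (0.0, 0.0)
        free = solve_fba(blocked, "EX_ara")
        assert pinned.objective_value == pytest.approx(
            free.objective_value, abs=1e-9
        )

    def test_pin_above_max_is_infeasible(self, mg_conditioned):
        max_growth = solve_fba(mg_conditioned).objective_value
        sol = solve_fba_fixed_growth(mg_conditioned, max_growth + 0.1, "EX_ara")
        assert sol.status == "infeasible"

    def test_pin_at_optimum_idempotent(self, mg_conditioned):
        opt = solve_fba(mg_conditioned).objective_value
        again = solve_fba_fixed_growth(mg_conditioned, opt, "BIOMASS")
        assert again.objective_value == pytest.approx(opt, abs=1e-9)


class TestFva:
    def test_objective_range_collapses_at_fraction_one(self, branched_model):
        opt = solve_fba(branched_model).objective_value
        result = fva(branched_model, ["BIO"], fraction_of_optimum=1.0)
        lo, hi = result["BIO"]
        assert lo == pytest.approx(opt, abs=1e-6)
        assert hi == pytest.approx(opt, abs=1e-6)

    def test_parallel_branches_full_range(self, parallel_model):
        result = fva(parallel_model, ["P1", "Q1"])
        for rxn_id in ("P1", "Q1"):
            lo, hi = result[rxn_id]
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(1.0, abs=1e-6)

    def test_blocked_reaction_zero_range(self, parallel_model):
        parallel_model.reaction("Q1").bounds = (0.0, 0.0)
        result = fva(parallel_model, ["Q1"])
        assert result["Q1"] == (0.0, 0.0)

    def test_matches_enumeration_oracle(self, branched_model):
        S, lb, ub = model_lp_data(branched_model)
        j = branched_model.reaction_index("BIO")
        opt, ranges = fva_oracle(S, lb, ub, j)
        result = fva(branched_model)
        for k, rxn in enumerate(branched_model.reactions):
            lo, hi = result[rxn.id]
            assert lo == pytest.approx(ranges[k][0], abs=1e-6)
            assert hi == pytest.approx(ranges[k][1], abs=1e-6)

    def test_envelope_contains_fba_vector(self, mg_conditioned):
        sol = solve_fba(mg_conditioned)
        result = fva(mg_conditioned)
        for rxn_id, flux in sol.fluxes.items():
            lo, hi = result[rxn_id]
            assert lo - 1e-6 <= flux <= hi + 1e-6

    def test_infeasible_base_aborts(self, chain_model):
        chain_model.reaction("BIO").bounds = (5.0, 10.0)
        with pytest.raises(FbaError):
            fva(chain_model)


class TestMedia:
    def test_mg_preset_supports_growth(self, mini_model, media):
        sol = solve_fba(apply_medium(mini_model, media[0]))
        assert sol.optimal and sol.objective_value > 0

    def test_empty_medium_no_growth(self, mini_model):
        sol = solve_fba(apply_medium(mini_model, Medium("empty")))
        # nothing to eat: either exactly zero growth or an infeasible
        # maintenance demand
        assert (not sol.optimal) or sol.objective_value == pytest.approx(
            0.0, abs=1e-9
        )

    def test_ye_preset_amino_acid_bounds(self, media):
        ye = media[1]
        for rxn_id, (lo, _) in ye.overrides.items():
            if rxn_id not in ("EX_glc", "EX_no3"):
                assert lo == -0.01  # uptake capped at 0.01 mmol/gDW/h

    def test_override_on_non_exchange_rejected(self, mini_model):
        bad = Medium("bad", {"HEX": (-1.0, 1.0)})
        with pytest.raises(ValueError, match="non-exchange"):
            apply_medium(mini_model, bad)

    def test_shipped_presets_match_generated(self, media):
        assert load_medium_preset("mg").overrides == media[0].overrides
        assert load_medium_preset("ye").overrides == media[1].overrides
        assert set(load_carbon_screen_list()) >= {"EX_glc", "EX_glyc", "EX_etoh"}


class TestRobustness:
    def test_single_peaked_oxygen_curve(self, mg_conditioned, mini_truth):
        values = [0.25 * k for k in range(49)]
        curve = robustness_scan(
            mg_conditioned, "EX_o2", values, "EX_ara", min_growth=0.03
        )
        objs = np.array(curve.objectives)
        assert len(objs) >= 5
        k = int(np.argmax(objs))
        assert 0 < k < len(objs) - 1  # interior optimum
        assert all(objs[i + 1] >= objs[i] - 1e-9 for i in range(k))
        assert all(objs[i + 1] <= objs[i] + 1e-9 for i in range(k, len(objs) - 1))
        lo, hi = mini_truth.oxygen_optimum_window
        assert lo <= curve.peak()[0] <= hi

    def test_infeasible_points_absent_not_zero(self, mg_conditioned):
        curve = robustness_scan(
            mg_conditioned, "EX_o2", [0.0, 1.0], "EX_ara", min_growth=0.03
        )
        assert 0.0 in curve.infeasible_values
        assert 0.0 not in curve.values

    def test_glucose_scan_monotone(self, chain_model):
        # pinning more substrate into a pure chain raises the optimum linearly
        curve = robustness_scan(
            chain_model, "EX_a", [0.1, 0.5, 1.0], "BIO"
        )
        assert curve.objectives == sorted(curve.objectives)

    def test_empty_values_rejected(self, chain_model):
        with pytest.raises(ValueError):
            robustness_scan(chain_model, "EX_a", [], "BIO")

    def test_non_increasing_values_rejected(self, chain_model):
        with pytest.raises(ValueError):
            robustness_scan(chain_model, "EX_a", [1.0, 0.5], "BIO")


class TestSubstrateScreen:
    def test_orphan_sugar_does_not_grow(self, mini_model, media):
        rows = substrate_utilization_screen(
            mini_model,
            media[0],
            ["EX_glc", "EX_glyc", "EX_etoh", "EX_orph"],
            uptake=1.0,
            replaced_exchange="EX_glc",
        )
        outcome = {rid: grows for rid, grows, _ in rows}
        assert outcome == {
            "EX_glc": True,
            "EX_glyc": True,
            "EX_etoh": True,
            "EX_orph": False,
        }

    def test_base_source_candidate_consistent(self, mini_model, media):
        base_growth = solve_fba(apply_medium(mini_model, media[0]))
        rows = substrate_utilization_screen(
            mini_model, media[0], ["EX_glc"], uptake=0.8,
            replaced_exchange="EX_glc",
        )
        assert rows[0][1] == (base_growth.objective_value > 1e-6)

    def test_glutamate_glycine_sole_nitrogen(self, mini_model, media):
        for candidate in ("EX_glu", "EX_gly"):
            rows = substrate_utilization_screen(
                mini_model, media[0], [candidate], uptake=1.0,
                replaced_exchange="EX_no3",
            )
            assert rows[0][1], f"{candidate} should support growth as sole N"

    def test_non_exchange_candidate_rejected(self, mini_model, media):
        with pytest.raises(ValueError):
            substrate_utilization_screen(mini_model, media[0], ["HEX"])
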