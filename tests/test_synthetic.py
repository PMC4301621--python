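import pytest

from oleaflux.core import elemental_imbalance
from oleaflux.fba import apply_medium, solve_fba, solve_fba_fixed_growth
from oleaflux.io import format_equation
from oleaflux.synthetic import (
    MiniAlpinaSpec,
    RandomModelSpec,
    SpecError,
    generate_mini_alpina,
    generate_random_viable_model,
    mini_alpina_media,
    perturb_remove_reactions,
)


class TestMiniAlpina:
    def test_default_spec_grows_on_mg(self, mini_model, media):
        sol = solve_fba(apply_medium(mini_model, media[0]))
        assert sol.optimal and sol.objective_value > 0

    def test_produces_ara_under_production_scenario(self, production_reference):
        assert production_reference.objective_value > 0

    def test_deterministic_regeneration(self, mini_model):
        again, _ = generate_mini_alpina()
        assert [r.id for r in again.reactions] == [
            r.id for r in mini_model.reactions
        ]
        for r1, r2 in zip(mini_model.reactions, again.reactions):
            assert r1.stoichiometry == r2.stoichiometry
            assert format_equation(r1) == format_equation(r2)

    def test_four_compartments_used(self, mini_model):
        used = {m.compartment for m in mini_model.metabolites}
        assert used == {"e", "c", "m", "x"}

    def test_no_nadph_source_kills_production(self):
        model, _ = generate_mini_alpina(
            MiniAlpinaSpec(me_present=False, ppp_present=False)
        )
        mg, _ = mini_alpina_media()
        conditioned = apply_medium(model, mg)
        sol = solve_fba_fixed_growth(conditioned, 0.0, "EX_ara")
        assert (not sol.optimal) or sol.objective_value == pytest.approx(
            0.0, abs=1e-9
        )

    def test_omega3_toggle_isolated(self, media):
        without, truth = generate_mini_alpina(MiniAlpinaSpec(include_omega3=False))
        assert truth.epa_exchange is None
        assert not without.has_reaction("HYD_EPA")
        conditioned = apply_medium(without, media[0])
        ara = solve_fba_fixed_growth(conditioned, 0.03, "EX_ara")
        with_branch, _ = generate_mini_alpina()
        ara_with = solve_fba_fixed_growth(
            apply_medium(with_branch, media[0]), 0.03, "EX_ara"
        )
        assert ara.objective_value == pytest.approx(
            ara_with.objective_value, abs=1e-9
        )

    def test_ara_without_delta5_rejected(self):
        with pytest.raises(SpecError, match="delta-5"):
            generate_mini_alpina(MiniAlpinaSpec(delta5_present=False))

    def test_elemental_audit_closes(self, mini_model):
        for rxn in mini_model.reactions:
            if rxn.rtype != "biochemical":
                continue
            imbalance = elemental_imbalance(mini_model, rxn)
            assert imbalance in (None, {}), (rxn.id, imbalance)

    def test_ground_truth_ids_resolve(self, mini_model, mini_truth):
        for rxn_id in [
            mini_truth.biomass_reaction,
            mini_truth.maintenance_reaction,
            mini_truth.ara_exchange,
            mini_truth.me_reaction,
            mini_truth.rhamnose_lyase_reaction,
            *mini_truth.nadph_reactions,
        ]:
            assert mini_model.has_reaction(rxn_id)
        for gene in [
            mini_truth.me_gene,
            mini_truth.nitrate_reductase_gene,
            *mini_truth.amino_acid_synthesis_genes.values(),
        ]:
            assert gene in mini_model.genes

    def test_size_in_target_band(self, mini_model):
        assert 100 <= mini_model.n_rxn <= 250
        assert len(mini_model.genes) < 120


class TestRandomModels:
    def test_same_seed_identical(self):
        spec = RandomModelSpec(seed=1)
        a = generate_random_viable_model(spec)
        b = generate_random_viable_model(spec)
        assert [r.id for r in a.reactions] == [r.id for r in b.reactions]
        for r1, r2 in zip(a.reactions, b.reactions):
            assert r1.stoichiometry == r2.stoichiometry
            assert r1.bounds == r2.bounds

    def test_different_seeds_differ(self):
        a = generate_random_viable_model(RandomModelSpec(seed=1))
        b = generate_random_viable_model(RandomModelSpec(seed=2))
        assert any(
            r1.stoichiometry != r2.stoichiometry
            for r1, r2 in zip(a.reactions, b.reactions)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_always_viable(self, seed):
        model = generate_random_viable_model(RandomModelSpec(seed=seed))
        sol = solve_fba(model)
        assert sol.optimal and sol.objective_value > 0

    def test_backbone_only_has_no_gaps(self):
        from oleaflux.gaps import find_blocked_metabolites

        model = generate_random_viable_model(
            RandomModelSpec(n_metabolites=3, n_reactions=4, n_genes=1)
        )
        report = find_blocked_metabolites(model)
        assert report.blocked_metabolites == set()

    def test_too_small_rejected(self):
        with pytest.raises(SpecError):
            generate_random_viable_model(RandomModelSpec(n_reactions=2))


class TestPerturb:
    def test_remove_me(self, mini_model):
        perturbed = perturb_remove_reactions(mini_model, ["ME"])
        assert not perturbed.has_reaction("ME")
        assert mini_model.has_reaction("ME")  # original untouched

    def test_remove_sole_transporter_stops_growth(self, mini_model, media):
        perturbed = perturb_remove_reactions(mini_model, ["T_glc"])
        sol = solve_fba(apply_medium(perturbed, media[0]))
        assert (not sol.optimal) or sol.objective_value == pytest.approx(
            0.0, abs=1e-9
        )

    def test_remove_biomass_rejected(self, mini_model):
        with pytest.raises(SpecError):
            perturb_remove_reactions(mini_model, ["BIOMASS"])

    def test_rhamnose_screen_negative_after_lyase_removal(
        self, mini_model, media
    ):
        from oleaflux.fba import substrate_utilization_screen

        perturbed = perturb_remove_reactions(mini_model, ["RHA_LYASE"])
        rows = substrate_utilization_screen(
            perturbed, media[0], ["EX_rha"], replaced_exchange="EX_glc"
        )
        assert rows[0][1] is False
        rows_intact = substrate_utilization_screen(
            mini_model, media[0], ["EX_rha"], replaced_exchange="EX_glc"
        )
        assert rows_intact[0][1] is True
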