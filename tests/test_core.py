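import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import gpr_eval_python

from oleaflux.core import (
    GprParseError,
    GprRule,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    build_stoichiometric_matrix,
    elemental_imbalance,
    evaluate_gpr,
    parse_formula,
    reactions_involving,
)


def two_met_model():
    model = MetabolicModel("toy")
    model.add_metabolite(Metabolite("A", compartment="c"))
    model.add_metabolite(Metabolite("B", compartment="c"))
    model.add_reaction(Reaction("R1", stoichiometry={"A": -1.0, "B": 1.0}))
    return model


class TestStoichiometricMatrix:
    def test_single_reaction_column(self):
        S = build_stoichiometric_matrix(two_met_model())
        assert S.shape == (2, 1)
        np.testing.assert_array_equal(S[:, 0], [-1.0, 1.0])

    def test_empty_model(self):
        S = build_stoichiometric_matrix(MetabolicModel("empty"))
        assert S.shape == (0, 0)

    def test_sparse_and_dense_agree(self, mini_model):
        dense = build_stoichiometric_matrix(mini_model)
        sparse = build_stoichiometric_matrix(mini_model, sparse_format=True)
        assert dense.shape == (mini_model.n_met, mini_model.n_rxn)
        np.testing.assert_array_equal(sparse.toarray(), dense)

    def test_matrix_round_trip_preserves_coefficients(self, mini_model):
        S = build_stoichiometric_matrix(mini_model)
        for j, rxn in enumerate(mini_model.reactions):
            rebuilt = {
                mini_model.metabolites[i].id: S[i, j]
                for i in np.nonzero(S[:, j])[0]
            }
            assert rebuilt == rxn.stoichiometry

    def test_unknown_metabolite_raises_naming_reaction(self):
        model = two_met_model()
        model.reactions[0].stoichiometry["ghost"] = 1.0
        with pytest.raises(ModelStructureError, match="R1"):
            build_stoichiometric_matrix(model)

    def test_mini_alpina_elemental_balance(self, mini_model):
        """Every biochemical reaction with complete formulas is mass-balanced."""
        audited = 0
        for rxn in mini_model.reactions:
            if rxn.rtype != "biochemical":
                continue
            imbalance = elemental_imbalance(mini_model, rxn)
            if imbalance is None:
                continue
            audited += 1
            assert imbalance == {}, f"{rxn.id}: {imbalance}"
        assert audited > 80  # the audit genuinely covers the model


class TestGpr:
    def test_single_gene_deleted(self):
        assert evaluate_gpr(GprRule("g1"), {"g1"}) is False

    def test_isozyme_survives_single_deletion(self):
        assert evaluate_gpr(GprRule("g1 or g2"), {"g1"}) is True

    def test_complex_with_isozyme(self):
        # frozen from full truth-table enumeration of (g1 and g2) or g3
        rule = GprRule("(g1 and g2) or g3")
        assert rule.evaluate({"g2", "g3"}) is False
        assert rule.evaluate({"g3"}) is True
        assert rule.evaluate({"g1", "g2"}) is True

    def test_empty_rule_always_active(self):
        assert evaluate_gpr(GprRule(""), {"anything"}) is True

    def test_comma_is_or(self):
        rule = GprRule("g1, g2, g3")
        assert rule.evaluate({"g1", "g2"}) is True
        assert rule.evaluate({"g1", "g2", "g3"}) is False

    def test_case_insensitive_keywords(self):
        rule = GprRule("g1 AND g2 Or g3")
        assert rule.genes() == {"g1", "g2", "g3"}
        assert rule.evaluate({"g1"}) is True  # g3 still active

    def test_parse_error_reports_position(self):
        with pytest.raises(GprParseError) as err:
            GprRule("g1 and (g2 or")
        assert err.value.position >= 0

    @pytest.mark.parametrize(
        "expression",
        ["g1", "g1 and g2", "g1 or g2 and g3", "(g1 or g2) and (g3 or g4)",
         "g1, g2, g3", "((g1 and g2) or g3) and g4"],
    )
    def test_truth_table_against_python_eval(self, expression):
        rule = GprRule(expression)
        genes = sorted(rule.genes())
        assert len(genes) <= 10
        for bits in itertools.product((0, 1), repeat=len(genes)):
            deleted = {g for g, bit in zip(genes, bits) if bit}
            assert rule.evaluate(deleted) == gpr_eval_python(expression, deleted)

    def test_to_string_round_trip(self):
        rule = GprRule("(g1 and g2) or g3, g4")
        again = GprRule(rule.to_string())
        assert again == rule

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**6 - 1))
    def test_random_deletions_match_oracle(self, mask):
        expression = "(gA and gB) or (gC and gD) or gE and gF"
        genes = ["gA", "gB", "gC", "gD", "gE", "gF"]
        deleted = {g for k, g in enumerate(genes) if mask >> k & 1}
        assert GprRule(expression).evaluate(deleted) == gpr_eval_python(
            expression, deleted
        )

    def test_no_deletion_is_true_for_all_mini_rules(self, mini_model):
        for rxn in mini_model.reactions:
            assert rxn.gpr.evaluate(set()) is True


class TestReactionsInvolving:
    def test_counts_in_toy(self):
        model = MetabolicModel("toy")
        model.add_metabolite(Metabolite("nadph", compartment="c"))
        model.add_metabolite(Metabolite("x", compartment="c"))
        for k in range(5):
            stoich = {"x": 1.0} if k >= 3 else {"nadph": -1.0, "x": 1.0}
            model.add_reaction(Reaction(f"R{k}", stoichiometry=stoich))
        assert reactions_involving(model, "nadph") == {"R0", "R1", "R2"}

    def test_unused_metabolite_empty_set(self):
        model = two_met_model()
        model.add_metabolite(Metabolite("C", compartment="c"))
        assert reactions_involving(model, "C") == set()

    def test_unknown_metabolite_raises(self, mini_model):
        with pytest.raises(KeyError):
            reactions_involving(mini_model, "nonexistent[c]")

    def test_mini_nadph_set_matches_ground_truth(self, mini_model, mini_truth):
        found = reactions_involving(mini_model, "nadph[c]")
        assert found == set(mini_truth.nadph_reactions)

    def test_compartment_filter(self, mini_model):
        assert reactions_involving(mini_model, "nadph[c]", "m") == set()
        assert reactions_involving(mini_model, "nadph[c]", "c")


class TestValidation:
    def test_duplicate_metabolite_rejected(self):
        model = two_met_model()
        with pytest.raises(ModelStructureError, match="duplicate"):
            model.add_metabolite(Metabolite("A", compartment="c"))

    def test_exchange_must_be_extracellular(self):
        model = MetabolicModel("bad")
        model.add_metabolite(Metabolite("A", compartment="c"))
        model.add_reaction(
            Reaction("EX_A", stoichiometry={"A": -1.0}, rtype="exchange")
        )
        with pytest.raises(ModelStructureError, match="extracellular"):
            model.validate()

    def test_transport_needs_two_compartments(self):
        model = two_met_model()
        model.reactions[0].rtype = "transport"
        with pytest.raises(ModelStructureError, match="compartments"):
            model.validate()

    def test_crossed_bounds_rejected(self):
        model = two_met_model()
        model.reactions[0].bounds = (5.0, 1.0)
        with pytest.raises(ModelStructureError, match="bound"):
            model.validate()

    def test_gene_list_must_match_gpr_union(self):
        model = two_met_model()
        model.genes.append("phantom")
        with pytest.raises(ModelStructureError, match="phantom"):
            model.validate()

    def test_mini_model_validates(self, mini_model):
        mini_model.validate()


def test_parse_formula():
    assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
    assert parse_formula("H2O") == {"H": 2, "O": 1}
    assert parse_formula("CHO") == {"C": 1, "H": 1, "O": 1}
    with pytest.raises(ValueError):
        parse_formula("2HO")
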