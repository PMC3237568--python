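"""Reaction-network core: table dialect, validation, stoichiometry,
conserved moieties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from egfrnet.network import (
    ConservationLaw,
    Law,
    Model,
    ModelError,
    Param,
    ParseError,
    Reaction,
    Species,
    complex_name,
    conserved_moieties,
    expand_enzymatic,
    moiety_count,
    parse_reaction_table,
    validate_model,
    write_reaction_table,
)
from egfrnet.synthetic import generate_random_massaction

RHEAD = "id\tequation\tlaw\tkf\tkr\tK\tkcat\ttags\tsource\n"
IHEAD = "species\tcompartment\tamount_nM\tsource\n"


class TestGrammar:
    def test_complex_name_canonical_and_merging(self):
        assert complex_name("EGFR", "EGF") == "EGF:EGFR"
        assert complex_name("EGF:EGFR", "Shc") == complex_name("Shc", "EGF", "EGFR")

    def test_moiety_count_matches_phospho_forms(self):
        assert moiety_count("EGF:EGF:p-EGFR:p-EGFR", "EGFR") == 2
        assert moiety_count("Grb2:SOS", "EGFR") == 0
        assert moiety_count("p-ERK", "ERK") == 1

    def test_species_invariants(self):
        with pytest.raises(ModelError):
            Species("bad name!")
        with pytest.raises(ModelError):
            Species("A", initial_amount=-1.0)
        with pytest.raises(ModelError):
            Species("A", compartment="nucleus")

    def test_rate_constants_strictly_positive(self):
        with pytest.raises(ModelError):
            Param("k", 0.0)
        with pytest.raises(ModelError):
            Param("k", float("nan"))

    def test_molecularity_capped_at_two(self):
        with pytest.raises(ModelError):
            Reaction("r", ("A", "B", "C"), ("D",), Law.MASS_ACTION_IRREVERSIBLE,
                     {"kf": Param("k", 1.0)})


class TestParse:
    def test_empty_tables_give_empty_model(self):
        m = parse_reaction_table(RHEAD, IHEAD)
        assert len(m.species) == 0 and len(m.reactions) == 0

    def test_reversible_binding_row(self):
        rt = RHEAD + "r1\tEGF + EGFR <-> EGF:EGFR\tmass_action_reversible\t0.1\t0.2\t\t\t\t\n"
        it = IHEAD + "EGF\tmembrane\t100\t\nEGFR\tmembrane\t150\t\nEGF:EGFR\tmembrane\t0\t\n"
        m = parse_reaction_table(rt, it)
        assert len(m.species) == 3
        assert len(m.reactions) == 1
        rxn = m.reactions[0]
        assert rxn.law is Law.MASS_ACTION_REVERSIBLE
        assert len(rxn.reactants) == 2
        assert rxn.constants["kf"].value == 0.1

    @pytest.mark.parametrize("row,match", [
        ("r1\tA -> X\tmass_action_irreversible\t1.0\t\t\t\t\t\n", "unknown species"),
        ("r1\tA -> A\tmass_action_irreversible\t-1.0\t\t\t\t\t\n", "rate constant"),
        ("r1\tA B\tmass_action_irreversible\t1.0\t\t\t\t\t\n", "malformed"),
        ("r1\tA -> A\tno_such_law\t1.0\t\t\t\t\t\n", "unknown law"),
    ])
    def test_row_addressed_errors(self, row, match):
        it = IHEAD + "A\tcytosol\t1\t\n"
        with pytest.raises(ParseError, match=match):
            parse_reaction_table(RHEAD + row, it)

    def test_duplicate_reaction_id_rejected(self):
        rt = RHEAD + ("r1\tA -> B\tmass_action_irreversible\t1.0\t\t\t\t\t\n" * 2)
        it = IHEAD + "A\tcytosol\t1\t\nB\tcytosol\t0\t\n"
        with pytest.raises(ParseError, match="duplicate reaction id"):
            parse_reaction_table(rt, it)

    def test_shared_parameter_names_survive(self):
        rt = RHEAD + ("r1\tA -> B\tmass_action_irreversible\tkshared=0.5\t\t\t\t\t\n"
                      "r2\tB -> A\tmass_action_irreversible\tkshared=0.5\t\t\t\t\t\n")
        it = IHEAD + "A\tcytosol\t1\t\nB\tcytosol\t0\t\n"
        m = parse_reaction_table(rt, it)
        assert m.n_parameters == 1
        assert m.parameters == {"kshared": 0.5}

    def test_enzymatic_rows_expand_to_elementary_steps(self):
        rt = RHEAD + "r1\tE + S -> E + P\tenzymatic_two_step\t\t\t0.01\t5.0\t\t\n"
        it = IHEAD + "E\tcytosol\t10\t\nS\tcytosol\t100\t\nP\tcytosol\t0\t\n"
        m = parse_reaction_table(rt, it)
        assert len(m.reactions) == 2
        laws = {r.law for r in m.reactions}
        assert laws == {Law.MASS_ACTION_REVERSIBLE, Law.MASS_ACTION_IRREVERSIBLE}
        assert complex_name("E", "S") in m.species_names


class TestRoundTrip:
    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_write_then_parse_is_identity(self, seed):
        model = generate_random_massaction(6, 9, seed)
        rt, it = write_reaction_table(model)
        again = parse_reaction_table(rt, it)
        assert model.structurally_equal(again)

    def test_two_writes_byte_identical(self):
        model = generate_random_massaction(5, 7, seed=3)
        assert write_reaction_table(model) == write_reaction_table(model)

    def test_zero_reaction_model_writes_header_only(self):
        rt, it = write_reaction_table(Model())
        assert rt.strip().splitlines() == [rt.strip().splitlines()[0]]
        assert len(it.strip().splitlines()) == 1


class TestValidate:
    def test_valid_toy_model_empty_report(self):
        m = generate_random_massaction(4, 5, seed=0)
        assert validate_model(m) == []

    def test_undeclared_species_reported_by_name(self):
        m = Model([Species("A", initial_amount=1.0)],
                  [Reaction("r", ("A",), ("X",), Law.MASS_ACTION_IRREVERSIBLE,
                            {"kf": Param("k", 1.0)})])
        report = validate_model(m)
        assert any("'X'" in line for line in report)

    def test_orphan_species_reported(self):
        m = Model([Species("A", initial_amount=1.0), Species("B"),
                   Species("Lost")],
                  [Reaction("r", ("A",), ("B",), Law.MASS_ACTION_IRREVERSIBLE,
                            {"kf": Param("k", 1.0)})])
        assert any("orphan" in line and "Lost" in line
                   for line in validate_model(m))

    def test_conflicting_shared_parameter_reported(self):
        m = Model([Species("A", initial_amount=1.0), Species("B")],
                  [Reaction("r1", ("A",), ("B",), Law.MASS_ACTION_IRREVERSIBLE,
                            {"kf": Param("k", 1.0)}),
                   Reaction("r2", ("B",), ("A",), Law.MASS_ACTION_IRREVERSIBLE,
                            {"kf": Param("k", 2.0)})])
        assert any("conflicting" in line for line in validate_model(m))


class TestStoichiometry:
    def test_entries_bounded_by_molecularity(self):
        for seed in range(5):
            S = generate_random_massaction(6, 10, seed).stoichiometry_matrix()
            assert S.min() >= -2 and S.max() <= 2

    def test_single_conversion_conservation_law(self):
        m = Model([Species("A", initial_amount=1.0), Species("B")],
                  [Reaction("r", ("A",), ("B",), Law.MASS_ACTION_IRREVERSIBLE,
                            {"kf": Param("k", 1.0)})])
        laws = conserved_moieties(m)
        assert len(laws) == 1
        assert laws[0].coefficients == {"A": 1, "B": 1}

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_laws_lie_in_left_null_space_exactly(self, seed):
        m = generate_random_massaction(6, 9, seed)
        S = m.stoichiometry_matrix()
        idx = m.species_index
        for law in conserved_moieties(m):
            v = np.zeros(len(m.species), dtype=int)
            for name, c in law.coefficients.items():
                v[idx[name]] = c
            assert np.all(v @ S == 0)          # exact integer arithmetic
            assert np.any(v != 0)

    def test_conversion_only_model_conserves_total_mass(self):
        m = generate_random_massaction(5, 8, seed=7, conversion_only=True)
        laws = conserved_moieties(m)
        totals = [law for law in laws
                  if set(law.coefficients.values()) == {1}
                  and len(law.coefficients) == len(m.species)]
        assert totals, "total-mass law missing from a pure conversion network"


class TestEnzymaticExpansion:
    def test_expansion_is_mass_consistent(self):
        m = Model([Species("E", initial_amount=1.0),
                   Species("S", initial_amount=5.0), Species("P")],
                  [Reaction("r", ("E", "S"), ("E", "P"), Law.ENZYMATIC_TWO_STEP,
                            {"K": Param("K", 0.1), "kcat": Param("kcat", 2.0)})])
        out = expand_enzymatic(m, unbinding_kd_nm=10.0)
        assert len(out.reactions) == 2
        # enzyme moiety is conserved across the expansion
        laws = conserved_moieties(out, within={"E", complex_name("E", "S")})
        assert any(law.support == {"E", complex_name("E", "S")} for law in laws)
        kr = out.reactions[0].constants["kr"].value
        assert kr == pytest.approx(0.1 * 10.0)
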