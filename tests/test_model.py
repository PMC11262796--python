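"""Model structures, GPR logic, stoichiometric matrix, and model I/O."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluxshift.io import (
    NativeFormatError,
    SBMLFormatError,
    read_native,
    read_sbml,
    write_native,
)
from fluxshift.model import (
    GPRSyntaxError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    evaluate_gpr,
    gpr_genes,
    parse_gpr,
    stoichiometric_matrix,
)
from oracles import brute_force_gpr


class TestValidation:
    def test_duplicate_reaction_ids_rejected(self):
        with pytest.raises(ModelValidationError, match="duplicate reaction"):
            MetabolicModel(
                metabolites=[Metabolite("A")],
                reactions=[
                    Reaction("R", {"A": 1}),
                    Reaction("R", {"A": -1}),
                ],
            )

    def test_undeclared_metabolite_rejected(self):
        with pytest.raises(ModelValidationError, match="undeclared"):
            MetabolicModel(
                metabolites=[Metabolite("A")],
                reactions=[Reaction("R", {"A": -1, "GHOST": 1})],
            )

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelValidationError, match="lb"):
            Reaction("R", {}, lb=5, ub=1)


class TestStoichiometricMatrix:
    @pytest.mark.parametrize(
        "stoich, expected",
        [
            ({"A": -1, "B": 1}, [-1.0, 1.0]),  # A -> B sign convention
            ({"A": -2, "B": 1}, [-2.0, 1.0]),  # 2A -> B
            ({"A": 1}, [1.0, 0.0]),  # boundary source -> A
        ],
    )
    def test_column_signs(self, stoich, expected):
        model = MetabolicModel(
            metabolites=[Metabolite("A"), Metabolite("B")],
            reactions=[Reaction("R", stoich)],
        )
        S = stoichiometric_matrix(model)
        assert S.shape == (2, 1)
        assert S[:, 0].tolist() == expected

    def test_shape_matches_model(self, toy_model):
        S = stoichiometric_matrix(toy_model)
        assert S.shape == (len(toy_model.metabolites), len(toy_model.reactions))


class TestGPR:
    @pytest.mark.parametrize(
        "expr, calls, expected",
        [
            ("g1 and g2", {"g1": "present", "g2": "absent"}, "inactive"),
            ("g1 or g2", {"g1": "absent", "g2": "present"}, "active"),
            ("", {}, "active"),
            # unknown resolved by a sibling
            ("g1 or g2", {"g1": "present"}, "active"),
            ("g1 and g2", {"g1": "absent"}, "inactive"),
            # unknown propagates when unresolved
            ("g1 and g2", {"g1": "present"}, "unknown"),
            ("g1 or g2", {"g1": "absent"}, "unknown"),
            ("(g1 AND g2) OR g3", {"g1": "absent", "g3": "present"}, "active"),
        ],
    )
    def test_three_valued_semantics(self, expr, calls, expected):
        assert evaluate_gpr(expr, calls) == expected

    @pytest.mark.parametrize("expr", ["g1 and", "(g1 or g2", "and g1", "g1 g2"])
    def test_syntax_errors(self, expr):
        with pytest.raises(GPRSyntaxError):
            parse_gpr(expr)

    def test_gene_extraction(self):
        assert gpr_genes("(a and b) or (b and c)") == ["a", "b", "c"]

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_truth_table(self, data):
        """On fully measured genes, three-valued evaluation must reduce to
        a plain boolean truth table, for random expressions of <= 10 genes."""
        genes = [f"g{i}" for i in range(data.draw(st.integers(2, 10)))]

        def random_expr(depth):
            if depth == 0 or data.draw(st.booleans()):
                return data.draw(st.sampled_from(genes))
            op = data.draw(st.sampled_from(["and", "or"]))
            return (
                f"({random_expr(depth - 1)} {op} {random_expr(depth - 1)})"
            )

        expr = random_expr(3)
        tree = parse_gpr(expr)
        used = gpr_genes(expr)
        assert len(used) <= 10
        for values in itertools.product([True, False], repeat=len(used)):
            assignment = dict(zip(used, values))
            calls = {
                g: ("present" if v else "absent") for g, v in assignment.items()
            }
            expected = "active" if brute_force_gpr(tree, assignment) else "inactive"
            assert evaluate_gpr(expr, calls) == expected


class TestNativeRoundTrip:
    def test_round_trip_exact(self, toy_model, tmp_path):
        write_native(toy_model, tmp_path)
        back = read_native(tmp_path)
        assert back.reaction_ids == toy_model.reaction_ids
        assert back.metabolite_ids == toy_model.metabolite_ids
        for orig, new in zip(toy_model.reactions, back.reactions):
            assert new.stoich == orig.stoich
            assert (new.lb, new.ub) == (orig.lb, orig.ub)
            assert new.gpr == orig.gpr
            assert new.subsystem == orig.subsystem

    def test_empty_gpr_preserved(self, tmp_path):
        model = MetabolicModel(
            metabolites=[Metabolite("A")],
            reactions=[Reaction("R", {"A": 1}, 0, 1, gpr="")],
        )
        write_native(model, tmp_path)
        assert read_native(tmp_path).reactions[0].gpr == ""

    def test_missing_bounds_column_is_parse_error(self, tmp_path):
        (tmp_path / "metabolites.tsv").write_text(
            "id\tcompartment\tname\nA\tc\t\n", encoding="utf-8"
        )
        (tmp_path / "reactions.tsv").write_text(
            "id\tequation\tgpr\tsubsystem\nR\t <=> A\t\t\n", encoding="utf-8"
        )
        with pytest.raises(NativeFormatError, match="missing required columns"):
            read_native(tmp_path)

    def test_malformed_equation_reports_line(self, tmp_path):
        (tmp_path / "metabolites.tsv").write_text(
            "id\tcompartment\tname\nA\tc\t\n", encoding="utf-8"
        )
        (tmp_path / "reactions.tsv").write_text(
            "id\tequation\tlb\tub\tgpr\tsubsystem\n"
            "R\tA -- B\t0\t1\t\t\n",
            encoding="utf-8",
        )
        with pytest.raises(NativeFormatError, match="line 2"):
            read_native(tmp_path)


class TestSBML:
    def test_l3_fbc_model(self, sbml_l3_path):
        model = read_sbml(sbml_l3_path)
        assert model.reaction_ids == ["SRC", "AB", "SNK"]
        ab = model.get_reaction("AB")
        assert ab.stoich == {"A": -2.0, "B": 1.0}
        assert (ab.lb, ab.ub) == (-1000.0, 1000.0)
        # fbc nested and/or association
        assert evaluate_gpr(ab.gpr, {"g1": "present", "g3": "present"}) == "active"
        assert evaluate_gpr(ab.gpr, {"g1": "absent"}) == "inactive"
        assert any("fbc" in line for line in model.provenance)

    def test_l2_notes_model_defaults(self, sbml_l2_path):
        model = read_sbml(sbml_l2_path)
        src = model.get_reaction("SRC")
        assert (src.lb, src.ub) == (0.0, 10.0)  # kinetic-law bounds
        ab = model.get_reaction("AB")
        assert (ab.lb, ab.ub) == (0.0, 1000.0)  # irreversible default
        assert gpr_genes(ab.gpr) == ["g1", "g2", "g3"]
        assert any("notes" in line for line in model.provenance)

    def test_minimal_one_reaction_model(self, tmp_path):
        text = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="m1">
    <listOfCompartments><compartment id="c"/></listOfCompartments>
    <listOfSpecies><species id="A" compartment="c"/></listOfSpecies>
    <listOfReactions>
      <reaction id="EX_A" reversible="true">
        <listOfProducts><speciesReference species="A"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
        path = tmp_path / "one.xml"
        path.write_text(text, encoding="utf-8")
        model = read_sbml(path)
        assert len(model.reactions) == 1
        assert model.reactions[0].lb == -1000.0  # reversible default

    def test_undeclared_species_is_error(self, sbml_bad_ref_path):
        with pytest.raises(SBMLFormatError, match="MISSING"):
            read_sbml(sbml_bad_ref_path)

    def test_agrees_with_cobra_reader(self, sbml_l3_path):
        """Independent cross-check: cobrapy reads the same file to the same
        stoichiometry, bounds and gene sets."""
        cobra_io = pytest.importorskip("cobra.io")
        ours = read_sbml(sbml_l3_path)
        theirs = cobra_io.read_sbml_model(str(sbml_l3_path))
        assert sorted(r.id for r in theirs.reactions) == sorted(ours.reaction_ids)
        for rx in theirs.reactions:
            mine = ours.get_reaction(rx.id)
            assert mine.lb == rx.lower_bound
            assert mine.ub == rx.upper_bound
            theirs_stoich = {m.id: c for m, c in rx.metabolites.items()}
            assert theirs_stoich == mine.stoich
            assert sorted(g.id for g in rx.genes) == gpr_genes(mine.gpr)

    def test_sbml_native_round_trip_preserves_structure(
        self, sbml_l3_path, tmp_path
    ):
        model = read_sbml(sbml_l3_path)
        write_native(model, tmp_path / "native")
        back = read_native(tmp_path / "native")
        assert back.reaction_ids == model.reaction_ids
        assert len(back.metabolites) == len(model.metabolites)
        for a, b in zip(model.reactions, back.reactions):
            assert (a.lb, a.ub) == (b.lb, b.ub)
            # GPR truth tables identical over all assignments
            genes = gpr_genes(a.gpr)
            assert genes == gpr_genes(b.gpr)
            for values in itertools.product(
                ["present", "absent"], repeat=len(genes)
            ):
                calls = dict(zip(genes, values))
                assert evaluate_gpr(a.gpr, calls) == evaluate_gpr(b.gpr, calls)
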