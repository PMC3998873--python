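"""I/O round trips, GPR grammar, and table validation."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from coccoa import model_io
from coccoa.model_io import (
    GeneAssociation,
    GeneLeaf,
    GprAnd,
    GprOr,
    MetabolicNetwork,
    ParseError,
    PhysiologyTable,
    Reaction,
    Species,
    ValidationError,
    parse_gpr,
)
from conftest import branched_network, chain_network, expr_from_lnfc


class TestGprGrammar:
    def test_nested_and_or(self):
        tree = parse_gpr("(g1 and g2) or g3")
        assert isinstance(tree.root, GprOr)
        and_node, leaf = tree.root.children
        assert isinstance(and_node, GprAnd)
        assert {c.gene for c in and_node.children} == {"g1", "g2"}
        assert isinstance(leaf, GeneLeaf) and leaf.gene == "g3"

    @pytest.mark.parametrize("bad", ["g1 and (g2 or", "and g1", "g1 or or g2", "(g1"])
    def test_malformed_names_reaction(self, bad):
        with pytest.raises(ParseError, match="R_test"):
            parse_gpr(bad, context="R_test")

    def test_empty_is_orphan(self):
        assert parse_gpr("").empty
        assert parse_gpr("   ").genes() == frozenset()

    @pytest.mark.parametrize(
        "text",
        [
            "g1",
            "g1 and g2 and g3",
            "g1 or g2 or g3",
            "(g1 or g2) and (g3 or (g4 and g5))",
            "g1 and (g2 or g3) and g4",
            "((g1))",
        ],
    )
    def test_reserialization_is_logically_equivalent(self, text):
        # truth table over every gene subset
        tree = parse_gpr(text)
        again = parse_gpr(tree.to_string())
        genes = sorted(tree.genes())
        assert again.genes() == tree.genes()
        for bits in itertools.product([False, True], repeat=len(genes)):
            present = dict(zip(genes, bits))
            assert tree.evaluate(present) == again.evaluate(present)

    def test_cross_check_against_cobra_parser(self):
        cobra = pytest.importorskip("cobra")
        text = "(g1 and g2) or (g3 and (g4 or g5))"
        ours = parse_gpr(text)
        theirs = cobra.core.gene.GPR.from_string(text)
        assert set(theirs.genes) == set(ours.genes())
        for bits in itertools.product([False, True], repeat=5):
            present = dict(zip(sorted(ours.genes()), bits))
            knockouts = {g for g, on in present.items() if not on}
            assert ours.evaluate(present) == theirs.eval(knockouts)


class TestSbmlRoundTrip:
    def test_toy_network_round_trips(self, tmp_path):
        net = branched_network()
        path = tmp_path / "toy.xml"
        model_io.write_sbml(net, path)
        back = model_io.read_sbml(path)
        assert len(back.reactions) == len(net.reactions)
        for a, b in zip(net.reactions, back.reactions):
            assert a.id == b.id
            assert a.stoichiometry == b.stoichiometry
            assert a.reversible == b.reversible
            assert a.gpr.genes() == b.gpr.genes()
            assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
        assert {m.id for m in back.metabolites} == {m.id for m in net.metabolites}

    def test_complex_gpr_survives(self, tmp_path):
        sp = [Species("A"), Species("B")]
        rxn = Reaction("R1", {"A": -1.0, "B": 1.0}, gpr=parse_gpr("(g1 and g2) or g3"))
        net = MetabolicNetwork(sp, [rxn, Reaction("R_in", {"A": 1.0}), Reaction("R_out", {"B": -1.0})])
        path = tmp_path / "gpr.xml"
        model_io.write_sbml(net, path)
        back = model_io.read_sbml(path)
        tree = back.reaction("R1").gpr
        assert isinstance(tree.root, GprOr)
        assert tree.genes() == {"g1", "g2", "g3"}

    def test_cobra_reads_our_sbml(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        net = branched_network()
        path = tmp_path / "toy.xml"
        model_io.write_sbml(net, path)
        model = cobra.io.read_sbml_model(str(path))
        # cobra strips the legacy R_ prefix from reaction ids on read
        cobra_id = lambda rid: rid[2:] if rid.startswith("R_") else rid
        assert {r.id for r in model.reactions} == {cobra_id(r.id) for r in net.reactions}
        ours = net.reaction("R_AB")
        theirs = model.reactions.get_by_id("AB")
        assert {m.id for m in theirs.metabolites} == set(ours.stoichiometry)
        assert {g.id for g in theirs.genes} == set(ours.gpr.genes())

    def test_malformed_sbml_raises(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<sbml><model><broken/></sbml>")
        with pytest.raises(ParseError):
            model_io.read_sbml(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(model_io.CoccoaError):
            model_io.read_sbml(tmp_path / "nope.xml")


class TestNetworkInvariants:
    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ValidationError, match="unknown metabolite"):
            MetabolicNetwork([Species("A")], [Reaction("R", {"A": -1.0, "B": 1.0})])

    def test_zero_coefficient_rejected(self):
        with pytest.raises(ValidationError, match="zero coefficient"):
            MetabolicNetwork([Species("A")], [Reaction("R", {"A": 0.0})])

    def test_irreversible_negative_lower_bound_rejected(self):
        with pytest.raises(ValidationError, match="negative lower bound"):
            MetabolicNetwork(
                [Species("A")],
                [Reaction("R", {"A": -1.0}, reversible=False, lower_bound=-5.0)],
            )


class TestExpressionTable:
    def test_read_well_formed(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tlog2fc\tpvalue\ng1\t1.0\t0.01\ng2\t-0.5\t0.2\ng3\t0.0\t1.0\n")
        t = model_io.read_expression(p)
        assert len(t) == 3
        assert t.lnfc_map()["g1"] == pytest.approx(math.log(2))

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tlog2fc\tpvalue\ng1\t1.0\t0.01\ng1\t0.5\t0.2\n")
        with pytest.raises(ValidationError, match="g1"):
            model_io.read_expression(p)

    def test_out_of_range_pvalue_rejected(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tlog2fc\tpvalue\ng1\t1.0\t1.2\n")
        with pytest.raises(ValidationError, match="P-value"):
            model_io.read_expression(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tfold\ng1\t1.0\n")
        with pytest.raises(ValidationError, match="log2fc"):
            model_io.read_expression(p)

    def test_non_numeric_row_located(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tlog2fc\tpvalue\ng1\t1.0\t0.01\ng2\toops\t0.2\n")
        with pytest.raises(ValidationError, match="line 3"):
            model_io.read_expression(p)

    def test_round_trip(self, tmp_path):
        t = expr_from_lnfc({"g1": 0.3, "g2": -0.7})
        p = tmp_path / "expr.tsv"
        model_io.write_expression(t, p, header="test")
        back = model_io.read_expression(p)
        pd.testing.assert_frame_equal(back.data, t.data)


class TestScoreTable:
    def test_empty_list_gives_header_only(self, tmp_path):
        p = tmp_path / "scores.tsv"
        model_io.write_scores([], p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == model_io.SCORE_COLUMNS

    def test_single_score_round_trips(self, tmp_path):
        from coccoa.coccoa_engine import CoCCoAScore

        s = CoCCoAScore(
            metabolite="M1",
            upstream_distance=1,
            downstream_distance=0,
            score=-0.25,
            gene_ids=frozenset({"g1", "g2"}),
            used_measured_neighbors=True,
        )
        p = tmp_path / "scores.tsv"
        model_io.write_scores([s], p)
        df = model_io.read_scores(p)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["metabolite"] == "M1"
        assert row["score"] == pytest.approx(-0.25)
        assert row["n_genes"] == 2
        assert set(row["gene_ids"].split(";")) == {"g1", "g2"}
        assert row["used_measured_neighbors"] == 1

    def test_gene_count_matches_gene_set(self, tmp_path):
        from coccoa.coccoa_engine import CoCCoAScore

        genes = frozenset(f"g{i:02d}" for i in range(47))
        s = CoCCoAScore("M1", 2, 0, 0.1, genes)
        p = tmp_path / "scores.tsv"
        model_io.write_scores([s], p)
        df = model_io.read_scores(p)
        assert df.iloc[0]["n_genes"] == 47
        assert len(df.iloc[0]["gene_ids"].split(";")) == 47


class TestPhysiologyAndMapping:
    def test_round_trip_with_growth(self, tmp_path):
        t = PhysiologyTable(
            bounds={"a": {"EX_glc": (-11.0, -9.0)}, "b": {"EX_glc": (-5.0, -5.0)}},
            growth_rate={"a": 0.1, "b": None},
        )
        p = tmp_path / "phys.tsv"
        model_io.write_physiology(t, p)
        back = model_io.read_physiology(p)
        assert back.bounds == t.bounds
        assert back.growth_rate["a"] == pytest.approx(0.1)
        assert back.growth_rate["b"] is None

    def test_lower_above_upper_rejected(self):
        with pytest.raises(ValidationError, match="lower > upper"):
            PhysiologyTable(bounds={"a": {"EX_glc": (5.0, 2.0)}})

    def test_mapping_read(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("measured\tspecies\nglucose 6-phosphate\tg6p_c\ncitrate\tcit_c\n")
        m = model_io.read_mapping(p)
        assert m == {"glucose 6-phosphate": "g6p_c", "citrate": "cit_c"}


class TestCompartmentPooling:
    def test_merges_species_and_drops_pure_transport(self):
        sp = [
            Species("pyr_c", name="pyruvate", compartment="c"),
            Species("pyr_m", name="pyruvate", compartment="m"),
            Species("acc_m", name="acetylcoa", compartment="m"),
        ]
        rxns = [
            Reaction("IN", {"pyr_c": 1.0}),
            Reaction("T_pyr", {"pyr_c": -1.0, "pyr_m": 1.0}, gpr=parse_gpr("gT")),
            Reaction("PDH", {"pyr_m": -1.0, "acc_m": 1.0}, gpr=parse_gpr("gP")),
            Reaction("OUT", {"acc_m": -1.0}),
        ]
        net = MetabolicNetwork(sp, rxns)
        merged = model_io.merge_compartment_pools(net)
        ids = {m.id for m in merged.metabolites}
        assert ids == {"pyruvate", "acetylcoa"}
        assert {r.id for r in merged.reactions} == {"IN", "PDH", "OUT"}  # transport gone
        pdh = merged.reaction("PDH")
        assert pdh.stoichiometry == {"pyruvate": -1.0, "acetylcoa": 1.0}
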