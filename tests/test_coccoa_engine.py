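"""Coupling-score recursion: degrees, weighting, truncation, invariants."""

from __future__ import annotations

import math

import numpy as np
import pytest

from coccoa.coccoa_engine import (
    KineticAdjustment,
    build_graph,
    score_degree0,
    score_degree1,
    score_degree_n,
    score_grid,
)
from coccoa.expression_mapping import reaction_deltas
from coccoa.model_io import (
    CoccoaError,
    MetabolicNetwork,
    Reaction,
    Species,
    parse_gpr,
)
from conftest import chain_network, expr_from_lnfc


def graph_for(net: MetabolicNetwork, lnfc: dict[str, float], **kwargs):
    return build_graph(net, reaction_deltas(net, expr_from_lnfc(lnfc)), **kwargs)


def two_consumer_net() -> MetabolicNetwork:
    sp = [Species("S"), Species("P")]
    rxns = [
        Reaction("R_in", {"S": 1.0}, gpr=parse_gpr("gp")),
        Reaction("Rc1", {"S": -1.0, "P": 1.0}, gpr=parse_gpr("gc1")),
        Reaction("Rc2", {"S": -1.0, "P": 1.0}, gpr=parse_gpr("gc2")),
        Reaction("R_out", {"P": -1.0}),
    ]
    return MetabolicNetwork(sp, rxns)


class TestDegree0:
    def test_single_consumer(self):
        g = graph_for(chain_network(2), {"g1": 0.7})
        assert score_degree0("M1", g).score == pytest.approx(-0.7)

    def test_two_consumers_geometric_mean(self):
        g = graph_for(two_consumer_net(), {"gc1": 0.2, "gc2": 0.8})
        assert score_degree0("S", g).score == pytest.approx(-0.5)

    def test_no_consumer_data_gives_no_score(self):
        g = graph_for(two_consumer_net(), {"gp": 0.5})
        assert score_degree0("S", g) is None

    def test_uses_only_consuming_genes(self):
        g = graph_for(two_consumer_net(), {"gp": 9.9, "gc1": 0.4, "gc2": 0.4})
        s = score_degree0("S", g)
        assert s.score == pytest.approx(-0.4)
        assert s.gene_ids == {"gc1", "gc2"}


class TestDegree1:
    def test_production_minus_consumption(self):
        g = graph_for(chain_network(3), {"g1": 0.3, "g2": 0.5})
        assert score_degree1("M2", g).score == pytest.approx(0.3 - 0.5)

    def test_balanced_regulation_predicts_homeostasis(self):
        g = graph_for(chain_network(3), {"g1": 0.4, "g2": 0.4})
        assert score_degree1("M2", g).score == pytest.approx(0.0)

    def test_measured_precursor_term_added(self):
        g = graph_for(chain_network(3), {"g1": 0.3, "g2": 0.5})
        s = score_degree1("M2", g, measured={"M1": 0.25})
        assert s.score == pytest.approx(0.3 - 0.5 + 0.25)
        assert s.used_measured_neighbors
        assert s.truncation_metabolites == {"M1"}


class TestDegreeN:
    def test_unbranched_chain_second_degree_formula(self):
        lnfc = {"g1": 0.11, "g2": 0.42, "g3": -0.27}
        g = graph_for(chain_network(4), lnfc)
        s = score_degree_n("M3", g, 2, 0)
        # Dprod(M3) - Dcons(M3) + Dprod(M2) - Dcons(M2)
        expect = lnfc["g2"] - lnfc["g3"] + lnfc["g1"] - lnfc["g2"]
        assert s.score == pytest.approx(expect, abs=1e-14)

    def test_downstream_telescoping_to_measured_product(self):
        lnfc = {"g1": 0.2, "g2": -0.4, "g3": 0.6, "g4": 0.1}
        g = graph_for(chain_network(4), lnfc)
        s = score_degree_n("M1", g, 0, 3, measured={"M4": 0.5})
        # -Dcons(M1) + Dcons(M4) + ln(M4/M4*)
        assert s.score == pytest.approx(-lnfc["g1"] + lnfc["g4"] + 0.5, abs=1e-14)

    def test_branch_point_weights_split_equally(self):
        # S has two producers, each fed by its own precursor
        sp = [Species(x) for x in ("S", "R1", "R2", "Q1", "Q2")]
        rxns = [
            Reaction("in1", {"Q1": 1.0}),
            Reaction("in2", {"Q2": 1.0}),
            Reaction("a1", {"Q1": -1.0, "R1": 1.0}, gpr=parse_gpr("ga1")),
            Reaction("a2", {"Q2": -1.0, "R2": 1.0}, gpr=parse_gpr("ga2")),
            Reaction("p1", {"R1": -1.0, "S": 1.0}, gpr=parse_gpr("gp1")),
            Reaction("p2", {"R2": -1.0, "S": 1.0}, gpr=parse_gpr("gp2")),
            Reaction("out", {"S": -1.0}, gpr=parse_gpr("go")),
        ]
        net = MetabolicNetwork(sp, rxns)
        lnfc = {"ga1": 0.3, "ga2": -0.5, "gp1": 0.1, "gp2": 0.2, "go": 0.4}
        g = graph_for(net, lnfc)
        s = score_degree_n("S", g, 2, 0)
        dprod_s = (lnfc["gp1"] + lnfc["gp2"]) / 2
        term_r1 = lnfc["ga1"] - lnfc["gp1"]  # Dprod(R1) - Dcons(R1)
        term_r2 = lnfc["ga2"] - lnfc["gp2"]
        expect = dprod_s - lnfc["go"] + 0.5 * term_r1 + 0.5 * term_r2
        assert s.score == pytest.approx(expect, abs=1e-14)

    def test_negative_distance_rejected(self):
        g = graph_for(chain_network(2), {"g1": 0.1})
        with pytest.raises(CoccoaError):
            score_degree_n("M1", g, -1, 0)

    def test_unknown_metabolite_rejected(self):
        g = graph_for(chain_network(2), {"g1": 0.1})
        with pytest.raises(CoccoaError, match="not in graph"):
            score_degree_n("XX", g, 1, 0)

    def test_distances_beyond_diameter_are_valid(self):
        lnfc = {"g1": 0.2, "g2": 0.3}
        g = graph_for(chain_network(2), lnfc)
        s = score_degree_n("M1", g, 10, 10)
        assert math.isfinite(s.score)

    def test_cycle_not_revisited(self):
        # A -> B -> A cycle plus exits; recursion must terminate
        sp = [Species("A"), Species("B")]
        rxns = [
            Reaction("in", {"A": 1.0}),
            Reaction("ab", {"A": -1.0, "B": 1.0}, gpr=parse_gpr("g_ab")),
            Reaction("ba", {"B": -1.0, "A": 1.0}, gpr=parse_gpr("g_ba")),
            Reaction("out", {"B": -1.0}, gpr=parse_gpr("g_out")),
        ]
        net = MetabolicNetwork(sp, rxns)
        g = graph_for(net, {"g_ab": 0.1, "g_ba": 0.2, "g_out": 0.3})
        s = score_degree_n("A", g, 5, 5)
        assert math.isfinite(s.score)

    def test_currency_metabolites_not_traversed(self):
        sp = [Species("S"), Species("atp_c"), Species("X")]
        rxns = [
            Reaction("in", {"S": 1.0}, gpr=parse_gpr("g_in")),
            # consumes S, regenerates ATP as a side product
            Reaction("use", {"S": -1.0, "atp_c": 1.0}, gpr=parse_gpr("g_use")),
            Reaction("drain", {"atp_c": -1.0, "X": 1.0}, gpr=parse_gpr("g_drain")),
            Reaction("out", {"X": -1.0}, gpr=parse_gpr("g_out")),
        ]
        net = MetabolicNetwork(sp, rxns)
        g = graph_for(net, {"g_in": 0.1, "g_use": 0.2, "g_drain": 9.0, "g_out": 9.0})
        s = score_degree_n("S", g, 3, 3)
        # downstream would pass through atp_c; exclusion keeps g_drain/g_out out
        assert "g_drain" not in s.gene_ids and "g_out" not in s.gene_ids

    def test_km_adjustment_subtracted_from_reaction_terms(self):
        lnfc = {"g1": 0.3, "g2": 0.5}
        g = graph_for(chain_network(3), lnfc)
        adj = KineticAdjustment({"R2": 0.2})
        s = score_degree1("M2", g, adjustment=adj)
        assert s.score == pytest.approx(0.3 - (0.5 - 0.2))

    def test_no_data_contributes_zero_but_scores_when_any_data(self):
        g = graph_for(chain_network(3), {"g2": 0.5})  # g1 unmeasured
        s = score_degree1("M2", g)
        assert s.score == pytest.approx(-0.5)
        assert s.gene_ids == {"g2"}
        assert score_degree1("M2", graph_for(chain_network(3), {})) is None


class TestScoreGrid:
    def test_distance4_grid_yields_16_plus_degree0(self):
        lnfc = {f"g{i+1}": 0.1 * (i + 1) for i in range(6)}
        g = graph_for(chain_network(6), lnfc)
        scores = score_grid("M3", g, max_distance=4)
        assert len(scores) == 17
        assert sum(1 for s in scores if (s.upstream_distance, s.downstream_distance) == (0, 0)) == 1

    def test_distance1_grid(self):
        g = graph_for(chain_network(3), {"g1": 0.1, "g2": 0.2})
        scores = score_grid("M2", g, max_distance=1)
        assert len(scores) == 2

    def test_gene_count_monotone_in_both_distances(self):
        lnfc = {f"g{i+1}": 0.1 for i in range(8)}
        g = graph_for(chain_network(8), lnfc)
        counts = {}
        for s in score_grid("M4", g, max_distance=4):
            counts[(s.upstream_distance, s.downstream_distance)] = len(s.gene_ids)
        for (du, dd), c in counts.items():
            if (du + 1, dd) in counts:
                assert counts[(du + 1, dd)] >= c
            if (du, dd + 1) in counts:
                assert counts[(du, dd + 1)] >= c

    def test_gene_count_plateaus_at_component_total(self):
        lnfc = {f"g{i+1}": 0.1 for i in range(5)}
        g = graph_for(chain_network(5), lnfc)
        big = score_grid("M3", g, max_distance=8)
        deepest = max(big, key=lambda s: (s.upstream_distance + s.downstream_distance))
        assert deepest.gene_ids == g.component_genes("M3")


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_condition_swap_negates_all_scores(self, seed):
        rng = np.random.default_rng(seed)
        lnfc = {f"g{i+1}": float(v) for i, v in enumerate(rng.normal(0, 0.6, 6))}
        net = chain_network(6)
        g_pos = graph_for(net, lnfc)
        g_neg = graph_for(net, {k: -v for k, v in lnfc.items()})
        measured = {"M5": 0.33}
        for du in range(0, 3):
            for dd in range(0, 3):
                a = score_degree_n("M3", g_pos, du, dd, measured)
                b = score_degree_n("M3", g_neg, du, dd, {"M5": -0.33})
                assert b.score == pytest.approx(-a.score, abs=1e-12)

    def test_nesting_degree1_equals_up1(self):
        rng = np.random.default_rng(3)
        lnfc = {f"g{i+1}": float(v) for i, v in enumerate(rng.normal(0, 0.5, 5))}
        g = graph_for(chain_network(5), lnfc)
        for met in ("M2", "M3", "M4"):
            assert score_degree_n(met, g, 1, 0).score == score_degree1(met, g).score

    def test_dilution_scores_stabilize_past_the_data_horizon(self):
        # only genes within two steps of M3 are significant; once the
        # recursion horizon passes them, unmeasured distant genes add
        # nothing and the scores (and gene sets) stay constant
        g = graph_for(chain_network(8), {"g2": 0.4, "g3": -0.2, "g4": 0.3})
        settled = score_degree_n("M3", g, 2, 2)
        for d in (3, 4, 5):
            deep = score_degree_n("M3", g, d, d)
            assert deep.score == pytest.approx(settled.score, abs=1e-14)
            assert deep.gene_ids == settled.gene_ids == {"g2", "g3", "g4"}
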