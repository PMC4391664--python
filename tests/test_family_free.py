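"""Gene similarity graph, matchings, reduced genomes, d_sigma / s_sigma."""

import numpy as np
import pytest

from ffdcj import (
    Component,
    GadgetParams,
    Matching,
    build_gs_graph,
    build_weighted_adjacency_graph,
    counterexample_instance,
    counterexample_matchings,
    dcj_distance,
    dsigma,
    dsigma_from_counts,
    enumerate_maximal_matchings,
    f_alpha,
    is_maximal_matching,
    load_fixture,
    parse_pair,
    random_instance,
    reduce_genomes,
    ssigma,
    weighted_component_contribution,
)
from ffdcj.adjacency import CYCLE, EVEN_PATH, ODD_PATH
from ffdcj.genomes import GenomeFormatError, SimilarityTable


@pytest.fixture(scope="module")
def fig4():
    return load_fixture("fig4")


class TestGeneSimilarityGraph:
    def test_fig4_degrees(self, fig4):
        g = build_gs_graph(fig4.genome_a, fig4.genome_b, fig4.similarities)
        # one-copy families have degree 1, two-copy families degree 2 on the
        # A side; every B gene sees exactly the single A copy of its family
        assert [g.degree_a(x) for x in g.part_a] == [1, 2, 2, 1]
        assert all(g.degree_b(x) == 1 for x in g.part_b)

    def test_empty_table(self):
        a, b = parse_pair(">A\n1 2 |\n>B\n7 8 |")
        g = build_gs_graph(a, b, SimilarityTable({}))
        assert not g.edges

    def test_counterexample_k1_edges(self):
        _a, _b, table = counterexample_instance(GadgetParams(k=1, epsilon=0.25))
        weights = sorted(table.entries.values())
        assert weights == [0.75, 1.0, 1.0]


class TestMaximality:
    def test_empty_on_empty_graph(self):
        a, b = parse_pair(">A\n1 |\n>B\n7 |")
        g = build_gs_graph(a, b, SimilarityTable({}))
        assert is_maximal_matching(g, Matching(()))

    def test_empty_on_fig4_graph(self, fig4):
        g = build_gs_graph(fig4.genome_a, fig4.genome_b, fig4.similarities)
        assert not is_maximal_matching(g, Matching(()))

    def test_all_light_edges_matching_is_maximal(self):
        params = GadgetParams(k=2, epsilon=0.1)
        a, b, table = counterexample_instance(params)
        _m, m_star = counterexample_matchings(params, table)
        g = build_gs_graph(a, b, table)
        assert is_maximal_matching(g, m_star)

    def test_non_matching_rejected(self):
        with pytest.raises(GenomeFormatError):
            Matching((("a", "x", 1.0), ("a", "y", 1.0)))


class TestReducedGenomes:
    def test_fig4_matching(self, fig4):
        m = Matching.from_pairs(
            [("1", "7"), ("2", "8"), ("3", "10"), ("4", "6")], table=fig4.similarities
        )
        r = reduce_genomes(fig4.genome_a, fig4.genome_b, m)
        assert r.genome_a.gene_set == r.genome_b.gene_set == {"1", "2", "3", "4"}
        # A is fully saturated; B drops its genes 5 and 9
        assert r.genome_a.n_genes == 4
        assert r.genome_b.n_genes == 4
        assert "5" not in r.labels and "9" not in r.labels
        # orientation preserved: gene 3 of A_F is reversed
        signs_a = [g.forward for g in r.genome_a.genes()]
        assert signs_a == [True, True, False, True]

    def test_empty_matching(self, fig4):
        r = reduce_genomes(fig4.genome_a, fig4.genome_b, Matching(()))
        assert r.genome_a.n_genes == 0 and r.genome_b.n_genes == 0

    def test_single_edge(self):
        a, b = parse_pair(">A\n1 2 3 4 5 |\n>B\n6 -7 -8 -9 10 11 |")
        m = Matching((("1", "6", 0.5),))
        r = reduce_genomes(a, b, m)
        assert r.genome_a.n_genes == r.genome_b.n_genes == 1
        assert r.genome_a.gene_set == {"1"}

    def test_fully_unsaturated_circular_chromosome_removed(self):
        a, b = parse_pair(">A\n1 |\n2 )\n>B\n7 |")
        r = reduce_genomes(a, b, Matching((("1", "7", 1.0),)))
        assert len(r.genome_a.chromosomes) == 1


class TestWeightedAdjacencyGraph:
    def test_total_weight_is_twice_matching_weight(self, rng):
        for _ in range(50):
            a, b, table = random_instance(rng)
            g = build_gs_graph(a, b, table)
            for m in enumerate_maximal_matchings(g):
                r = reduce_genomes(a, b, m)
                if len(m):
                    ag = build_weighted_adjacency_graph(r)
                    assert ag.total_weight == pytest.approx(2 * m.weight)
                break  # one matching per instance suffices

    def test_unit_weights(self, fig4):
        m = Matching.from_pairs(
            [("1", "7"), ("2", "8"), ("3", "10"), ("4", "6")], table=fig4.similarities
        )
        ag = build_weighted_adjacency_graph(reduce_genomes(fig4.genome_a, fig4.genome_b, m))
        weights = [d["weight"] for _, _, d in ag.graph.edges(data=True)]
        assert weights == [1.0] * 8


@pytest.mark.parametrize(
    "kind,length,weight,expect",
    [
        (CYCLE, 2, 2.0, 0.0),  # all weights 1: family-based case
        (ODD_PATH, 1, 0.5, 0.25),
        (CYCLE, 2, 1.0, 0.5),
        (EVEN_PATH, 2, 1.0, 1.5),
    ],
)
def test_weighted_component_contribution(kind, length, weight, expect):
    assert weighted_component_contribution(Component(kind, length, weight)) == pytest.approx(expect)


class TestDsigma:
    def test_census_form_matches_worked_values(self):
        fx = load_fixture("fig2")
        m1, m2 = fx.matching_summaries["M1"], fx.matching_summaries["M2"]
        assert dsigma_from_counts(m1.size, m1.weight, m1.cycles, m1.odd_paths) == pytest.approx(3.3, abs=1e-9)
        assert dsigma_from_counts(m2.size, m2.weight, m2.cycles, m2.odd_paths) == pytest.approx(3.1, abs=1e-9)

    def test_empty_matching_gives_zero(self, fig4):
        assert dsigma(reduce_genomes(fig4.genome_a, fig4.genome_b, Matching(()))) == 0.0

    def test_route_agreement_and_nonnegativity(self, rng):
        """Component-sum route equals d_DCJ + |M| - w(M) (asserted inside
        dsigma) and is non-negative, on random instances and matchings."""
        checked = 0
        for _ in range(100):
            a, b, table = random_instance(rng)
            g = build_gs_graph(a, b, table)
            for m in enumerate_maximal_matchings(g):
                value = dsigma(reduce_genomes(a, b, m))
                assert value >= -1e-9
                checked += 1
                break
        assert checked == 100

    def test_unit_weights_reduce_to_family_based(self, fig4):
        m = Matching.from_pairs(
            [("1", "7"), ("2", "8"), ("3", "10"), ("4", "6")], table=fig4.similarities
        )
        r = reduce_genomes(fig4.genome_a, fig4.genome_b, m)
        assert dsigma(r) == pytest.approx(dcj_distance(r.genome_a, r.genome_b))

    def test_weight_decrease_increases_distance_linearly(self):
        """Lowering one matched edge's sigma by delta raises d_sigma by
        exactly delta."""
        a, b = parse_pair(">A\n1 2 |\n>B\n7 8 |")
        delta = 0.3
        for sigma in (1.0, 0.9):
            table = SimilarityTable({("1", "7"): sigma, ("2", "8"): 0.8})
            m = Matching.from_pairs([("1", "7"), ("2", "8")], table=table)
            if sigma == 1.0:
                base = dsigma(reduce_genomes(a, b, m))
        table2 = SimilarityTable({("1", "7"): 1.0 - delta, ("2", "8"): 0.8})
        m2 = Matching.from_pairs([("1", "7"), ("2", "8")], table=table2)
        assert dsigma(reduce_genomes(a, b, m2)) == pytest.approx(base + delta)


class TestSsigma:
    def test_single_circular_gene_pair(self):
        a, b = parse_pair(">A\n1 )\n>B\n7 )")
        m = Matching((("1", "7", 1.0),))
        assert ssigma(reduce_genomes(a, b, m)) == pytest.approx(1.0)

    def test_single_linear_gene_pair(self):
        a, b = parse_pair(">A\n1 |\n>B\n7 |")
        m = Matching((("1", "7", 1.0),))
        # two odd paths of length 1 and weight 1: 1/2 + 1/2
        assert ssigma(reduce_genomes(a, b, m)) == pytest.approx(1.0)

    def test_all_unit_circular_equals_cycle_count(self, rng):
        """With unit weights and circular genomes, s_sigma counts cycles,
        i.e. equals |M| - d_DCJ of the reduced genomes."""
        from ffdcj import exemplar_to_ff_instance, random_exemplar_instance

        for _ in range(20):
            src_a, src_b = random_exemplar_instance(rng, max_families=5, topology="circular")
            a, b, table = exemplar_to_ff_instance(src_a, src_b)
            g = build_gs_graph(a, b, table)
            for m in enumerate_maximal_matchings(g):
                r = reduce_genomes(a, b, m)
                expect = len(m) - dcj_distance(r.genome_a, r.genome_b)
                assert ssigma(r) == pytest.approx(expect)
                break


class TestFAlpha:
    def test_endpoints_and_midpoint(self):
        a, b = parse_pair(">A\n1 )\n>B\n7 )")
        r = reduce_genomes(a, b, Matching((("1", "7", 1.0),)))
        assert f_alpha(r, 0.0) == pytest.approx(r.matching.weight)
        assert f_alpha(r, 1.0) == pytest.approx(ssigma(r))
        assert f_alpha(r, 0.5) == pytest.approx(1.0)  # s_sigma = w(M) = 1 here

    @pytest.mark.parametrize("alpha", [-0.1, 1.1])
    def test_alpha_out_of_range(self, alpha):
        a, b = parse_pair(">A\n1 )\n>B\n7 )")
        r = reduce_genomes(a, b, Matching((("1", "7", 1.0),)))
        with pytest.raises(ValueError):
            f_alpha(r, alpha)
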