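"""Simulator, hardness gadgets and worked-example fixtures."""

import numpy as np
import pytest

from ffdcj import (
    GadgetParams,
    Matching,
    SimulationConfig,
    counterexample_instance,
    counterexample_matchings,
    dcj_distance,
    dsigma,
    exemplar_dcj_bruteforce,
    exemplar_to_ff_instance,
    ff_matching_to_exemplar,
    ffdcj_distance_bruteforce,
    load_fixture,
    parse_pair,
    preset,
    random_exemplar_instance,
    reduce_genomes,
    simulate_pair,
    write_genomes,
)
from ffdcj.genomes import GenomeFormatError


class TestCounterexample:
    def test_structure_k3(self):
        a, b, table = counterexample_instance(GadgetParams(k=3, epsilon=0.1))
        assert a.n_genes == b.n_genes == 6
        assert len(table) == 9  # 2k unit edges + k light edges
        # alternating orientation, A starts forward, B starts reversed
        assert [g.forward for g in a.genes()] == [True, False] * 3
        assert [g.forward for g in b.genes()] == [False, True] * 3

    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("eps", [0.5, 0.1, 0.01])
    def test_heavy_vs_light_matchings(self, k, eps):
        """The all-weight-1 matching has d_sigma = |M|; the all-(1-eps)
        matching has d_sigma = eps|M*|; their ratio is 2/eps, so the
        maximum-weight matching approximates arbitrarily badly."""
        params = GadgetParams(k=k, epsilon=eps)
        a, b, table = counterexample_instance(params)
        m, m_star = counterexample_matchings(params, table)
        assert len(m) == 2 * len(m_star)
        d_m = dsigma(reduce_genomes(a, b, m))
        d_star = dsigma(reduce_genomes(a, b, m_star))
        assert d_m == pytest.approx(len(m), abs=1e-9)
        assert d_star == pytest.approx(eps * len(m_star), abs=1e-9)
        assert d_m / d_star == pytest.approx(2 / eps, rel=1e-9)


class TestExemplarGadget:
    def test_fig4_transform(self):
        src_a, src_b = parse_pair(">A\na c -b d |\n>B\n-c d a c b -b |", allow_duplicates=True)
        ff_a, ff_b, table = exemplar_to_ff_instance(src_a, src_b)
        assert ff_a.gene_set == {"1", "2", "3", "4"}
        assert ff_b.gene_set == {"5", "6", "7", "8", "9", "10"}
        assert all(s == 1.0 for s in table.entries.values())
        assert len(table) == 6

    def test_identity_instance(self):
        a, b = parse_pair(">A\n1 2 3 |\n>B\n1 2 3 |")
        ff_a, ff_b, table = exemplar_to_ff_instance(a, b)
        value, _ = ffdcj_distance_bruteforce(ff_a, ff_b, table)
        assert value == 0.0

    def test_single_family_two_copies(self):
        a, b = parse_pair(">A\nf |\n>B\nf f |", allow_duplicates=True)
        _fa, _fb, table = exemplar_to_ff_instance(a, b)
        assert len(table) == 2

    def test_duplicated_a_rejected(self):
        a, b = parse_pair(">A\nf f |\n>B\nf |", allow_duplicates=True)
        with pytest.raises(GenomeFormatError):
            exemplar_to_ff_instance(a, b)

    def test_matching_back_projection(self):
        src_a, src_b = parse_pair(">A\na c -b d |\n>B\n-c d a c b -b |", allow_duplicates=True)
        ff_a, ff_b, table = exemplar_to_ff_instance(src_a, src_b)
        m = Matching.from_pairs([("1", "7"), ("2", "8"), ("3", "10"), ("4", "6")], table=table)
        ax, bx = ff_matching_to_exemplar(m, src_a, src_b)
        assert write_genomes([ax]).splitlines()[1] == "a c -b d |"
        assert write_genomes([bx]).splitlines()[1] == "d a c -b |"
        # the exemplar distance equals d_sigma of the matching
        assert dcj_distance(ax, bx) == pytest.approx(dsigma(reduce_genomes(ff_a, ff_b, m)))

    def test_empty_matching_gives_empty_genomes(self):
        src_a, src_b = parse_pair(">A\na |\n>B\na |")
        ax, bx = ff_matching_to_exemplar(Matching(()), src_a, src_b)
        assert not ax.chromosomes and not bx.chromosomes

    def test_transform_optima_agree(self, rng):
        """Brute-force exemplar optimum equals brute-force family-free
        optimum on the transformed instance (small random (1,2)-instances)."""
        for _ in range(15):
            src_a, src_b = random_exemplar_instance(rng, max_families=5)
            ex, _ax, _bx = exemplar_dcj_bruteforce(src_a, src_b)
            ff_a, ff_b, table = exemplar_to_ff_instance(src_a, src_b)
            ff, _m = ffdcj_distance_bruteforce(ff_a, ff_b, table)
            assert ff == pytest.approx(ex)


class TestSimulator:
    def test_determinism(self):
        cfg = preset(2, n_genes=40, seed=11)
        out1 = simulate_pair(cfg)
        out2 = simulate_pair(cfg)
        assert write_genomes(out1[:2]) == write_genomes(out2[:2])
        assert out1[2].entries == out2[2].entries
        assert out1[3] == out2[3]

    def test_zero_events_is_identity(self):
        cfg = SimulationConfig(
            n_genes=8, n_rearrangements=0, dup_rate=0, loss_rate=0,
            weight_noise=0, spurious_edge_rate=0, seed=3,
        )
        a, b, table, truth = simulate_pair(cfg)
        assert len(truth) == 8
        assert dsigma(reduce_genomes(a, b, truth)) == 0.0

    def test_truth_recovery_without_duplications(self):
        """With no duplications/losses and mild similarity noise, the
        optimal matching recovers the ground-truth orthology in at least
        90% of replicates."""
        recovered = 0
        for seed in range(50):
            cfg = SimulationConfig(
                n_genes=6, n_rearrangements=1, dup_rate=0, loss_rate=0,
                weight_noise=0.1, seed=seed,
            )
            a, b, table, truth = simulate_pair(cfg)
            _d, m = ffdcj_distance_bruteforce(a, b, table)
            recovered += m.pairs() == truth.pairs()
        assert recovered >= 45

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dup_rate=-1)
        with pytest.raises(ValueError):
            SimulationConfig(weight_noise=1.0)
        with pytest.raises(ValueError):
            preset(3)

    def test_events_leave_valid_instance(self):
        cfg = preset(5, n_genes=60, seed=21)
        a, b, table, truth = simulate_pair(cfg)
        assert not a.has_duplicates() and not b.has_duplicates()
        assert a.gene_set.isdisjoint(b.gene_set)
        assert all(0 < s <= 1 for s in table.entries.values())
        # truth is a matching over surviving genes
        assert truth.saturated_a <= a.gene_set
        assert truth.saturated_b <= b.gene_set


class TestFixtures:
    def test_fig1(self):
        fx = load_fixture("fig1")
        assert write_genomes([fx.genome_a]).splitlines()[1] == "-1 3 4 2 |"
        assert write_genomes([fx.genome_b]).splitlines()[1] == "-2 1 4 3 |"

    def test_fig2_aggregates(self):
        fx = load_fixture("fig2")
        assert fx.matching_summaries["M1"].weight == 2.7
        assert fx.matching_summaries["M2"].weight == 3.9

    def test_fig4_unit_weights(self):
        fx = load_fixture("fig4")
        assert all(s == 1.0 for s in fx.similarities.entries.values())

    def test_fig5(self):
        fx = load_fixture("fig5_k3")
        assert fx.genome_a.n_genes == 6 and len(fx.similarities) == 9

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            load_fixture("fig9")
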