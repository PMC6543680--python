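"""The coalescent-with-hybridization simulator against closed forms."""

import numpy as np
import pytest

from hils.patterns import cumulative_frequencies
from hils.simnet import (
    ClockTree,
    SimulationConfig,
    SpeciesNetwork,
    benchmark_gtr,
    example_network,
    four_taxon_network,
    general_network,
    jc69,
    parse_extended_newick,
    sample_parental_tree,
    simulate_dataset,
    simulate_gene_trees,
    simulate_site_matrix,
    stretch_tip,
)
from hils.simnet import _quartet_counts_from_matrix


class TestClockTree:
    def test_from_joins_structure(self):
        t = ClockTree.from_joins(("a", "b", "c"), [(1.0, "a", "b"), (2.0, "a", "c")])
        assert t.n_tips == 3
        assert t.node_time == (0.0, 0.0, 0.0, 1.0, 2.0)
        assert t.pendant_length("c") == 2.0
        assert t.mrca(["a", "b"]) == 3

    def test_newick_roundtrip(self):
        t = ClockTree.from_joins(("a", "b", "c", "d"),
                                 [(0.5, "a", "b"), (1.0, "c", "d"), (2.0, "a", "c")])
        back = ClockTree.from_newick(t.to_newick())
        assert sorted(back.taxa) == sorted(t.taxa)
        assert back.node_time[back.mrca(["a", "b"])] == pytest.approx(0.5)
        assert back.node_time[back.mrca(["a", "d"])] == pytest.approx(2.0)

    def test_non_ultrametric_newick_rejected(self):
        with pytest.raises(ValueError):
            ClockTree.from_newick("((a:1,b:2):1,c:2);")

    def test_attach_inserts_on_donor_edge(self):
        base = ClockTree.from_joins(("a", "b", "c"),
                                    [(1.0, "a", "b"), (2.0, "a", "c")])
        grown = base.attach("h", "a", 0.5)
        assert grown.node_time[grown.mrca(["a", "h"])] == pytest.approx(0.5)
        assert grown.node_time[grown.mrca(["a", "b"])] == pytest.approx(1.0)

    def test_attach_outside_edge_span_rejected(self):
        base = ClockTree.from_joins(("a", "b", "c"),
                                    [(1.0, "a", "b"), (2.0, "a", "c")])
        with pytest.raises(ValueError):
            base.attach("h", "a", 1.5)  # pendant edge of a ends at 1.0


class TestNetworks:
    def test_four_taxon_parental_trees(self):
        net = four_taxon_network(0.25, 0.5, 1.0, 0.3)
        q = net.quartet_assignment()
        assert q.taxa == ("O", "P1", "H", "P2")
        assert net.s1.node_time[net.s1.mrca(["H", "P2"])] == pytest.approx(0.25)
        assert net.s2.node_time[net.s2.mrca(["H", "P1"])] == pytest.approx(0.25)
        assert net.s1.node_time[net.s1.mrca(["H", "O"])] == pytest.approx(1.0)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            four_taxon_network(0.5, 0.5, 1.0, 0.1)

    def test_stretch_tip_adds_pendant_length(self):
        net = four_taxon_network(0.25, 0.5, 1.0, 0.1)
        doubled = stretch_tip(net, "P1", 2.0)
        # P1 pendant spans tau2 in S1 and tau1 in S2
        i1 = doubled.s1.taxa.index("P1")
        i2 = doubled.s2.taxa.index("P1")
        assert doubled.s1.tip_extra[i1] == pytest.approx(0.5)
        assert doubled.s2.tip_extra[i2] == pytest.approx(0.25)

    def test_stretch_identity(self):
        net = four_taxon_network(0.25, 0.5, 1.0, 0.1)
        same = stretch_tip(net, "H", 1.0)
        assert all(x == 0 for x in same.s1.tip_extra)

    def test_general_network_deep_event(self):
        net = example_network(9, "deep", 0.2)
        assert len(net.taxa) == 9
        assert net.hybrid_taxa == {"h1", "h2"}
        crown = net.s1.node_time[net.s1.mrca(["h1", "h2"])]
        assert crown == pytest.approx(0.5)

    @pytest.mark.parametrize("n,event", [(9, "shallow"), (9, "deep"),
                                         (20, "shallow"), (20, "deep")])
    def test_example_networks_well_formed(self, n, event):
        net = example_network(n, event, 0.3)
        assert len(net.taxa) == n
        assert net.outgroup == "O"
        assert set(net.s1.taxa) == set(net.s2.taxa)
        assert net.hybrid_taxa and net.parent1_taxa and net.parent2_taxa

    def test_incompatible_attach_time_rejected(self):
        base = ClockTree.from_joins(("O", "a", "b"),
                                    [(1.0, "a", "b"), (2.0, "a", "O")])
        with pytest.raises(ValueError):
            general_network(base, "h", "a", "b", 1.5, 0.1, "O")


class TestParentalSampling:
    def test_degenerate_mixtures(self, rng):
        net0 = four_taxon_network(0.5, 1.0, 2.0, 0.0)
        net1 = four_taxon_network(0.5, 1.0, 2.0, 1.0)
        assert not sample_parental_tree(net0, rng, 1000).any()
        assert sample_parental_tree(net1, rng, 1000).all()

    def test_fraction_converges_to_gamma(self, rng):
        net = four_taxon_network(0.5, 1.0, 2.0, 0.3)
        draws = sample_parental_tree(net, rng, 100_000)
        se = np.sqrt(0.3 * 0.7 / 100_000)
        assert draws.mean() == pytest.approx(0.3, abs=4 * se)


class TestGeneTrees:
    def test_pairwise_coalescent_mean(self, rng):
        """Mean tip-to-tip distance on a two-taxon tree is 2(tau + 1)."""
        tree = ClockTree.from_joins(("a", "b"), [(1.0, "a", "b")])
        _, heights = simulate_gene_trees(tree, 20_000, rng)
        root = heights[:, -1]
        # root height = tau + Exp(1); tip-to-tip distance doubles it
        assert root.mean() == pytest.approx(2.0, abs=4 / np.sqrt(20_000))
        assert 2 * root.mean() == pytest.approx(2 * (1.0 + 1.0), rel=0.03)

    def test_rooted_triple_discordance(self, rng):
        """P(gene tree disagrees with ((a,b),c)) = (2/3) exp(-T)."""
        T = 0.5
        tree = ClockTree.from_joins(("a", "b", "c"),
                                    [(1.0, "a", "b"), (1.0 + T, "a", "c")])
        parent, _ = simulate_gene_trees(tree, 50_000, rng)
        # node 3 is the first coalescence; the cherry is the pair whose
        # parent is node 3
        cherry_ab = (parent[:, 0] == 3) & (parent[:, 1] == 3)
        expected = (2.0 / 3.0) * np.exp(-T)
        se = np.sqrt(expected * (1 - expected) / 50_000)
        assert (~cherry_ab).mean() == pytest.approx(expected, abs=4 * se)

    def test_long_internal_branch_forces_concordance(self, rng):
        tree = ClockTree.from_joins(("a", "b", "c"),
                                    [(0.1, "a", "b"), (30.0, "a", "c")])
        parent, _ = simulate_gene_trees(tree, 2000, rng)
        assert ((parent[:, 0] == 3) & (parent[:, 1] == 3)).all()

    def test_single_gene_tree_newick_export(self, rng):
        import dendropy

        from hils.simnet import simulate_gene_tree_newick

        tree = ClockTree.from_joins(("a", "b", "c", "d"),
                                    [(0.5, "a", "b"), (1.0, "c", "d"),
                                     (2.0, "a", "c")])
        nwk = simulate_gene_tree_newick(tree, rng)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == \
            ["a", "b", "c", "d"]

    def test_heights_are_consistent(self, rng):
        net = four_taxon_network(0.5, 1.0, 2.0, 0.0)
        parent, heights = simulate_gene_trees(net.s2, 500, rng)
        n = 4
        assert (heights[:, :n] == 0).all()
        for v in range(2 * n - 2):
            rows = np.arange(500)
            assert (heights[rows, parent[:, v]] >= heights[:, v]).all()


class TestSubstitution:
    def test_jc69_transition_closed_form(self):
        model = jc69()
        for t in (0.01, 0.3, 2.0):
            p = model.transition_matrix(t)
            p_change = 0.75 * (1 - np.exp(-4 * t / 3))
            assert p[0, 1] == pytest.approx(p_change / 3, rel=1e-10)
            assert p[0, 0] == pytest.approx(1 - p_change, rel=1e-10)

    def test_gtr_rows_sum_to_one_and_stationarity(self):
        model = benchmark_gtr()
        p = model.transition_matrix(0.7)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        pi = np.asarray(model.base_freqs)
        np.testing.assert_allclose(pi @ p, pi, atol=1e-12)

    def test_mean_rate_normalization(self):
        model = benchmark_gtr()
        pi = np.asarray(model.base_freqs)
        assert -float(pi @ np.diag(model.rate_matrix)) == pytest.approx(1.0)

    def test_site_rate_mixture_with_invariable_fraction(self, rng):
        """Variable-site gamma rates have mean 1; invariable sites rate 0."""
        model = benchmark_gtr()
        rates, probs = model.rate_categories
        assert rates[0] == 0.0 and probs[0] == pytest.approx(0.2)
        assert float(rates[1:] @ probs[1:]) == pytest.approx(1.0 - 0.2)
        assert np.mean(rates[1:]) == pytest.approx(1.0)  # equal-weight categories
        draws = model.draw_site_rates(200_000, rng)
        assert (draws == 0).mean() == pytest.approx(0.2, abs=0.005)
        assert draws.mean() == pytest.approx(0.8, abs=0.01)

    def test_two_taxon_mismatch_probability(self, rng):
        """JC69 mismatch for a coalescent pair has a closed form.

        With divergence tau and coalescent tail S ~ Exp(1), the
        tip-to-tip distance is d = 2(tau + S) and
        P(mismatch) = 3/4 (1 - exp(-8 tau/3) E[exp(-8S/3)])
                    = 3/4 (1 - exp(-8 tau/3) / (1 + 8/3)).
        """
        tau = 0.5
        tree = ClockTree.from_joins(("a", "b"), [(tau, "a", "b")])
        net = SpeciesNetwork(tree, tree, 0.0, hybrid="a", outgroup="b")
        mat = simulate_site_matrix(net, jc69(), SimulationConfig(n_sites=100_000),
                                   rng)
        mismatch = (mat[0] != mat[1]).mean()
        expected = 0.75 * (1 - np.exp(-8 * tau / 3) / (1 + 8 / 3))
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert mismatch == pytest.approx(expected, abs=4 * se)

    def test_tip_base_frequencies_match_stationary(self, rng):
        net = four_taxon_network(0.5, 1.0, 2.0, 0.0)
        mat = simulate_site_matrix(net, benchmark_gtr(),
                                   SimulationConfig(n_sites=100_000), rng)
        freqs = np.bincount(mat.ravel(), minlength=4) / mat.size
        np.testing.assert_allclose(freqs, (0.15, 0.35, 0.15, 0.35), atol=0.01)


class TestDatasets:
    def test_multilocus_total_length(self, rng):
        net = four_taxon_network(0.5, 1.0, 2.0, 0.2)
        cfg = SimulationConfig(mode="multilocus", n_loci=20, locus_length=50)
        aln = simulate_dataset(net, jc69(), cfg, rng)
        assert aln.length == 1000
        assert aln.n_taxa == 4

    def test_seeded_determinism(self):
        net = four_taxon_network(0.5, 1.0, 2.0, 0.3)
        cfg = SimulationConfig(n_sites=2000)
        a = simulate_dataset(net, benchmark_gtr(), cfg, 99)
        b = simulate_dataset(net, benchmark_gtr(), cfg, 99)
        c = simulate_dataset(net, benchmark_gtr(), cfg, 100)
        assert a.sequences == b.sequences
        assert a.sequences != c.sequences

    def test_fixed_allocation_uses_rounded_counts(self):
        """gamma=0 and gamma=1 use exactly one parental tree."""
        net1 = four_taxon_network(0.5, 1.0, 2.0, 1.0)
        mat = simulate_site_matrix(net1, jc69(), SimulationConfig(n_sites=100), 1)
        assert mat.shape == (4, 100)

    def test_mixture_consistency(self):
        """Pattern frequencies at gamma interpolate the two endpoints."""
        model = benchmark_gtr()
        cfg = SimulationConfig(n_sites=200_000)
        freqs = {}
        for gamma in (0.0, 0.3, 1.0):
            net = four_taxon_network(0.5, 1.0, 2.0, gamma)
            mat = simulate_site_matrix(net, model, cfg, 12345)
            counts = _quartet_counts_from_matrix(mat, net.taxa,
                                                 net.quartet_assignment())
            freqs[gamma] = cumulative_frequencies(counts)
        for name in ("p_iijj", "p_ijij", "p_ijji"):
            blend = 0.3 * getattr(freqs[1.0], name) + 0.7 * getattr(freqs[0.0], name)
            se = np.sqrt(getattr(freqs[0.3], name) / 200_000)
            assert getattr(freqs[0.3], name) == pytest.approx(blend, abs=5 * se)


class TestExtendedNewick:
    NET = ("(((P1:0.5,(H:0.5)#H1:0::0.7):0.5,(P2:0.5,#H1:0::0.3):0.5):1.0,"
           "O:2.0);")

    def test_parses_one_reticulation(self):
        net = parse_extended_newick(self.NET)
        assert sorted(net.taxa) == ["H", "O", "P1", "P2"]
        assert net.hybrid == "H"
        assert net.gamma == pytest.approx(0.7)
        assert net.outgroup == "O"
        # first #H occurrence keeps H with P1; the reference tree joins H to P2
        assert net.s1.node_time[net.s1.mrca(["P1", "H"])] == pytest.approx(0.5)
        assert net.s2.node_time[net.s2.mrca(["P2", "H"])] == pytest.approx(0.5)
        assert net.s1.node_time[net.s1.mrca(["P1", "P2"])] == pytest.approx(1.0)

    def test_gamma_from_second_edge_when_first_unannotated(self):
        text = self.NET.replace(":0::0.7", ":0")
        net = parse_extended_newick(text)
        assert net.gamma == pytest.approx(1 - 0.3)

    def test_missing_gamma_rejected(self):
        text = self.NET.replace("::0.7", "").replace("::0.3", "")
        with pytest.raises(ValueError):
            parse_extended_newick(text)

    def test_simulation_from_parsed_network(self):
        net = parse_extended_newick(self.NET)
        aln = simulate_dataset(net, jc69(), SimulationConfig(n_sites=500), 3)
        assert aln.length == 500
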