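"""Synthetic generators and the packaged study fixture."""

import numpy as np
import pytest

from cophylotrack import (CophyloSimConfig, EventCosts, build_tanglegram,
                          clade_rank, study_fixture, random_binary_tree,
                          simulate_claderank_table, simulate_cophylogeny,
                          simulate_host_tree, solve, write_newick)


class TestYuleHostTree:
    def test_shape_and_ultrametricity(self):
        t = simulate_host_tree(8, 1)
        assert t.n_tips == 8
        assert len(t.internal_nodes()) == 7
        heights = {round(t.root_to_tip_length(lab), 9) for lab in t.tip_labels()}
        assert len(heights) == 1

    def test_bit_reproducible(self):
        a = write_newick(simulate_host_tree(8, 5), canonical=True)
        b = write_newick(simulate_host_tree(8, 5), canonical=True)
        assert a == b

    def test_mean_height_matches_yule_expectation(self):
        """E[height] for n tips is sum_{k=2..n} 1/k."""
        n_rep = 1000
        heights = [simulate_host_tree(10, s).root_to_tip_length("h1")
                   for s in range(n_rep)]
        expected = sum(1 / k for k in range(2, 11))
        # var of height = sum 1/k^2; SE of the mean accordingly
        se = np.sqrt(sum(1 / k ** 2 for k in range(2, 11)) / n_rep)
        assert abs(np.mean(heights) - expected) < 3 * se

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_host_tree(1, 0)


class TestCophylogenySimulator:
    def test_pure_codivergence(self):
        host = simulate_host_tree(12, 3)
        cfg = CophyloSimConfig(seed=4, p_cospeciation=1.0, switch_rate=0.0,
                               duplication_rate=0.0, p_ftd_cherry=0.0)
        tg, hist = simulate_cophylogeny(host, cfg)
        assert hist.counts.cospeciations == 11
        assert hist.counts.duplications == hist.counts.switches == 0
        assert hist.counts.losses == hist.counts.ftd == 0
        rec = solve(tg, EventCosts(0, 1, 1, 1, 1))
        assert rec.total_cost == 0
        assert rec.counts.cospeciations == 11

    @pytest.mark.parametrize("seed", range(10))
    def test_event_identity(self, seed):
        """cosp + dup + switch equals internal symbiont node count."""
        host = simulate_host_tree(10, seed)
        cfg = CophyloSimConfig(seed=seed + 50, p_cospeciation=0.6,
                               switch_rate=0.8, duplication_rate=0.3,
                               p_ftd_cherry=0.2)
        tg, hist = simulate_cophylogeny(host, cfg)
        c = hist.counts
        assert c.cospeciations + c.duplications + c.switches == \
            len(tg.symbiont.internal_nodes())

    def test_reproducible(self):
        host = simulate_host_tree(10, 9)
        a, _ = simulate_cophylogeny(host, CophyloSimConfig(seed=10))
        b, _ = simulate_cophylogeny(host, CophyloSimConfig(seed=10))
        assert write_newick(a.symbiont, canonical=True) == \
            write_newick(b.symbiont, canonical=True)
        assert a.assoc == b.assoc

    def test_widespread_tips_recorded_as_ftd(self):
        host = simulate_host_tree(10, 13)
        cfg = CophyloSimConfig(seed=14, p_cospeciation=0.0, switch_rate=0.0,
                               duplication_rate=0.0, p_ftd_cherry=1.0)
        tg, hist = simulate_cophylogeny(host, cfg)
        wide = [t for t, hosts in tg.assoc.items() if len(hosts) == 2]
        assert len(wide) == hist.counts.ftd
        # the single non-cospeciating lineage either dies onto a tip or
        # spans one cherry; every host speciation it met is accounted for
        assert hist.counts.ftd <= 1
        assert tg.n_symbiont_tips == 1

    def test_lengths_required(self):
        host = random_binary_tree(["a", "b", "c"], 1)
        with pytest.raises(ValueError):
            simulate_cophylogeny(host, CophyloSimConfig(seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CophyloSimConfig(p_cospeciation=1.5)
        with pytest.raises(ValueError):
            CophyloSimConfig(switch_rate=-0.1)
        with pytest.raises(ValueError):
            CophyloSimConfig(n_host_tips=2)


class TestCladeRankTable:
    def test_poisson_law_under_degenerate_config(self):
        """beta1 = 0, no random effects: y ~ Poisson(exp(beta0))."""
        host = simulate_host_tree(10, 40)
        recs = simulate_claderank_table(host, 1.0, 0.0, 0, 0, 0,
                                        n_per_host=100, seed=41)
        ys = np.array([r.symbiont_clade_rank for r in recs])
        mu = np.exp(1.0)
        assert abs(ys.mean() - mu) < 3 * np.sqrt(mu / len(ys))

    def test_reproducible(self):
        host = simulate_host_tree(8, 42)
        a = simulate_claderank_table(host, 1, 0.3, 0.2, 0.1, 0.1, 5, seed=43)
        b = simulate_claderank_table(host, 1, 0.3, 0.2, 0.1, 0.1, 5, seed=43)
        assert a == b

    def test_structure(self):
        host = simulate_host_tree(8, 44)
        recs = simulate_claderank_table(host, 1, 0.3, 0.2, 0.1, 0.1, 3, seed=45)
        tips = set(host.tip_labels())
        assert len(recs) == 24
        for r in recs:
            assert r.symbiont_clade_rank >= 0
            assert r.host in tips
            assert r.host_clade_rank == clade_rank(host, r.host)
            assert r.genus

    def test_negative_variance_rejected(self):
        host = simulate_host_tree(8, 46)
        with pytest.raises(ValueError):
            simulate_claderank_table(host, 1, 0, -1, 0, 0, 3, seed=0)


class TestPaperFixture:
    def test_host_tree_shape(self):
        host, _ = study_fixture()
        assert host.n_tips == 15
        assert host.is_binary()
        genera = {lab.split()[0] for lab in host.tip_labels()}
        assert len(genera) == 10

    def test_viburnum_subtree(self):
        """prunifolium and rufidulum are sisters; lentago joins next."""
        host, _ = study_fixture()
        prun = host.find_tip("Viburnum prunifolium")
        rufi = host.find_tip("Viburnum rufidulum")
        assert prun.parent is rufi.parent
        lent = host.find_tip("Viburnum lentago")
        assert lent.parent is prun.parent.parent

    def test_juglans_sisters_relative_to_carya(self):
        host, _ = study_fixture()
        jn = host.find_tip("Juglans nigra")
        jc = host.find_tip("Juglans cinerea")
        carya = host.find_tip("Carya")
        assert jn.parent is jc.parent
        assert carya.parent is jn.parent.parent

    def test_association_counts(self):
        _, assoc = study_fixture()
        assert len(assoc) == 61
        complex_recs = assoc.filter(lambda r: r.species == "E. binotata")
        assert len(complex_recs) == 44
        assert len(complex_recs.host_taxa()) == 15
        assert len(complex_recs.host_genera()) == 10

    def test_tanglegram_assembly_drops_outgroups(self):
        host, assoc = study_fixture()
        sym = random_binary_tree([r.symbiont_tip for r in assoc], seed=2024)
        tg, dropped = build_tanglegram(host, sym, assoc, drop_unmapped=True)
        assert dropped == 17
        assert tg.n_symbiont_tips == 44


class TestRandomBinaryTree:
    def test_deterministic_and_binary(self):
        labels = [f"t{i}" for i in range(9)]
        a = random_binary_tree(labels, 5)
        b = random_binary_tree(labels, 5)
        assert write_newick(a, canonical=True) == write_newick(b, canonical=True)
        assert a.is_binary()
        assert sorted(a.tip_labels()) == sorted(labels)
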