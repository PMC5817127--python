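"""Reconciliation solver: examples, oracle equivalence, invariants."""

import numpy as np
import pytest

from cophylotrack import (EventCosts, Tanglegram, Tree, TreeNode,
                          brute_force_solve, cost_sweep, enumerate_optima,
                          parse_newick, solve)
from conftest import make_random_tanglegram


class TestSolveExamples:
    def test_congruent_three_tip(self, congruent3, default_costs):
        rec = solve(congruent3, default_costs)
        assert rec.total_cost == 0
        assert (rec.counts.cospeciations, rec.counts.switches) == (2, 0)
        assert rec.counts.duplications == rec.counts.losses == rec.counts.ftd == 0

    def test_one_switch(self, default_costs):
        host = parse_newick("((h1,h2),h3);")
        sym = parse_newick("((p1,p3),p2);")
        assoc = {f"p{i}": frozenset({f"h{i}"}) for i in (1, 2, 3)}
        rec = solve(Tanglegram(host, sym, assoc), default_costs)
        assert rec.total_cost == 1
        assert (rec.counts.cospeciations, rec.counts.switches) == (1, 1)

    def test_duplication_on_shared_host(self, default_costs):
        host = parse_newick("(h1,h2);")
        sym = parse_newick("(a,b);")
        assoc = {"a": frozenset({"h1"}), "b": frozenset({"h1"})}
        rec = solve(Tanglegram(host, sym, assoc), default_costs)
        assert rec.total_cost == 1
        assert rec.counts.duplications == 1

    def test_widespread_tip_failure_to_diverge(self, default_costs):
        host = parse_newick("(h1,h2);")
        sym = Tree(TreeNode("w"))
        rec = solve(Tanglegram(host, sym, {"w": frozenset({"h1", "h2"})}),
                    default_costs)
        assert rec.total_cost == 1
        assert rec.counts.ftd == 1

    def test_widespread_tip_spanning_partial_subtree(self, default_costs):
        # spanning {h1,h3} on (h1,(h2,h3)): one ftd at the root, one loss
        # on the edge leaving the spanning subtree toward h2
        host = parse_newick("(h1,(h2,h3));")
        sym = Tree(TreeNode("w"))
        rec = solve(Tanglegram(host, sym, {"w": frozenset({"h1", "h3"})}),
                    default_costs)
        assert rec.counts.ftd == 1
        assert rec.counts.losses == 1
        assert rec.total_cost == 2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_random_instances_match_brute_force(self, seed):
        """DP optimum equals the exhaustive oracle's, exactly."""
        rng = np.random.default_rng(seed)
        tg = make_random_tanglegram(int(rng.integers(3, 7)),
                                    int(rng.integers(3, 7)), seed + 500)
        costs = EventCosts(*(float(rng.integers(0, 4)) for _ in range(5)))
        assert solve(tg, costs).total_cost == \
            brute_force_solve(tg, costs).total_cost

    def test_guard_rail(self, default_costs):
        tg = make_random_tanglegram(8, 5, 1)
        with pytest.raises(ValueError):
            brute_force_solve(tg, default_costs)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(15))
    def test_event_count_identity(self, seed, default_costs):
        """cospeciations + duplications + switches = internal symbiont nodes."""
        tg = make_random_tanglegram(5, 5, seed)
        rec = solve(tg, default_costs)
        c = rec.counts
        assert c.cospeciations + c.duplications + c.switches == \
            len(tg.symbiont.internal_nodes())

    @pytest.mark.parametrize("n", [5, 20, 50])
    def test_congruence_identity(self, n, default_costs):
        """Identical trees + identity mapping reconcile to pure tracking."""
        labels = [f"x{i}" for i in range(n)]
        from cophylotrack import random_binary_tree
        host = random_binary_tree(labels, 7)
        sym = random_binary_tree(labels, 7)
        assoc = {lab: frozenset({lab}) for lab in labels}
        rec = solve(Tanglegram(host, sym, assoc), default_costs)
        assert rec.total_cost == 0
        assert rec.counts.cospeciations == n - 1
        assert rec.counts.switches == rec.counts.losses == \
            rec.counts.duplications == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_cost_monotonicity(self, seed):
        """Optimal cost is non-decreasing in every cost component."""
        tg = make_random_tanglegram(5, 5, seed + 100)
        base = EventCosts(0, 1, 1, 1, 1)
        c0 = solve(tg, base).total_cost
        for bumped in [EventCosts(1, 1, 1, 1, 1), EventCosts(0, 2, 1, 1, 1),
                       EventCosts(0, 1, 2, 1, 1), EventCosts(0, 1, 1, 2, 1),
                       EventCosts(0, 1, 1, 1, 2)]:
            assert solve(tg, bumped).total_cost >= c0

    @pytest.mark.parametrize("seed", range(10))
    def test_rescore_self_consistency(self, seed, default_costs):
        """Dot product of counts and costs reproduces total_cost exactly."""
        tg = make_random_tanglegram(6, 5, seed + 300)
        rec = solve(tg, default_costs)
        assert rec.rescore() == rec.total_cost

    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError):
            EventCosts(-1, 1, 1, 1, 1)


class TestEnumerateOptima:
    def test_congruent_has_unique_optimum(self, congruent3, default_costs):
        assert len(enumerate_optima(congruent3, default_costs, 100)) == 1

    def test_tied_optima_all_reported(self, default_costs):
        # two-tip symbiont split across incomparable hosts: cospeciation
        # at the root plus one loss, or a switch placed at either tip.
        host = parse_newick("((h1,h2),h3);")
        sym = parse_newick("(p1,p2);")
        tg = Tanglegram(host, sym, {"p1": frozenset({"h1"}),
                                    "p2": frozenset({"h3"})})
        optima = enumerate_optima(tg, default_costs, 100)
        assert all(o.total_cost == 1 for o in optima)
        assert len(optima) == 3
        kinds = sorted(o.events[next(iter(o.events))][0] for o in optima)
        assert kinds == ["cospeciation", "switch", "switch"]

    def test_limit_truncates(self, default_costs):
        host = parse_newick("((h1,h2),h3);")
        sym = parse_newick("(p1,p2);")
        tg = Tanglegram(host, sym, {"p1": frozenset({"h1"}),
                                    "p2": frozenset({"h3"})})
        assert len(enumerate_optima(tg, default_costs, 1)) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_all_optima_share_cost_and_are_deterministic(self, seed,
                                                         default_costs):
        tg = make_random_tanglegram(5, 5, seed + 700)
        a = enumerate_optima(tg, default_costs, 50)
        b = enumerate_optima(tg, default_costs, 50)
        assert len(a) == len(b)
        assert all(x.total_cost == a[0].total_cost for x in a)
        assert [x.events for x in a] == [x.events for x in b]


class TestCostSweep:
    def test_congruent_rows(self, default_costs):
        from cophylotrack import PAPER_SCHEMES, random_binary_tree
        labels = [f"x{i}" for i in range(6)]
        host = random_binary_tree(labels, 3)
        sym = random_binary_tree(labels, 3)
        tg = Tanglegram(host, sym, {lab: frozenset({lab}) for lab in labels})
        df = cost_sweep(tg, PAPER_SCHEMES)
        assert len(df) == 3
        assert (df["cospeciations"] == 5).all()
        assert (df["switches"] == 0).all()

    def test_cost_non_decreasing_across_nested_schemes(self):
        tg = make_random_tanglegram(5, 5, 900)
        schemes = [EventCosts(0, 1, s, 1, 1) for s in (0, 1, 2)]
        df = cost_sweep(tg, schemes)
        assert df["total_cost"].is_monotonic_increasing

    def test_empty_schemes_rejected(self, congruent3):
        with pytest.raises(ValueError):
            cost_sweep(congruent3, [])
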