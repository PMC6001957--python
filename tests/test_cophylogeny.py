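"""Reconciliation DP, brute-force oracle, and the random-tree null."""

import random

import pytest

from conftest import make_random_costs, make_random_problem
from ervpipe.cophylogeny import (CophylogenyProblem, CostScheme,
                                 brute_force_reconcile, minimal_cost,
                                 random_parasite_test, random_topology,
                                 reconcile, summarize_table)
from ervpipe.phylo import parse_newick

COSP_ONLY = CostScheme(-1, 0, 0, 0, 0)
DEFAULT = CostScheme(0, 1, 2, 1, 1)


def congruent_problem(n):
    """Perfectly congruent caterpillars with 1:1 tip associations."""
    def cat(labels):
        s = f"({labels[0]},{labels[1]})"
        for lab in labels[2:]:
            s = f"({s},{lab})"
        return parse_newick(s + ";")

    hosts = [f"H{i}" for i in range(n)]
    viruses = [f"V{i}" for i in range(n)]
    return CophylogenyProblem(cat(hosts), cat(viruses),
                              {f"V{i}": {f"H{i}"} for i in range(n)})


class TestReconcile:
    def test_perfect_two_tip_pair(self):
        res = reconcile(congruent_problem(2), COSP_ONLY)
        assert res.total_cost == -1
        assert res.event_counts["cospeciation"] == (1, 1)
        for ev in ("duplication", "duplication_host_switch", "loss",
                   "failure_to_diverge"):
            assert res.event_counts[ev] == (0, 0)

    def test_three_tip_one_switch(self):
        """Host ((A,B),C) vs virus ((a,c),b): one cospeciation plus one
        duplication & host switch is optimal under the default scheme."""
        problem = CophylogenyProblem(
            parse_newick("((A,B),C);"), parse_newick("((a,c),b);"),
            {"a": {"A"}, "b": {"B"}, "c": {"C"}})
        res = reconcile(problem, DEFAULT)
        assert res.total_cost == 2
        oracle = brute_force_reconcile(problem, DEFAULT)
        assert oracle.total_cost == 2
        assert res.event_counts == oracle.event_counts

    @pytest.mark.parametrize("n", range(2, 9))
    def test_congruence_law(self, n):
        """n-tip congruent pairs: n-1 cospeciations, nothing else, for every
        scheme whose cospeciation cost is the cheapest."""
        problem = congruent_problem(n)
        for scheme in (COSP_ONLY, DEFAULT, CostScheme(0, 1, 1, 2, 0)):
            res = reconcile(problem, scheme)
            assert res.total_cost == (n - 1) * scheme.cospeciation
            assert res.event_counts["cospeciation"] == (n - 1, n - 1)
            for ev in ("duplication", "duplication_host_switch", "loss",
                       "failure_to_diverge"):
                assert res.event_counts[ev] == (0, 0)

    def test_multifurcation_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            CophylogenyProblem(parse_newick("(A,B,C);"),
                               parse_newick("(a,b);"),
                               {"a": {"A"}, "b": {"B"}})

    def test_unmapped_virus_tip_rejected(self):
        with pytest.raises(ValueError, match="no host association"):
            CophylogenyProblem(parse_newick("(A,B);"), parse_newick("(a,b);"),
                               {"a": {"A"}})

    def test_failure_to_diverge_counted_per_extra_host(self):
        problem = CophylogenyProblem(
            parse_newick("(A,B);"), parse_newick("(a,b);"),
            {"a": {"A", "B"}, "b": {"B"}})
        res = reconcile(problem, CostScheme(0, 0, 0, 0, 5))
        assert res.event_counts["failure_to_diverge"] == (1, 1)
        assert res.total_cost == 5

    def test_isomorphism_invariance(self, rng):
        for _ in range(10):
            problem = make_random_problem(rng, 5, 5)
            cost = make_random_costs(rng)
            base = minimal_cost(problem, cost)
            relabeled = CophylogenyProblem(
                problem.host_tree.relabel(lambda x: "X" + x),
                problem.virus_tree.relabel(lambda x: "Y" + x),
                {"Y" + v: {"X" + h for h in hs}
                 for v, hs in problem.associations.items()})
            assert minimal_cost(relabeled, cost) == base

    def test_monotone_in_event_costs(self, rng):
        for _ in range(10):
            problem = make_random_problem(rng, 5, 5)
            cost = make_random_costs(rng)
            base = minimal_cost(problem, cost)
            for ev in ("cospeciation", "duplication",
                       "duplication_host_switch", "loss",
                       "failure_to_diverge"):
                bumped = CostScheme(**{**{n: getattr(cost, n) for n in
                                          ("cospeciation", "duplication",
                                           "duplication_host_switch", "loss",
                                           "failure_to_diverge")},
                                       ev: getattr(cost, ev) + 1})
                assert minimal_cost(problem, bumped) >= base


class TestBruteForceOracle:
    def test_congruent_five_tips(self):
        res = brute_force_reconcile(congruent_problem(5), COSP_ONLY)
        assert res.total_cost == -4

    def test_two_tip_crossed_association(self):
        # crossing the tanglegram lines of a cherry changes nothing: which
        # virus child follows which host child is free under cospeciation
        problem = CophylogenyProblem(
            parse_newick("(A,B);"), parse_newick("(a,b);"),
            {"a": {"B"}, "b": {"A"}})
        res = brute_force_reconcile(problem, DEFAULT)
        assert res.total_cost == reconcile(problem, DEFAULT).total_cost == 0
        assert res.event_counts["cospeciation"] == (1, 1)

    def test_rejects_large_trees(self):
        with pytest.raises(ValueError, match="tips"):
            brute_force_reconcile(congruent_problem(9), DEFAULT)

    def test_dp_matches_enumeration_on_random_instances(self, rng):
        for _ in range(40):
            problem = make_random_problem(rng, rng.randint(3, 7),
                                          rng.randint(3, 7))
            cost = make_random_costs(rng)
            a = reconcile(problem, cost)
            b = brute_force_reconcile(problem, cost)
            assert a.total_cost == pytest.approx(b.total_cost)
            assert a.event_counts == b.event_counts


class TestRandomTopology:
    def test_uniform_over_four_tip_topologies(self):
        """All 15 labeled rooted topologies appear with ~equal frequency."""
        rng = random.Random(99)
        counts = {}
        n = 6000
        for _ in range(n):
            t = random_topology(list("abcd"), rng)
            counts[t.to_newick()] = counts.get(t.to_newick(), 0) + 1
        assert len(counts) == 15
        for c in counts.values():
            assert abs(c / n - 1 / 15) < 0.02

    def test_tip_set_preserved(self, rng):
        t = random_topology([f"x{i}" for i in range(12)], rng)
        assert sorted(t.tip_labels()) == sorted(f"x{i}" for i in range(12))
        assert t.is_binary()


class TestRandomParasiteTest:
    def test_p_zero_when_congruent(self):
        problem = congruent_problem(8)
        res = random_parasite_test(problem, COSP_ONLY, n=200, seed=5)
        assert res.observed_cost == -7
        assert res.p == 0.0
        assert res.n_better_or_equal == 0

    def test_p_equals_ratio(self):
        problem = congruent_problem(4)
        res = random_parasite_test(problem, DEFAULT, n=250, seed=5)
        assert res.p == res.n_better_or_equal / res.n_random

    def test_matches_exact_null_at_four_tips(self):
        """The empirical p converges on the exactly enumerable null: at 4
        tips there are only 15 labeled topologies, so the null distribution
        of minimal costs is computable by full enumeration."""
        host = parse_newick("((A,B),(C,D));")
        virus = parse_newick("((a,c),(b,d));")
        assoc = {v: {v.upper()} for v in "abcd"}
        problem = CophylogenyProblem(host, virus, assoc)
        observed = minimal_cost(problem, DEFAULT)

        exact_hits = 0
        labels = list("abcd")
        all_topos = []
        for i1 in range(1):          # insertion positions: 1 x 3 x 5 choices
            for i2 in range(3):
                for i3 in range(5):
                    all_topos.append((i1, i2, i3))
        for choice in all_topos:
            rng = _ForcedChoices(choice)
            topo = random_topology(labels, rng)
            if minimal_cost(CophylogenyProblem(host, topo, assoc),
                            DEFAULT) <= observed:
                exact_hits += 1
        exact_p = exact_hits / 15

        res = random_parasite_test(problem, DEFAULT, n=2000, seed=31)
        assert abs(res.p - exact_p) < 0.05


class _ForcedChoices:
    """Deterministic stand-in for random.Random driving random_topology
    through one explicit insertion sequence (enumerates all topologies)."""

    def __init__(self, picks):
        self.picks = list(picks)

    def choice(self, seq):
        return seq[self.picks.pop(0)]


class TestSummarizeTable:
    def test_congruent_three_tips_default_scheme(self):
        table = summarize_table({"toy": congruent_problem(3)}, [DEFAULT],
                                n_random=20, seed=1)
        row = table.iloc[0]
        assert row["total_cost"] == 0
        assert row["cospeciation"] == "2"
        assert list(table.columns[:8]) == [
            "test", "event_costs", "total_cost", "cospeciation",
            "duplication", "duplication_host_switch", "loss",
            "failure_to_diverge"]

    def test_empty_scheme_list_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            summarize_table({"toy": congruent_problem(3)}, [])
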