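"""Parallel divergence: tree resolution, haplotype separation, subtree
matching, rooted-topology counting and the exact binomial tail."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from meselson.paralleldiv import (
    ParallelDivergenceError,
    binomial_tail,
    is_haplotype_separating,
    is_resolved,
    n_rooted_topologies,
    parallel_divergence_test,
    subtrees_match,
)
from meselson.treemath import parse_newick, root_at_leaf


class TestIsResolved:
    def test_binary_tree_with_real_branches(self):
        t = parse_newick("((a:0.1,b:0.1):0.01,(c:0.1,d:0.1):0.01,e:0.1);")
        assert is_resolved(t)

    def test_tiny_internal_branch_collapses(self):
        t = parse_newick("((a:0.1,b:0.1):1e-9,(c:0.1,d:0.1):0.01,e:0.1);")
        assert not is_resolved(t)

    def test_star_tree(self):
        assert not is_resolved(parse_newick("(a:0.1,b:0.1,c:0.1,d:0.1);"))

    def test_leaf_rooted_form_equivalent(self):
        t = parse_newick("((a:0.1,b:0.1):0.01,(c:0.1,d:0.1):0.01);")
        assert is_resolved(t) == is_resolved(root_at_leaf(t))


class TestHaplotypeSeparation:
    def test_separating_quartet(self):
        t = parse_newick("((x_A:0.1,y_A:0.1):0.05,(x_B:0.1,y_B:0.1):0.05);")
        sep, edge = is_haplotype_separating(t)
        assert sep and edge is not None

    def test_population_grouping_not_separating(self):
        t = parse_newick("((x_A:0.1,x_B:0.1):0.05,(y_A:0.1,y_B:0.1):0.05);")
        sep, _ = is_haplotype_separating(t)
        assert not sep

    def test_unbalanced_leaf_sets_error(self):
        t = parse_newick("((x_A:0.1,y_A:0.1):0.05,(x_B:0.1,z_B:0.1):0.05);")
        with pytest.raises(ParallelDivergenceError, match="unbalanced"):
            is_haplotype_separating(t)


class TestSubtreesMatch:
    def test_mirrored_subtrees_match(self):
        t = parse_newick(
            "(((H1_A:1,H2_A:1):1,(SA1_A:1,SA3_A:1):1):1,"
            "((H1_B:1,H2_B:1):1,(SA1_B:1,SA3_B:1):1):1);"
        )
        assert subtrees_match(t)

    def test_discordant_subtrees(self):
        t = parse_newick(
            "(((H1_A:1,H2_A:1):1,(SA1_A:1,SA3_A:1):1):1,"
            "((H1_B:1,SA1_B:1):1,(H2_B:1,SA3_B:1):1):1);"
        )
        assert not subtrees_match(t)

    def test_three_taxon_sides_match_iff_same_cherry(self):
        # enumeration of the three rooted shapes per side
        def tri(pair):
            a, b = pair
            c = ({"x", "y", "z"} - set(pair)).pop()
            return f"(({a}_%s:1,{b}_%s:1):1,{c}_%s:1)"

        for pa, pb in itertools.product(
            [("x", "y"), ("x", "z"), ("y", "z")], repeat=2
        ):
            nwk = f"({tri(pa) % ('A','A','A')}:1,{tri(pb) % ('B','B','B')}:1);"
            t = parse_newick(nwk)
            assert subtrees_match(t) == (set(pa) == set(pb))

    def test_invariance_to_global_ab_swap_and_leaf_order(self):
        nwk_ab = (
            "(((H1_A:1,H2_A:1):1,SA1_A:1):1,((H2_B:1,H1_B:1):1,SA1_B:1):1);"
        )
        swapped = nwk_ab.replace("_A", "_T").replace("_B", "_A").replace("_T", "_B")
        assert subtrees_match(parse_newick(nwk_ab))
        assert subtrees_match(parse_newick(swapped))


def enumerate_rooted_topologies(k):
    """Oracle: grow all rooted binary labeled trees by stepwise leaf addition
    and count distinct canonical shapes."""

    def canon(t):
        if isinstance(t, str):
            return t
        return "(" + ",".join(sorted(canon(c) for c in t)) + ")"

    trees = [["L0", "L1"]]
    for leaf in range(2, k):
        name = f"L{leaf}"
        nxt = []
        for t in trees:
            # insert on any edge: enumerate attachment points recursively
            def attach(node, path):
                points = [path]
                if not isinstance(node, str):
                    for i, child in enumerate(node):
                        points += attach(child, path + [i])
                return points

            for path in attach(t, []) + [[None]]:
                import copy

                nt = copy.deepcopy(t)
                if path == [None] or not path:  # new root above everything
                    nt = [nt, name]
                else:
                    parent = nt
                    for i in path[:-1]:
                        parent = parent[i]
                    parent[path[-1]] = [parent[path[-1]], name]
                nxt.append(nt)
        # dedupe by canonical form
        seen = {}
        for t in nxt:
            seen[canon(t)] = t
        trees = list(seen.values())
    return len(trees)


class TestRootedTopologyCount:
    @pytest.mark.parametrize("k,expected", [(2, 1), (3, 3), (4, 15)])
    def test_known_values(self, k, expected):
        assert n_rooted_topologies(k) == expected

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_against_exhaustive_generation(self, k):
        assert n_rooted_topologies(k) == enumerate_rooted_topologies(k)

    def test_k_below_two_error(self):
        with pytest.raises(ParallelDivergenceError):
            n_rooted_topologies(1)


def binomial_tail_bruteforce(n, k, x):
    x = Fraction(x)
    total = Fraction(0)
    for outcome in itertools.product([0, 1], repeat=n):
        if sum(outcome) >= k:
            p = Fraction(1)
            for o in outcome:
                p *= x if o else (1 - x)
            total += p
    return float(total)


class TestBinomialTail:
    def test_boundaries_exact(self):
        assert binomial_tail(10, 0, Fraction(1, 3)) == 1.0
        assert binomial_tail(10, 10, Fraction(1, 3)) == float(Fraction(1, 3) ** 10)
        assert binomial_tail(2, 1, Fraction(1, 2)) == 0.75

    @pytest.mark.parametrize("n,k", [(5, 2), (8, 5), (12, 7)])
    def test_against_outcome_enumeration(self, n, k):
        x = Fraction(1, 15)
        assert binomial_tail(n, k, x) == pytest.approx(
            binomial_tail_bruteforce(n, k, x), abs=1e-15
        )

    def test_study_scale_values_significant(self):
        assert binomial_tail(31, 8, Fraction(1, 15)) < 0.001
        assert binomial_tail(55, 38, Fraction(1, 3)) < 0.001


class TestParallelDivergenceTest:
    def _mirror_tree(self, pairs, internal=0.05):
        (a, b), (c, d) = pairs
        return parse_newick(
            f"((({a}_A:0.1,{b}_A:0.1):{internal},({c}_A:0.1,{d}_A:0.1):{internal}):{internal},"
            f"((({a}_B:0.1,{b}_B:0.1):{internal},({c}_B:0.1,{d}_B:0.1):{internal}):{internal}));"
        )

    def test_all_matching_trees_small_p(self):
        trees = [self._mirror_tree((("H1", "H2"), ("SA1", "SA3")))] * 5
        res = parallel_divergence_test(trees)
        assert res.k_taxa == 4
        assert res.x_null == pytest.approx(1 / 15)
        assert res.n_resolved == res.n_separating == res.n_matching == 5
        assert res.p_value == pytest.approx(float(Fraction(1, 15) ** 5), rel=1e-9)

    def test_no_separating_trees_na(self):
        t = parse_newick(
            "((H1_A:0.1,H1_B:0.1):0.05,(H2_A:0.1,H2_B:0.1):0.05,"
            "(SA1_A:0.1,SA1_B:0.1,SA3_A:0.1,SA3_B:0.1):0.05);"
        )
        res = parallel_divergence_test([t])
        assert res.n_separating == 0 and res.p_value is None

    def test_null_matching_rate_near_x(self):
        # uniformly random rooted shapes on each side: matching frequency ~ x
        rng = np.random.default_rng(8)
        labels = ["H1", "H2", "SA1", "SA3"]

        def random_rooted(suffix):
            items = [f"{l}_{suffix}:0.1" for l in rng.permutation(labels)]
            while len(items) > 1:
                i, j = sorted(rng.choice(len(items), 2, replace=False))
                merged = f"({items[i]},{items[j]}):0.1"
                items = [x for k, x in enumerate(items) if k not in (i, j)]
                items.append(merged)
            return items[0]

        n = 600
        match = 0
        for _ in range(n):
            t = parse_newick(f"({random_rooted('A')},{random_rooted('B')});")
            if subtrees_match(t):
                match += 1
        x = 1 / 15
        se = np.sqrt(x * (1 - x) / n)
        assert abs(match / n - x) < 3 * se

    def test_mismatched_leaf_sets_error(self):
        t1 = self._mirror_tree((("H1", "H2"), ("SA1", "SA3")))
        t2 = self._mirror_tree((("H1", "H2"), ("SA1", "KF1")))
        with pytest.raises(ParallelDivergenceError, match="leaf set"):
            parallel_divergence_test([t1, t2])
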