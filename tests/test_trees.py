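"""Tree utilities, JC69 likelihood engine and constraint templates."""

import itertools

import numpy as np
import pytest

from meselson.likelihood import (
    LikelihoodError,
    encode_alignment,
    log_likelihood,
    optimize_branch_lengths,
)
from meselson.simulate import evolve_sequences
from meselson.treemath import (
    TreeError,
    bipartition_lengths,
    branch_score_distance,
    build_constraint_topology,
    nni_neighbors,
    nontrivial_bipartitions,
    parse_newick,
    resolve_polytomies,
    root_at_leaf,
    satisfies_constraint,
    tip_names,
    to_newick,
)
from meselson.treetests import (
    TopologyTestError,
    alignment_distance_matrix,
    jc69_pairwise_distance,
    nj_tree,
    nni_search,
)

from conftest import make_metadata

B = "ACGT"


def seq_rows(tree, length, seed):
    seqs = evolve_sequences(tree, length, np.random.default_rng(seed))
    return [(k, "".join(B[i] for i in v)) for k, v in sorted(seqs.items())]


class TestBranchScoreDistance:
    def test_identity_and_single_branch_difference(self):
        t1 = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.05);")
        t2 = parse_newick("((a:0.2,b:0.1):0.1,(c:0.1,d:0.1):0.05);")
        assert branch_score_distance(t1, t1) == 0.0
        assert branch_score_distance(t1, t2) == pytest.approx(0.1)

    def test_conflicting_topologies_hand_enumeration(self):
        ta = parse_newick("((a:0.1,b:0.1):0.1,c:0.1,d:0.1);")
        tb = parse_newick("((a:0.1,c:0.1):0.1,b:0.1,d:0.1);")
        # external edges agree; the two internal bipartitions conflict
        assert branch_score_distance(ta, tb) == pytest.approx(np.sqrt(0.02))

    def test_matches_dendropy_oracle_on_random_trees(self):
        import dendropy
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(4)
        taxa = [f"t{i}" for i in range(7)]
        for rep in range(5):
            nwks = []
            for _ in range(2):
                perm = list(rng.permutation(taxa))
                nwk = f"(({perm[0]}:{rng.uniform(0.01,.2):.3f},{perm[1]}:{rng.uniform(0.01,.2):.3f}):{rng.uniform(0.01,.2):.3f},({perm[2]}:{rng.uniform(0.01,.2):.3f},({perm[3]}:{rng.uniform(0.01,.2):.3f},{perm[4]}:{rng.uniform(0.01,.2):.3f}):{rng.uniform(0.01,.2):.3f}):{rng.uniform(0.01,.2):.3f},({perm[5]}:{rng.uniform(0.01,.2):.3f},{perm[6]}:{rng.uniform(0.01,.2):.3f}):{rng.uniform(0.01,.2):.3f});"
                nwks.append(nwk)
            got = branch_score_distance(parse_newick(nwks[0]), parse_newick(nwks[1]))
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=nwks[0], schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=nwks[1], schema="newick", taxon_namespace=tns)
            exp = treecompare.euclidean_distance(d1, d2)
            assert got == pytest.approx(exp, abs=1e-9)

    def test_pseudometric_on_random_triples(self):
        rng = np.random.default_rng(9)
        trees = []
        labels = list("abcdef")
        for _ in range(3):
            perm = list(rng.permutation(labels))
            lens = rng.uniform(0.01, 0.3, size=9)
            trees.append(parse_newick(
                f"(({perm[0]}:{lens[0]},{perm[1]}:{lens[1]}):{lens[2]},"
                f"({perm[2]}:{lens[3]},{perm[3]}:{lens[4]}):{lens[5]},"
                f"({perm[4]}:{lens[6]},{perm[5]}:{lens[7]}):{lens[8]});"
            ))
        d01 = branch_score_distance(trees[0], trees[1])
        d12 = branch_score_distance(trees[1], trees[2])
        d02 = branch_score_distance(trees[0], trees[2])
        assert d01 == pytest.approx(branch_score_distance(trees[1], trees[0]))
        assert d02 <= d01 + d12 + 1e-12

    def test_leaf_set_mismatch(self):
        with pytest.raises(TreeError):
            branch_score_distance(
                parse_newick("(a:1,b:1,c:1);"), parse_newick("(a:1,b:1,d:1);")
            )

    def test_leaf_rooted_form_gives_same_distance(self):
        t1 = parse_newick("((a:0.1,b:0.2):0.1,(c:0.1,d:0.1):0.05);")
        t2 = parse_newick("((a:0.1,c:0.1):0.07,(b:0.1,d:0.3):0.05);")
        d_plain = branch_score_distance(t1, t2)
        d_rooted = branch_score_distance(root_at_leaf(t1), root_at_leaf(t2))
        assert d_plain == pytest.approx(d_rooted)


class TestJcDistanceAndNj:
    def test_closed_form(self):
        a = "A" * 90 + "C" * 10
        b = "A" * 100
        assert jc69_pairwise_distance(a, a) == 0.0
        assert jc69_pairwise_distance(a, b) == pytest.approx(
            -0.75 * np.log(1 - 4 * 0.1 / 3)
        )

    def test_saturation_and_empty_overlap(self):
        with pytest.warns(UserWarning, match="saturated"):
            assert jc69_pairwise_distance("AAAA", "CCCC") == float("inf")
        with pytest.raises(TopologyTestError):
            jc69_pairwise_distance("NNNN", "AAAA")

    def test_ambiguity_uses_pairwise_deletion(self):
        assert jc69_pairwise_distance("ANAA", "A-AA") == 0.0

    def test_nj_recovers_additive_tree(self):
        true = parse_newick("((a:0.02,b:0.03):0.015,(c:0.025,d:0.01):0.02);")
        names = sorted(tip_names(true))
        import skbio

        # additive distances = path lengths in the generating tree
        dm_data = np.zeros((4, 4))
        tdm = true.tip_tip_distances()
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                dm_data[i, j] = 0.0 if i == j else tdm[x, y]
        tree = nj_tree(skbio.DistanceMatrix(dm_data, ids=names))
        assert nontrivial_bipartitions(tree) == nontrivial_bipartitions(true)
        assert branch_score_distance(tree, true) < 1e-9

    def test_infinite_distance_rejected(self):
        import skbio

        dm = skbio.DistanceMatrix(
            [[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]], ids=list("abc")
        )
        with pytest.raises(TopologyTestError, match="exclude"):
            nj_tree(dm)


class TestLikelihood:
    def test_two_taxon_ml_equals_jc_closed_form(self):
        rows = seq_rows(parse_newick("(x:0.04,y:0.04);"), 4000, 0)
        enc = encode_alignment(rows)
        fit, _, _ = optimize_branch_lengths(root_at_leaf(parse_newick("(x:0.01,y:0.01);")), enc)
        total = sum(n.length for n in fit.traverse(include_self=False))
        d = jc69_pairwise_distance(rows[0][1], rows[1][1])
        assert total == pytest.approx(d, abs=1e-6)

    def test_constant_alignment_lnl(self):
        rows = [("a", "AAAA"), ("b", "AAAA"), ("c", "AAAA")]
        enc = encode_alignment(rows)
        tree = root_at_leaf(parse_newick("(a:0.0,b:0.0,c:0.0);"))
        fit, lnl, site = optimize_branch_lengths(tree, enc)
        assert lnl == pytest.approx(4 * np.log(0.25), abs=1e-4)
        assert all(n.length <= 1e-6 for n in fit.traverse(include_self=False))

    def test_invalid_symbol_rejected(self):
        with pytest.raises(LikelihoodError, match="symbol"):
            encode_alignment([("a", "ACGX")])

    def test_lnl_monotone_over_rounds(self):
        tree = parse_newick("(((a:0.02,b:0.02):0.01,(c:0.02,d:0.02):0.01):0.01,(e:0.02,f:0.02):0.01);")
        rows = seq_rows(tree, 800, 3)
        enc = encode_alignment(rows)
        start = root_at_leaf(tree)
        for node in start.traverse(include_self=False):
            node.length = 0.2  # deliberately bad start
        traces = []
        prev = log_likelihood(start, enc)[0]
        for rounds in range(1, 6):
            _, lnl, _ = optimize_branch_lengths(start, enc, max_rounds=rounds)
            traces.append(lnl)
        assert traces[0] >= prev - 1e-9
        assert all(b >= a - 1e-9 for a, b in zip(traces, traces[1:]))

    def test_branch_length_recovery_within_ten_percent(self):
        tree = parse_newick(
            "(((a:0.03,b:0.03):0.02,(c:0.03,d:0.03):0.02):0.02,(e:0.03,f:0.05):0.02);"
        )
        rows = seq_rows(tree, 10000, 11)
        enc = encode_alignment(rows)
        fit, _, _ = optimize_branch_lengths(root_at_leaf(tree), enc)
        got = bipartition_lengths(fit)
        exp = bipartition_lengths(root_at_leaf(tree))
        total_got = sum(got.values())
        total_exp = sum(exp.values())
        assert total_got == pytest.approx(total_exp, rel=0.10)


class TestNniSearch:
    def test_no_move_from_true_topology_on_clean_data(self):
        tree = parse_newick(
            "(((a:0.05,b:0.05):0.03,(c:0.05,d:0.05):0.03):0.03,(e:0.05,f:0.05):0.03);"
        )
        rows = seq_rows(tree, 4000, 7)
        enc = encode_alignment(rows)
        best, _, _ = nni_search(root_at_leaf(tree), enc)
        assert nontrivial_bipartitions(best) == nontrivial_bipartitions(root_at_leaf(tree))

    def test_four_taxon_matches_exhaustive_search(self):
        # all 3 unrooted topologies fitted exhaustively as the oracle
        topologies = [
            "((a:0.05,b:0.05):0.03,(c:0.05,d:0.05):0.0);",
            "((a:0.05,c:0.05):0.03,(b:0.05,d:0.05):0.0);",
            "((a:0.05,d:0.05):0.03,(b:0.05,c:0.05):0.0);",
        ]
        wins = 0
        reps = 20
        for rep in range(reps):
            true = parse_newick(topologies[rep % 3])
            rows = seq_rows(true, 600, 100 + rep)
            enc = encode_alignment(rows)
            best_exh, best_lnl = None, -np.inf
            for nwk in topologies:
                _, lnl, _ = optimize_branch_lengths(
                    root_at_leaf(parse_newick(nwk)), enc
                )
                if lnl > best_lnl:
                    best_exh, best_lnl = nwk, lnl
            dm = alignment_distance_matrix(rows)
            found, lnl_found, _ = nni_search(root_at_leaf(nj_tree(dm)), enc)
            if nontrivial_bipartitions(found) == nontrivial_bipartitions(
                root_at_leaf(parse_newick(best_exh))
            ) or lnl_found >= best_lnl - 1e-6:
                wins += 1
        assert wins >= 0.95 * reps

    def test_neighbor_count_binary_tree(self):
        t = root_at_leaf(parse_newick("((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);"))
        # unrooted 6-taxon binary tree: 3 internal edges x 2 moves
        assert sum(1 for _ in nni_neighbors(t)) == 6


class TestConstraints:
    @pytest.fixture()
    def meta(self):
        pops = {"H1": "H", "H2": "H", "SA1": "SA", "SA3": "SA",
                "H3": "H", "KF1": "KF", "KF2": "KF"}
        lins = {"H1": "I", "H2": "I", "SA1": "I", "SA3": "I",
                "H3": "II", "KF1": "II", "KF2": "II"}
        return make_metadata(pops, lins)

    def test_asex_constraint_separates_haplotypes_at_base(self, meta):
        parts = sorted(meta.individuals)
        t = build_constraint_topology("asex", parts, meta, "two-lineage")
        bip = nontrivial_bipartitions(t)
        a_side = frozenset(f"{i}_A" for i in parts)
        all_tips = frozenset(tip_names(t))
        canon = min(a_side, all_tips - a_side, key=lambda s: (len(s), sorted(s)))
        assert canon in bip

    def test_sex_constraint_never_separates_haplotypes(self, meta):
        parts = sorted(meta.individuals)
        t = build_constraint_topology("sex", parts, meta, "two-lineage")
        a_side = frozenset(f"{i}_A" for i in parts)
        all_tips = frozenset(tip_names(t))
        canon = min(a_side, all_tips - a_side, key=lambda s: (len(s), sorted(s)))
        assert canon not in nontrivial_bipartitions(t)

    def test_two_population_sex_template_single_bipartition(self):
        meta = make_metadata({"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2"})
        t = build_constraint_topology("sex", ["a1", "a2", "b1", "b2"], meta,
                                      "single-species")
        bip = nontrivial_bipartitions(t)
        assert frozenset({"a1_A", "a1_B", "a2_A", "a2_B"}) in bip

    def test_resolution_preserves_constraint(self, meta):
        parts = sorted(meta.individuals)
        t = build_constraint_topology("asex", parts, meta, "two-lineage")
        resolved = resolve_polytomies(t)
        assert satisfies_constraint(root_at_leaf(resolved), nontrivial_bipartitions(t))
        internal = [n for n in resolved.traverse(include_self=False) if n.children]
        assert all(len(n.children) == 2 for n in resolved.traverse() if n.children)

    def test_missing_lineage_label_error(self):
        meta = make_metadata({"x1": "P"}, {})
        with pytest.raises(TreeError, match="lineage"):
            build_constraint_topology("asex", ["x1"], meta, "two-lineage")

    def test_roundtrip_newick(self, meta):
        t = build_constraint_topology("asex", sorted(meta.individuals), meta,
                                      "two-lineage")
        again = parse_newick(to_newick(t))
        assert nontrivial_bipartitions(again) == nontrivial_bipartitions(t)
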