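"""Tree utilities: Newick I/O, bipartitions, branch-score distance, NNI moves,
polytomy resolution and the haplotype/population constraint templates.

Trees are scikit-bio ``TreeNode`` objects. For topology search and
likelihood computation a canonical "leaf-rooted" form is used: the root node
is a leaf (carries a tip name) with exactly one child, and every other
internal node is strictly binary. In that form the internal edges of the
underlying unrooted tree are exactly the parent-child edges between two
internal nodes, which makes nearest-neighbor-interchange enumeration simple
and duplicate-free.
"""

from __future__ import annotations

import io
from collections import defaultdict

import numpy as np
from skbio import TreeNode


class TreeError(ValueError):
    pass


def parse_newick(s: str) -> TreeNode:
    return TreeNode.read(io.StringIO(s), convert_underscores=False)


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tip_names(tree: TreeNode) -> set[str]:
    """All leaf names; in the leaf-rooted form the named root counts as a leaf."""
    names = {t.name for t in tree.tips()}
    if tree.name is not None and len(tree.children) == 1:
        names.add(tree.name)
    return names


def root_at_leaf(tree: TreeNode, leaf_name: str | None = None) -> TreeNode:
    """Return a copy rooted at a leaf (the lexicographically smallest by default).

    Unifurcations created by the original root are suppressed (edge lengths
    summed), so a binary unrooted tree yields strictly binary internal nodes.
    """
    names = sorted(tip_names(tree))
    if leaf_name is None:
        leaf_name = names[0]
    elif leaf_name not in names:
        raise TreeError(f"{leaf_name} is not a tip of the tree")

    adj: dict[int, list[tuple]] = defaultdict(list)
    nodes: dict[int, TreeNode] = {}
    for node in tree.traverse(include_self=True):
        nodes[id(node)] = node
        for child in node.children:
            ln = child.length if child.length is not None else 0.0
            adj[id(node)].append((id(child), ln))
            adj[id(child)].append((id(node), ln))

    start = next(t for t in tree.tips() if t.name == leaf_name)

    def build(cur: int, prev: int | None, edge_len) -> TreeNode:
        orig = nodes[cur]
        neighbors = [(o, ln) for o, ln in adj[cur] if o != prev]
        new = TreeNode(name=orig.name if not neighbors or prev is None else orig.name)
        new.length = edge_len
        for o, ln in neighbors:
            new.append(build(o, cur, ln))
        return new

    root = build(id(start), None, None)
    # suppress unifurcations below the root (the root-leaf keeps one child)
    for node in list(root.traverse(include_self=False)):
        while len(node.children) == 1 and node.children[0].children:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            parent.remove(node)
            parent.append(child)
            node = child
    # a unifurcation chain directly under the root
    top = root.children[0]
    while len(top.children) == 1:
        child = top.children[0]
        child.length = (child.length or 0.0) + (top.length or 0.0)
        root.remove(top)
        root.append(child)
        top = child
    return root


def _canonical(tipset: frozenset, all_tips: frozenset) -> frozenset:
    comp = all_tips - tipset
    a, b = sorted([tipset, comp], key=lambda s: (len(s), sorted(s)))
    return a


def bipartition_lengths(tree: TreeNode) -> dict[frozenset, float]:
    """Branch length of every bipartition (external edges included).

    For a rooted representation the two edges meeting at a bifurcating root
    describe the same bipartition of the underlying unrooted tree; their
    lengths are summed.
    """
    all_tips = frozenset(tip_names(tree))
    out: dict[frozenset, float] = defaultdict(float)
    for node in tree.traverse(include_self=False):
        below = frozenset(t.name for t in node.tips(include_self=True))
        if not below or below == all_tips:
            continue
        out[_canonical(below, all_tips)] += node.length if node.length else 0.0
    return dict(out)


def branch_score_distance(t1: TreeNode, t2: TreeNode) -> float:
    """Kuhner-Felsenstein branch-score distance.

    Square root of the sum, over the union of the two trees' bipartitions,
    of squared branch-length differences; a bipartition absent from one tree
    contributes length zero there.
    """
    if tip_names(t1) != tip_names(t2):
        raise TreeError("trees must share the same leaf set")
    b1 = bipartition_lengths(t1)
    b2 = bipartition_lengths(t2)
    total = 0.0
    for key in set(b1) | set(b2):
        total += (b1.get(key, 0.0) - b2.get(key, 0.0)) ** 2
    return float(np.sqrt(total))


def _preorder_index(tree: TreeNode) -> list[TreeNode]:
    return list(tree.traverse(include_self=True))


def nni_neighbors(tree: TreeNode):
    """Yield the NNI neighbors of a leaf-rooted binary tree (deterministic order).

    One internal edge (p -> c with both internal) admits two interchanges:
    swap c's sibling with either child of c.
    """
    order = _preorder_index(tree)
    for i, node in enumerate(order):
        if not node.children or node.parent is None:
            continue
        p = node.parent
        if p.parent is None:  # p is the leaf-root: edge is external
            continue
        for child_idx in range(len(node.children)):
            neigh = tree.copy()
            n_order = _preorder_index(neigh)
            c = n_order[i]
            pp = c.parent
            sibs = [x for x in pp.children if x is not c]
            if len(sibs) != 1 or len(c.children) != 2:
                raise TreeError("NNI requires a strictly binary leaf-rooted tree")
            s = sibs[0]
            a = c.children[child_idx]
            pp.remove(s)
            c.remove(a)
            pp.append(a)
            c.append(s)
            yield neigh


def resolve_polytomies(tree: TreeNode) -> TreeNode:
    """Deterministically resolve polytomies into ladders (zero-length edges).

    Children are ordered by their smallest descendant tip name and combined
    pairwise; the result is binary and contains every bipartition of the
    input.
    """
    t = tree.copy()
    for node in list(t.traverse(include_self=True)):
        while len(node.children) > 2:
            kids = sorted(
                node.children,
                key=lambda c: min(x.name for x in c.tips(include_self=True)),
            )
            a, b = kids[0], kids[1]
            node.remove(a)
            node.remove(b)
            joint = TreeNode(length=0.0)
            joint.append(a)
            joint.append(b)
            node.append(joint)
    return t


def nontrivial_bipartitions(tree: TreeNode) -> set[frozenset]:
    all_tips = frozenset(tip_names(tree))
    out = set()
    for node in tree.traverse(include_self=False):
        below = frozenset(t.name for t in node.tips(include_self=True))
        if 2 <= len(below) <= len(all_tips) - 2:
            out.add(_canonical(below, all_tips))
    return out


def satisfies_constraint(tree: TreeNode, constraint_biparts: set[frozenset]) -> bool:
    return constraint_biparts <= nontrivial_bipartitions(tree)


def _clade(children: list[TreeNode]) -> TreeNode:
    if len(children) == 1:
        return children[0]
    node = TreeNode(length=None)
    for c in children:
        node.append(c)
    return node


def _leaf(name: str) -> TreeNode:
    return TreeNode(name=name, length=None)


def build_constraint_topology(
    mode: str,
    participants: list[str],
    metadata,
    species_template: str = "two-lineage",
    most_divergent_population: str | None = None,
) -> TreeNode:
    """Multifurcating constraint topology for the asex-/sex-tree contrast.

    Leaves are ``<individual>_<A|B>``. Two-lineage template (clonal species
    with divergent lineages): the asex constraint separates all A from all B
    haplotypes at its base, then lineages per haplotype clade, then
    populations per lineage; the sex constraint separates lineages at the
    base and populations per lineage with NO haplotype separation.
    Single-species template: the asex constraint separates A from B with
    populations per haplotype clade (optionally splitting the most divergent
    population's B haplotypes to avoid a basal trichotomy); the sex
    constraint groups exclusively by population. Grouping levels with a
    single member collapse into the parent polytomy.
    """
    if mode not in ("asex", "sex"):
        raise TreeError("mode must be 'asex' or 'sex'")
    if species_template not in ("two-lineage", "single-species"):
        raise TreeError("species_template must be 'two-lineage' or 'single-species'")

    def pop_of(ind):
        return str(metadata.population(ind))

    def lin_of(ind):
        lab = metadata.lineage(ind)
        import pandas as pd

        if pd.isna(lab) or lab == "":
            raise TreeError(f"participant {ind} lacks a lineage label")
        return str(lab)

    pops = sorted({pop_of(i) for i in participants})

    def hap_clade(suffix: str) -> TreeNode:
        """A or B side grouped lineage -> population (two-lineage template)."""
        lins = sorted({lin_of(i) for i in participants})
        lin_nodes = []
        for lin in lins:
            members = [i for i in participants if lin_of(i) == lin]
            pop_nodes = []
            for p in sorted({pop_of(i) for i in members}):
                inds = sorted(i for i in members if pop_of(i) == p)
                pop_nodes.append(_clade([_leaf(f"{i}_{suffix}") for i in inds]))
            lin_nodes.append(_clade(pop_nodes))
        return _clade(lin_nodes)

    def pop_clade(suffix: str, subset_pops=None) -> TreeNode:
        nodes = []
        for p in subset_pops if subset_pops is not None else pops:
            inds = sorted(i for i in participants if pop_of(i) == p)
            nodes.append(_clade([_leaf(f"{i}_{suffix}") for i in inds]))
        return _clade(nodes)

    root = TreeNode(length=None)
    if species_template == "two-lineage":
        if mode == "asex":
            root.append(hap_clade("A"))
            root.append(hap_clade("B"))
        else:
            lins = sorted({lin_of(i) for i in participants})
            for lin in lins:
                members = [i for i in participants if lin_of(i) == lin]
                pop_nodes = []
                for p in sorted({pop_of(i) for i in members}):
                    inds = sorted(i for i in members if pop_of(i) == p)
                    leaves = [_leaf(f"{i}_{s}") for i in inds for s in ("A", "B")]
                    pop_nodes.append(_clade(leaves))
                root.append(_clade(pop_nodes))
    else:
        if mode == "asex":
            root.append(pop_clade("A"))
            if most_divergent_population and most_divergent_population in pops:
                others = [p for p in pops if p != most_divergent_population]
                b = TreeNode(length=None)
                b.append(pop_clade("B", [most_divergent_population]))
                b.append(pop_clade("B", others))
                root.append(b)
            else:
                root.append(pop_clade("B"))
        else:
            for p in pops:
                inds = sorted(i for i in participants if pop_of(i) == p)
                leaves = [_leaf(f"{i}_{s}") for i in inds for s in ("A", "B")]
                root.append(_clade(leaves))
    return root
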