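"""Signature IV: parallel divergence of haplotype subtrees.

In a clonal lineage both haplotype clades co-diverge through the same
population history, so the rooted topology of the haplotype-A subtree should
match the haplotype-B subtree. Among resolved (nonpolytomous) per-region
trees that fully separate A from B haplotypes, matching subtree pairs are
counted and the excess over the uniform-topology null probability
x = 1 / #rooted-topologies(k) is assessed with an exact binomial tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

from skbio import TreeNode


class ParallelDivergenceError(ValueError):
    pass


# ---------------------------------------------------------------- graph form


def _unrooted_graph(tree: TreeNode):
    """(names, adj) adjacency of the unrooted tree; degree-2 artifacts of
    rooting are suppressed."""
    names: dict[int, str | None] = {}
    adj: dict[int, dict[int, float]] = {}
    idx = 0
    ids: dict[int, int] = {}
    for node in tree.traverse(include_self=True):
        ids[id(node)] = idx
        is_leaf = not node.children or (
            node.parent is None and node.name is not None and len(node.children) == 1
        )  # the named root of a leaf-rooted tree is a leaf of the unrooted tree
        names[idx] = node.name if is_leaf else None
        adj[idx] = {}
        idx += 1
    for node in tree.traverse(include_self=True):
        for child in node.children:
            u, v = ids[id(node)], ids[id(child)]
            ln = child.length if child.length is not None else 0.0
            adj[u][v] = ln
            adj[v][u] = ln
    # suppress unnamed degree-2 nodes (the artificial root of a rooted newick)
    for u in list(adj):
        if names[u] is None and len(adj[u]) == 2:
            (a, la), (b, lb) = adj[u].items()
            del adj[a][u]
            del adj[b][u]
            adj[a][b] = la + lb
            adj[b][a] = la + lb
            del adj[u]
            del names[u]
    return names, adj


def _contract_short_internal_edges(names, adj, eps: float):
    """Union-find contraction of internal edges with length < eps."""
    parent = {u: u for u in adj}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for u in adj:
        for v, ln in adj[u].items():
            if u < v and names[u] is None and names[v] is None and ln < eps:
                parent[find(v)] = find(u)
    groups: dict[int, int] = {u: find(u) for u in adj}
    new_adj: dict[int, set[int]] = {}
    for u in adj:
        gu = groups[u]
        new_adj.setdefault(gu, set())
        for v in adj[u]:
            gv = groups[v]
            if gu != gv:
                new_adj[gu].add(gv)
    new_names = {}
    for u, nm in names.items():
        if nm is not None:
            new_names[groups[u]] = nm
    return new_names, new_adj


def is_resolved(tree: TreeNode, eps: float = 1e-6) -> bool:
    """True when, after collapsing internal branches shorter than ``eps``,
    the unrooted tree is fully binary (every internal node of degree 3)."""
    names, adj = _unrooted_graph(tree)
    names, cadj = _contract_short_internal_edges(names, adj, eps)
    for u, nbrs in cadj.items():
        if u not in names and len(nbrs) != 3:
            return False
        if u in names and len(nbrs) > 1:
            return False
    return True


def _side_tips(adj, names, u, banned) -> set[str]:
    out, stack, seen = set(), [u], {banned, u}
    while stack:
        cur = stack.pop()
        if names.get(cur) is not None:
            out.add(names[cur])
        for nxt in adj[cur]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return out


def _split_suffix(name: str) -> tuple[str, str]:
    if name.endswith("_A") or name.endswith("_B"):
        return name[:-2], name[-1]
    raise ParallelDivergenceError(f"leaf {name!r} lacks an _A/_B suffix")


def is_haplotype_separating(tree: TreeNode):
    """Whether some edge bipartitions all _A leaves from all _B leaves.

    Returns (flag, edge) with the edge as a pair of graph node ids (opaque;
    reuse with :func:`subtrees_match`). Raises when the A and B leaf sets do
    not cover the same individuals.
    """
    names, adj = _unrooted_graph(tree)
    tips = {u: nm for u, nm in names.items() if nm is not None}
    a_set = {nm for nm in tips.values() if _split_suffix(nm)[1] == "A"}
    b_set = {nm for nm in tips.values() if _split_suffix(nm)[1] == "B"}
    if {_split_suffix(n)[0] for n in a_set} != {_split_suffix(n)[0] for n in b_set}:
        raise ParallelDivergenceError("unbalanced A/B leaf sets")
    for u in adj:
        for v in adj[u]:
            if u < v:
                side = _side_tips(adj, names, u, v)
                if side == a_set or side == b_set:
                    return True, (u, v)
    return False, None


def _canonical_shape(adj, names, u, parent) -> str:
    if names.get(u) is not None:
        return _split_suffix(names[u])[0]
    parts = sorted(
        _canonical_shape(adj, names, v, u) for v in adj[u] if v != parent
    )
    return "(" + ",".join(parts) + ")"


def subtrees_match(tree: TreeNode, edge=None) -> bool:
    """Whether the two rooted subtrees on either side of the haplotype-
    separating edge are topologically identical after stripping _A/_B
    suffixes (branch lengths ignored)."""
    names, adj = _unrooted_graph(tree)
    if edge is None:
        sep, edge = is_haplotype_separating(tree)
        if not sep:
            raise ParallelDivergenceError("tree is not haplotype-separating")
    u, v = edge
    shape_u = _canonical_shape(adj, names, u, v)
    shape_v = _canonical_shape(adj, names, v, u)
    return shape_u == shape_v


def n_rooted_topologies(k: int) -> int:
    """Number of rooted binary leaf-labeled topologies on k taxa: (2k-3)!!."""
    if k < 2:
        raise ParallelDivergenceError("k must be >= 2")
    out = 1
    for i in range(3, 2 * k - 2, 2):
        out *= i
    return out


def binomial_tail(n: int, k: int, x) -> float:
    """Exact upper-tail binomial probability P(X >= k | n, x).

    Computed in exact rational arithmetic and returned as float.
    """
    if not (0 <= k <= n):
        raise ParallelDivergenceError("need 0 <= k <= n")
    x = Fraction(x)
    if not (0 < x < 1):
        raise ParallelDivergenceError("need 0 < x < 1")
    y = 1 - x
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * x**i * y ** (n - i)
    return float(total)


@dataclass
class ParallelResult:
    n_trees: int
    n_resolved: int
    n_separating: int
    n_matching: int
    k_taxa: int
    x_null: float
    fold: float | None
    p_value: float | None

    def __post_init__(self):
        assert self.n_matching <= self.n_separating <= self.n_resolved


def parallel_divergence_test(trees: list[TreeNode], eps: float = 1e-6) -> ParallelResult:
    """Count resolved / haplotype-separating / subtree-matching trees and the
    exact binomial significance of the matching frequency.

    All trees must share one leaf set of 2k ``<ind>_<A|B>`` leaves; the null
    matching probability is x = 1/#rooted-topologies(k).
    """
    if not trees:
        raise ParallelDivergenceError("no trees supplied")
    from .treemath import tip_names

    leafsets = {frozenset(tip_names(tr)) for tr in trees}
    if len(leafsets) != 1:
        raise ParallelDivergenceError("trees must share the lineage's leaf set")
    leaves = leafsets.pop()
    k = len(leaves) // 2
    x = Fraction(1, n_rooted_topologies(k))
    n_res = n_sep = n_match = 0
    for tr in trees:
        if not is_resolved(tr, eps=eps):
            continue
        n_res += 1
        sep, edge = is_haplotype_separating(tr)
        if not sep:
            continue
        n_sep += 1
        if subtrees_match(tr, edge):
            n_match += 1
    if n_sep == 0:
        fold = p = None
    else:
        fold = n_match / (n_sep * float(x))
        p = binomial_tail(n_sep, n_match, x)
    return ParallelResult(
        n_trees=len(trees),
        n_resolved=n_res,
        n_separating=n_sep,
        n_matching=n_match,
        k_taxa=k,
        x_null=float(x),
        fold=fold,
        p_value=p,
    )
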