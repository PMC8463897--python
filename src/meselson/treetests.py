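"""Signature III inference: per-region constrained-topology likelihood tests.

For each phaseable region the best unconstrained maximum-likelihood tree is
compared, by Kuhner-Felsenstein branch-score distance, with two fitted
constraint topologies: the "asex-tree" (haplotypes A and B separated at the
base) and the "sex-tree" (populations/lineages separated, no haplotype
separation). The Delta statistic is

    Delta = dist(best ML, asex-tree) - dist(best ML, sex-tree)

so negative values favor haplotype divergence under clonality. Pairwise tree
comparisons use the approximately unbiased (AU) test on RELL-resampled
per-site log-likelihoods (multiscale bootstrap with a normal-quantile
weighted least-squares fit), and each region is assigned one of five
topology categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .likelihood import (
    EncodedAlignment,
    encode_alignment,
    optimize_branch_lengths,
)
from .treemath import (
    branch_score_distance,
    nni_neighbors,
    nontrivial_bipartitions,
    resolve_polytomies,
    root_at_leaf,
    satisfies_constraint,
)

AU_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))
CATEGORIES = (
    "unconst=asex>sex",
    "asex>sex",
    "no-difference",
    "sex>asex",
    "unconst=sex>asex",
    "untestable",
)


class TopologyTestError(ValueError):
    pass


def jc69_pairwise_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance with pairwise deletion of ambiguous columns.

    Saturated pairs (mismatch fraction >= 3/4) return +inf with a warning.
    """
    if len(seq_a) != len(seq_b):
        raise TopologyTestError("sequences differ in length")
    used = mism = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in "ACGT" and b in "ACGT":
            used += 1
            if a != b:
                mism += 1
    if used == 0:
        raise TopologyTestError("no usable (unambiguous) columns in common")
    p = mism / used
    if p >= 0.75:
        warnings.warn("JC69 distance saturated (p >= 0.75)", stacklevel=2)
        return float("inf")
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


def alignment_distance_matrix(rows: list[tuple[str, str]]) -> DistanceMatrix:
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc69_pairwise_distance(rows[i][1], rows[j][1])
    return DistanceMatrix(d, ids=[name for name, _ in rows])


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining starting tree (negative branch lengths clamped to 0)."""
    if len(dm.ids) < 3:
        raise TopologyTestError("neighbor joining needs >= 3 labels")
    if not np.isfinite(dm.data).all():
        raise TopologyTestError(
            "infinite pairwise distance; exclude the region (saturated haplotypes)"
        )
    return nj(dm, neg_as_zero=True)


def nni_search(
    start: TreeNode,
    enc: EncodedAlignment,
    lnl_tol: float = 1e-4,
    max_iter: int = 50,
) -> tuple[TreeNode, float, np.ndarray]:
    """Hill-climbing over nearest-neighbor interchanges from a starting tree.

    Candidates are screened with a single branch-length sweep (they inherit
    the current tree's lengths, so one sweep is nearly converged); the best
    screened move is then fully re-optimized and accepted on strict
    improvement (> ``lnl_tol``). Deterministic given the start tree.
    """
    cur, cur_lnl, cur_site = optimize_branch_lengths(start, enc)
    for _ in range(max_iter):
        best, best_lnl = None, cur_lnl
        for cand in nni_neighbors(cur):
            fit, lnl, _ = optimize_branch_lengths(cand, enc, max_rounds=1)
            if lnl > best_lnl + lnl_tol:
                best, best_lnl = fit, lnl
        if best is None:
            break
        fit, lnl, site = optimize_branch_lengths(best, enc)
        if lnl <= cur_lnl + lnl_tol:
            break
        cur, cur_lnl, cur_site = fit, lnl, site
    return cur, cur_lnl, cur_site


def constrained_fit(
    constraint: TreeNode,
    enc: EncodedAlignment,
    lnl_tol: float = 1e-4,
    max_iter: int = 50,
) -> tuple[TreeNode, float, np.ndarray]:
    """Fit a constraint topology: resolve polytomies, then NNI restricted to
    moves that preserve every constraint bipartition, with full branch-length
    optimization."""
    cbip = nontrivial_bipartitions(constraint)
    start = root_at_leaf(resolve_polytomies(constraint))
    cur, cur_lnl, cur_site = optimize_branch_lengths(start, enc)
    for _ in range(max_iter):
        best, best_lnl = None, cur_lnl
        for cand in nni_neighbors(cur):
            if not satisfies_constraint(cand, cbip):
                continue
            fit, lnl, _ = optimize_branch_lengths(cand, enc, max_rounds=1)
            if lnl > best_lnl + lnl_tol:
                best, best_lnl = fit, lnl
        if best is None:
            break
        fit, lnl, site = optimize_branch_lengths(best, enc)
        if lnl <= cur_lnl + lnl_tol:
            break
        cur, cur_lnl, cur_site = fit, lnl, site
    return cur, cur_lnl, cur_site


def au_test_pair(
    site_lnl_x: np.ndarray,
    site_lnl_y: np.ndarray,
    n_rell: int = 10000,
    scales=AU_SCALES,
    seed: int | None = None,
) -> float | None:
    """AU p-value for "tree X fits at least as well as tree Y".

    Small values reject X in favor of Y. RELL resampling: at each scale r,
    ceil(r L) site indices are drawn with replacement and the per-tree totals
    recomputed from the fixed per-site log-likelihoods; the bootstrap
    proportions are mapped through the normal quantile and the signed
    distance d and curvature c fitted by weighted least squares, giving
    p = 1 - Phi(d - c). Returns None (untestable) when the two trees have
    identical per-site log-likelihoods.
    """
    d_site = np.asarray(site_lnl_x, dtype=float) - np.asarray(site_lnl_y, dtype=float)
    n_sites = d_site.size
    if n_sites < 2 or np.max(np.abs(d_site)) < 1e-12:
        return None
    rng = np.random.default_rng(seed)
    bps = []
    for r in scales:
        m = int(np.ceil(r * n_sites))
        counts = rng.multinomial(m, np.full(n_sites, 1.0 / n_sites), size=n_rell)
        sums = counts @ d_site
        bp = float(np.mean(sums > 0) + 0.5 * np.mean(sums == 0))
        bps.append(bp)
    bps = np.asarray(bps)
    if np.all(bps <= 0.0):
        return 0.0
    if np.all(bps >= 1.0):
        return 1.0
    eps = 1.0 / (2.0 * n_rell)
    bps_c = np.clip(bps, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bps_c)
    # at scale sigma^2 = 1/r the signed distance contributes d/sigma (it
    # grows with sqrt of the resample size) and the boundary curvature c*sigma
    sig = 1.0 / np.sqrt(np.asarray(scales))
    X = np.column_stack([1.0 / sig, sig])
    w = n_rell * norm.pdf(z) ** 2 / (bps_c * (1.0 - bps_c))
    wx = X * w[:, None]
    beta, *_ = np.linalg.lstsq(wx.T @ X, wx.T @ z, rcond=None)
    d_hat, c_hat = float(beta[0]), float(beta[1])
    return float(np.clip(1.0 - norm.cdf(d_hat - c_hat), 0.0, 1.0))


def rell_au_tests(
    site_lnl: dict[str, np.ndarray],
    n_rell: int = 10000,
    scales=AU_SCALES,
    seed: int | None = None,
) -> dict[str, float | None]:
    """Pairwise AU p-values between the unconstrained, asex and sex trees.

    Keys are ``"<X>_vs_<Y>"`` = p-value that X is not worse than Y; a value
    None marks the comparison untestable (identical site log-likelihoods).
    """
    required = {"unconstrained", "asex", "sex"}
    if not required <= set(site_lnl):
        raise TopologyTestError(f"site_lnl needs keys {sorted(required)}")
    pairs = [
        ("asex", "sex"),
        ("sex", "asex"),
        ("asex", "unconstrained"),
        ("sex", "unconstrained"),
    ]
    ss = np.random.SeedSequence(seed)
    out = {}
    for (x, y), child in zip(pairs, ss.spawn(len(pairs))):
        out[f"{x}_vs_{y}"] = au_test_pair(
            site_lnl[x], site_lnl[y], n_rell=n_rell, scales=scales,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
    return out


def classify_topology(au: dict[str, float | None], alpha: float = 0.05) -> str:
    """Five-way topology category from the pairwise AU p-values.

    Categories, most to least consistent with clonal haplotype divergence:
    the sex-tree rejected and the asex-tree indistinguishable from the
    unconstrained tree; the sex-tree rejected against the asex-tree; no
    difference; and the two mirrored sex-favoring categories.
    """
    p_sex = au.get("sex_vs_asex")
    p_asex = au.get("asex_vs_sex")
    if p_sex is None or p_asex is None:
        return "untestable"
    p_asex_unc = au.get("asex_vs_unconstrained")
    p_sex_unc = au.get("sex_vs_unconstrained")
    if p_sex < alpha and (p_asex_unc is None or p_asex_unc >= alpha):
        return "unconst=asex>sex"
    if p_sex < alpha:
        return "asex>sex"
    if p_asex < alpha and (p_sex_unc is None or p_sex_unc >= alpha):
        return "unconst=sex>asex"
    if p_asex < alpha:
        return "sex>asex"
    return "no-difference"


@dataclass
class TopologyTestResult:
    region: str
    delta: float | None
    lnl: dict = field(default_factory=dict)
    au: dict = field(default_factory=dict)
    category: str = "untestable"
    best_tree: TreeNode | None = None
    asex_tree: TreeNode | None = None
    sex_tree: TreeNode | None = None
    n_unique_sequences: int = 0


def delta_statistic(
    rows: list[tuple[str, str]],
    constraint_asex: TreeNode,
    constraint_sex: TreeNode,
    region: str = "",
    n_rell: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> TopologyTestResult:
    """Full per-region topology test: Delta statistic, AU tests, category.

    Regions with fewer than four unique aligned sequences are untestable
    (constrained tree reconstruction is not meaningful below that), as are
    regions with saturated pairwise distances.
    """
    uniq = len({seq for _, seq in rows})
    res = TopologyTestResult(region=region, delta=None, n_unique_sequences=uniq)
    if uniq < 4:
        return res
    try:
        dm = alignment_distance_matrix(rows)
        start = root_at_leaf(nj_tree(dm))
    except TopologyTestError:
        return res
    enc = encode_alignment(rows)
    best, lnl_best, site_best = nni_search(start, enc)
    asex_fit, lnl_asex, site_asex = constrained_fit(constraint_asex, enc)
    sex_fit, lnl_sex, site_sex = constrained_fit(constraint_sex, enc)
    res.best_tree, res.asex_tree, res.sex_tree = best, asex_fit, sex_fit
    res.delta = branch_score_distance(best, asex_fit) - branch_score_distance(
        best, sex_fit
    )
    res.lnl = {"unconstrained": lnl_best, "asex": lnl_asex, "sex": lnl_sex}
    res.au = rell_au_tests(
        {"unconstrained": site_best, "asex": site_asex, "sex": site_sex},
        n_rell=n_rell,
        seed=seed,
    )
    res.category = classify_topology(res.au, alpha=alpha)
    return res
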