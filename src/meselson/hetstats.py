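"""Signature II (part 1): heterozygosity, per-individual F_IS, exact rank-sum.

F_IS follows the vcftools ``--het`` method-of-moments estimator: for a focal
individual inside a reference group of n diploids,

    F = (O_hom - E_hom) / (n_sites - E_hom)

with ``E_hom = sum_sites [1 - 2 p (1-p) * 2n/(2n-1)]`` and p the group
non-reference allele frequency (focal individual included). Strongly negative
values indicate a genome-wide excess of observed heterozygosity, the clonal
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotypes import HET, MISSING, GenotypeMatrix


class HetStatsError(ValueError):
    pass


def individual_heterozygosity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Percentage of heterozygous genotypes per individual.

    Intended for matrices filtered with the heterozygosity recipe
    (depth-mask, complete, biallelic SNPs, monomorphic sites KEPT) so the
    denominator is identical for every individual.
    """
    used = (gm.calls != MISSING).sum(axis=0)
    if (used == 0).any():
        raise HetStatsError("individual with zero usable sites")
    n_het = (gm.calls == HET).sum(axis=0)
    return pd.DataFrame(
        {
            "individual": gm.individuals,
            "n_sites_used": used,
            "n_het": n_het,
            "pct_het": 100.0 * n_het / used,
        }
    )


def fis_per_individual(gm_group: GenotypeMatrix, focal: str) -> tuple[float, int]:
    """F_IS of ``focal`` within its (sub)population/lineage matrix.

    Sites monomorphic within the group are dropped (they carry no
    information), which is why the reported ``n_sites`` differs between
    groups. Raises when the group has a single individual: F_IS requires a
    (sub)population context.
    """
    if gm_group.n_individuals < 2:
        raise HetStatsError("F_IS requires a (sub)population context (>= 2 individuals)")
    if focal not in gm_group.individuals:
        raise HetStatsError(f"{focal!r} not in group {gm_group.individuals}")
    if (gm_group.calls == MISSING).any():
        raise HetStatsError("group matrix must be complete; filter first")
    dos = gm_group.calls.astype(np.int64)
    n = gm_group.n_individuals
    p = dos.sum(axis=1) / (2.0 * n)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise HetStatsError("no site polymorphic within the group; F_IS undefined")
    p = p[poly]
    e_hom = 1.0 - 2.0 * p * (1.0 - p) * (2 * n) / (2 * n - 1.0)
    j = gm_group.individuals.index(focal)
    o_hom = int((dos[poly, j] != 1).sum())
    n_sites = int(poly.sum())
    e_sum = float(e_hom.sum())
    if n_sites - e_sum <= 0:
        raise HetStatsError("degenerate group: expected homozygosity saturates")
    return (o_hom - e_sum) / (n_sites - e_sum), n_sites


def fis_table(groups: dict[str, GenotypeMatrix], refilter=None) -> pd.DataFrame:
    """F_IS for every individual of every group matrix.

    ``refilter`` optionally maps each group matrix through a filter callable
    (e.g. to re-apply completeness within the subset) before estimation.
    """
    rows = []
    for label, gm in groups.items():
        g = refilter(gm) if refilter is not None else gm
        for ind in g.individuals:
            f, n_sites = fis_per_individual(g, ind)
            rows.append((ind, label, f, n_sites))
    return pd.DataFrame(rows, columns=["individual", "group", "fis", "n_sites"])


@dataclass
class RankSumResult:
    w: float  # Mann-Whitney count of pairs (a, b) with a > b, ties 1/2
    p_value: float  # exact two-sided, by complete enumeration


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def rank_sum_exact(group_a, group_b) -> RankSumResult:
    """Exact Wilcoxon/Mann-Whitney two-sample test by complete enumeration.

    W counts pairs (a, b), a in ``group_a``, with a > b (ties contribute
    1/2). The p-value enumerates all C(nA+nB, nA) label assignments of the
    pooled values; the two-sided p doubles the smaller tail, capped at 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise HetStatsError("both groups must be non-empty")
    n_total = a.size + b.size
    if n_total > 25:
        raise HetStatsError("exact enumeration limited to <= 25 values")
    w_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    idx = range(n_total)
    n_le = n_ge = total = 0
    for pick in combinations(idx, a.size):
        mask = np.zeros(n_total, dtype=bool)
        mask[list(pick)] = True
        w = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if w <= w_obs + 1e-12:
            n_le += 1
        if w >= w_obs - 1e-12:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return RankSumResult(w=w_obs, p_value=min(p, 1.0))
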