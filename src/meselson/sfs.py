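"""Signature II (part 2): multi-individual SFS and shared-heterozygote excess.

The null model conditions on the observed non-reference allele count j at a
site: the j alternate and 2m-j reference alleles are assigned uniformly at
random into m diploid genotypes (exact finite-sample Hardy-Weinberg
conditioning). The probability of an ordered genotype configuration is then

    P(profile | j) = 2^{#het} / C(2m, j)

since each heterozygous individual can receive its two distinct alleles in
two orders. Fold-excess compares the observed frequency of a profile among
sites with the same j against this probability; values far above 1 for
"het in everyone" profiles indicate heterozygosity shared across populations,
the clonal expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix


class SfsError(ValueError):
    pass


def _dosages(gm: GenotypeMatrix) -> np.ndarray:
    if (gm.calls == MISSING).any():
        raise SfsError("matrix contains missing genotypes; filter first")
    return gm.calls.astype(np.int64)


def nonreference_sfs(gm: GenotypeMatrix) -> np.ndarray:
    """Counts of sites by total non-reference dosage j in 0..2m."""
    dos = _dosages(gm)
    j = dos.sum(axis=1)
    return np.bincount(j, minlength=2 * gm.n_individuals + 1)


def profile_probability_given_j(profile) -> float:
    """HWE-conditional probability of an ordered genotype configuration.

    ``profile`` is a sequence of genotype codes (0 hom-ref / 1 het /
    2 hom-alt) across the m individuals; conditioning is on j = total
    dosage of the profile.
    """
    profile = np.asarray(profile, dtype=int)
    if not np.isin(profile, [HOM_REF, HET, HOM_ALT]).all():
        raise SfsError("profile entries must be genotype codes 0/1/2")
    m = profile.size
    j = int(profile.sum())
    n_het = int((profile == HET).sum())
    return (2.0**n_het) / comb(2 * m, j)


@dataclass
class FoldExcess:
    profile: tuple
    j: int
    observed: int
    n_sites_with_j: int
    expected_probability: float
    fold: float | None  # None when no site carries the required j

    @property
    def expected_count(self) -> float:
        return self.n_sites_with_j * self.expected_probability


def fold_excess(gm: GenotypeMatrix, het_subset, elsewhere: int = HOM_REF) -> FoldExcess:
    """Observed/expected fold of the profile "het in ``het_subset``, ``elsewhere`` code otherwise".

    Restricted to sites whose total dosage matches the profile's j; the
    profile is evaluated as an exact (unordered within the subset, but the
    subset is fixed) genotype configuration.
    """
    if elsewhere not in (HOM_REF, HOM_ALT):
        raise SfsError("elsewhere must be hom-ref or hom-alt")
    het_idx = [gm.individuals.index(i) for i in het_subset]
    if not het_idx:
        raise SfsError("het_subset must name at least one individual")
    profile = np.full(gm.n_individuals, elsewhere, dtype=int)
    profile[het_idx] = HET
    j = int(profile.sum())
    dos = _dosages(gm)
    with_j = dos.sum(axis=1) == j
    observed = int(((dos == profile[None, :]).all(axis=1) & with_j).sum())
    n_j = int(with_j.sum())
    p = profile_probability_given_j(profile)
    fold = (observed / n_j) / p if n_j > 0 else None
    if n_j > 0 and observed == 0:
        fold = 0.0
    return FoldExcess(
        profile=tuple(profile),
        j=j,
        observed=observed,
        n_sites_with_j=n_j,
        expected_probability=p,
        fold=fold,
    )


def shared_het_branch_counts(
    gm: GenotypeMatrix, lineage_of: dict[str, str]
) -> dict[str, int]:
    """Counts of heterozygote-sharing site classes mapped onto lineage branches.

    A site is "shared_all" when every individual is het; "private_<L>" when
    all members of lineage L are het and no one else is. Sites where any
    individual is hom-alt are excluded from all classes (they are neither
    shared-het nor private-het configurations); classes are disjoint.
    """
    missing = [i for i in gm.individuals if i not in lineage_of]
    if missing:
        raise SfsError(f"lineage map does not cover {missing}")
    dos = _dosages(gm)
    clean = ~(dos == HOM_ALT).any(axis=1)
    het = dos == HET
    counts = {"shared_all": int((het.all(axis=1) & clean).sum())}
    lineages = sorted(set(lineage_of.values()))
    for lin in lineages:
        members = np.array([lineage_of[i] == lin for i in gm.individuals])
        private = het[:, members].all(axis=1) & ~het[:, ~members].any(axis=1)
        # exclude the all-individuals case when a lineage spans everyone
        if members.all():
            private &= np.zeros(len(private), bool)
        counts[f"private_{lin}"] = int((private & clean).sum())
    return counts


def sfs_report(gm: GenotypeMatrix, lineage_of: dict[str, str] | None = None) -> pd.DataFrame:
    """SFS table (j, count) with optional per-category breakdown columns."""
    sfs = nonreference_sfs(gm)
    df = pd.DataFrame({"j": np.arange(sfs.size), "count": sfs})
    if lineage_of is not None:
        counts = shared_het_branch_counts(gm, lineage_of)
        for name, c in counts.items():
            df.attrs[name] = c
    return df
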