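"""Hamming distances, classical MDS and hierarchical AMOVA."""

import itertools

import numpy as np
import pytest
from scipy.spatial import procrustes

from meselson.genotypes import HET, HOM_ALT, HOM_REF
from meselson.popstruct import (
    PopstructError,
    allele_hamming_distance,
    amova,
    amova_permutation_test,
    classical_mds,
    pseudo_haplotypes,
)
from skbio import DistanceMatrix

from conftest import make_matrix, make_metadata


class TestHammingDistance:
    def test_dosage_l1_against_pair_enumeration(self):
        # every genotype pair: |dosage difference| cross-checked by explicit
        # enumeration of the 9 ordered pairs
        for a, b in itertools.product([HOM_REF, HET, HOM_ALT], repeat=2):
            gm = make_matrix([[a, b]] * 5)
            d = allele_hamming_distance(gm)
            assert d["i0", "i1"] == 5 * abs(a - b)

    def test_identical_individuals_and_hom_extremes(self):
        gm = make_matrix([[HOM_REF, HOM_REF, HOM_ALT]] * 5)
        d = allele_hamming_distance(gm)
        assert d["i0", "i1"] == 0
        assert d["i0", "i2"] == 10  # 2 allele differences per site x 5 sites

    def test_missing_genotype_is_error(self):
        gm = make_matrix([[HET, -1]])
        with pytest.raises(PopstructError, match="filter"):
            allele_hamming_distance(gm)

    def test_normalized_variant(self):
        gm = make_matrix([[HOM_REF, HOM_ALT]] * 4)
        d = allele_hamming_distance(gm, normalize=True)
        assert d["i0", "i1"] == pytest.approx(2.0)


class TestClassicalMds:
    def test_equilateral_triangle(self):
        dm = DistanceMatrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=list("abc"))
        res = classical_mds(dm, dims=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_collinear_points_recovered(self):
        # 1-D points 0, 1, 3: second eigenvalue 0, distances recovered
        pts = np.array([0.0, 1.0, 3.0])
        dm = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]), ids=list("abc"))
        res = classical_mds(dm, dims=1)
        x = res.coordinates["MDS1"].to_numpy()
        got = np.abs(x[:, None] - x[None, :])
        assert np.allclose(got, dm.data, atol=1e-9)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_points_coincide(self):
        dm = DistanceMatrix(
            [[0, 0, 2], [0, 0, 2], [2, 2, 0]], ids=list("abc")
        )
        res = classical_mds(dm, dims=1)
        c = res.coordinates.to_numpy()
        assert np.allclose(c[0], c[1])

    def test_recovers_2d_configuration_up_to_rotation(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        res = classical_mds(DistanceMatrix(d, ids=[str(i) for i in range(8)]), dims=2)
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy())
        assert disparity < 1e-8


def amova_oracle(alleles, row_ind, pop_of):
    """Independent variance decomposition from coordinates (balanced design):
    classic nested ANOVA expected-mean-square equations on allele vectors."""
    alleles = np.asarray(alleles, float)
    inds = list(dict.fromkeys(row_ind))
    pops = sorted({pop_of[i] for i in inds})
    n_per_pop = len(inds) // len(pops)
    grand = alleles.mean(axis=0)
    ss_wi = ss_ai = ss_ap = 0.0
    for p in pops:
        rows_p = [k for k, r in enumerate(row_ind) if pop_of[r] == p]
        mean_p = alleles[rows_p].mean(axis=0)
        ss_ap += len(rows_p) * ((mean_p - grand) ** 2).sum()
        for i in [i for i in inds if pop_of[i] == p]:
            rows_i = [k for k, r in enumerate(row_ind) if r == i]
            mean_i = alleles[rows_i].mean(axis=0)
            ss_ai += 2 * ((mean_i - mean_p) ** 2).sum()
            ss_wi += ((alleles[rows_i] - mean_i) ** 2).sum()
    df_ap, df_ai, df_wi = len(pops) - 1, len(inds) - len(pops), len(inds)
    sig_w = ss_wi / df_wi
    sig_i = (ss_ai / df_ai - sig_w) / 2 if df_ai else 0.0
    sig_p = (ss_ap / df_ap - sig_w - 2 * sig_i) / (2 * n_per_pop)
    return sig_p, sig_i, sig_w


class TestAmova:
    def _run(self, calls, pops):
        gm = make_matrix(calls)
        alleles, labels, row_ind = pseudo_haplotypes(gm)
        d2 = np.abs(alleles[:, None, :] - alleles[None, :, :]).sum(axis=2).astype(float)
        pop_of = {f"i{k}": p for k, p in enumerate(pops)}
        return amova(d2, row_ind, pop_of), alleles, row_ind, pop_of

    def test_all_identical_rows_zero_components(self):
        res, *_ = self._run([[HET, HET, HET, HET]] * 3, ["a", "a", "b", "b"])
        # all het: the allele rows differ within individuals but every
        # individual is identical, so pop and ind components vanish
        assert res.percentages["within_individuals"] == pytest.approx(100.0)

    def test_fixed_difference_between_clonal_pops(self):
        res, alleles, row_ind, pop_of = self._run(
            [[HOM_REF, HOM_REF, HOM_ALT, HOM_ALT]] * 4, ["a", "a", "b", "b"]
        )
        assert res.percentages["among_populations"] == pytest.approx(100.0)
        oracle = amova_oracle(alleles, row_ind, pop_of)
        assert res.sigma2["among_populations"] == pytest.approx(oracle[0])

    def test_matches_anova_oracle_on_random_data(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(30, 6))
        res, alleles, row_ind, pop_of = self._run(
            calls, ["a", "a", "a", "b", "b", "b"]
        )
        sp, si, sw = amova_oracle(alleles, row_ind, pop_of)
        assert res.sigma2["within_individuals"] == pytest.approx(sw)
        # implementation truncates negatives; compare raw via SSD identity
        assert res.ssd["total"] == pytest.approx(
            res.ssd["among_populations"]
            + res.ssd["among_individuals"]
            + res.ssd["within_individuals"]
        )
        for got, exp in zip(
            [res.sigma2["among_populations"], res.sigma2["among_individuals"]],
            [sp, si],
        ):
            assert got == pytest.approx(max(exp, 0.0), abs=1e-9)

    def test_phase_invariance(self):
        # swapping the two allele rows of any individual leaves AMOVA unchanged
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(20, 4))
        gm = make_matrix(calls)
        alleles, _, row_ind = pseudo_haplotypes(gm)
        pop_of = {f"i{k}": p for k, p in enumerate(["a", "a", "b", "b"])}
        d2 = np.abs(alleles[:, None, :] - alleles[None, :, :]).sum(axis=2).astype(float)
        base = amova(d2, row_ind, pop_of)
        sw = alleles.copy()
        sw[[0, 1]] = sw[[1, 0]]  # swap i0's alleles
        d2s = np.abs(sw[:, None, :] - sw[None, :, :]).sum(axis=2).astype(float)
        swapped = amova(d2s, row_ind, pop_of)
        for k in base.sigma2:
            assert base.sigma2[k] == pytest.approx(swapped.sigma2[k])

    def test_single_population_is_error(self):
        with pytest.raises(PopstructError, match="2 populations"):
            self._run([[HET, HOM_REF]], ["a", "a"])


class TestPermutationTest:
    def test_perfect_separation_gives_minimal_p(self):
        gm = make_matrix(
            [[HOM_REF, HOM_REF, HOM_ALT, HOM_ALT]] * 6,
            individuals=["a1", "a2", "b1", "b2"],
        )
        meta = make_metadata({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        p, res = amova_permutation_test(gm, meta, n_perm=99, seed=1)
        # the observed component is maximal over permutations; only the 1/3
        # of permutations that reproduce the same partition tie with it
        assert p < 0.45
        assert res.percentages["among_populations"] == pytest.approx(100.0)

    def test_determinism(self, asex_dataset):
        from meselson.genotypes import filter_sites

        gm, _ = filter_sites(asex_dataset.genotypes)
        p1, _ = amova_permutation_test(gm, asex_dataset.metadata, n_perm=99, seed=7)
        p2, _ = amova_permutation_test(gm, asex_dataset.metadata, n_perm=99, seed=7)
        assert p1 == p2

    def test_n_perm_floor(self):
        gm = make_matrix([[HET, HOM_REF]], individuals=["a", "b"])
        meta = make_metadata({"a": "A", "b": "B"})
        with pytest.raises(PopstructError):
            amova_permutation_test(gm, meta, n_perm=10)
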