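"""Published per-individual reference values for the two *Oppiella* species.

These printed estimates (transcriptome-wide heterozygosity percentages and
within-group inbreeding coefficients of nine individuals per species from
three German forest sites) serve as reference inputs for worked examples and
for desk-scale reproduction of the study-level summary statistics. KF3 and
SA2 of the clonal *O. nova* are highly homozygous divergent singletons: no
F_IS can be estimated for them (no (sub)population context), and they are
excluded from Meselson-effect testing.
"""

from __future__ import annotations

# individual -> percent heterozygous sites (O. nova: 126,196 sites;
# O. subpectinata: 355,249 sites)
O_NOVA_PCT_HET = {
    "H1": 1.273, "H2": 1.285, "H3": 0.741,
    "KF1": 0.746, "KF2": 0.771, "KF3": 0.414,
    "SA1": 1.268, "SA2": 0.441, "SA3": 1.288,
}

O_SUBPECTINATA_PCT_HET = {
    "H1": 0.619, "H2": 0.665, "H3": 0.640,
    "KF1": 0.599, "KF2": 0.581, "KF3": 0.591,
    "SA1": 0.723, "SA2": 0.685, "SA3": 0.743,
}

#: individuals of the clonal species without Meselson-effect potential
O_NOVA_HOMOZYGOUS_SINGLETONS = ("KF3", "SA2")

# individual -> (F_IS, number of group-polymorphic sites); groups are the
# divergent lineages I/II for O. nova and the sampling locations for
# O. subpectinata
O_NOVA_FIS = {
    "H1": (-0.390, 5414), "H2": (-0.361, 5414), "H3": (-0.243, 3471),
    "KF1": (-0.246, 3471), "KF2": (-0.296, 3471),
    "SA1": (-0.361, 5414), "SA3": (-0.398, 5414),
}

O_SUBPECTINATA_FIS = {
    "H1": (0.015, 12730), "H2": (-0.034, 12730), "H3": (0.001, 12730),
    "KF1": (-0.006, 40145), "KF2": (0.023, 40145), "KF3": (0.002, 40145),
    "SA1": (-0.018, 10197), "SA2": (0.058, 10197), "SA3": (-0.019, 10197),
}

O_NOVA_LINEAGES = {
    "H1": "I", "H2": "I", "SA1": "I", "SA3": "I",
    "H3": "II", "KF1": "II", "KF2": "II",
}

# per-region topology-test outcomes (counts printed with the study's Fig. 4
# and text): testable regions, regions with Delta < 0, regions significantly
# better explained by the asex-tree, and phaseable-site totals
O_NOVA_REGION_COUNTS = {
    "testable_regions": 223,
    "delta_negative": 115,
    "asex_significant": 69,
    "asex_significant_sites": 37693,
    "phaseable_sites": 163418,
}

O_SUBPECTINATA_REGION_COUNTS = {
    "testable_regions": 268,
    "delta_negative": 6,
}

# parallel-divergence counts per O. nova lineage: (n haplotype-separating
# resolved trees, n with matching subtrees, individuals per subtree)
PARALLEL_DIVERGENCE_COUNTS = {
    "I": (31, 8, 4),
    "II": (55, 38, 3),
}
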