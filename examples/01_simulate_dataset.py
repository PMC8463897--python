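"""Generate a small clonal dataset with known truth and inspect it.

The clonal preset emulates a two-lineage asexual mite species sampled from
three forest sites: nine diploid individuals, two divergent lineages, two
heterozygosity-eroded singletons, phase blocks, coverage tracks and a
conspecific reference haplotype.
"""

from meselson import oppiella_like_config, simulate_dataset

cfg = oppiella_like_config("asexual", n_regions=6, region_length_bp=300, seed=1)
ds = simulate_dataset(cfg)

print(f"individuals      : {ds.genotypes.individuals}")
print(f"sites (all-sites): {ds.genotypes.n_sites}")
print(f"phase blocks     : {len(ds.blocks)}")
print(f"regions simulated: {len(ds.truth)}")
print(ds.metadata.table.to_string(index=False))
print()
print("First region's true genealogy (substitutions/site):")
print(ds.truth[0].genealogy[:120], "...")
# Every genotype in the all-sites VCF is derived from these true haplotype
# pairs, so each downstream stage can be checked against the truth bundle.
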