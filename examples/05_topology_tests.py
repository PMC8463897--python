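"""Signature III: per-region constrained-topology tests (Delta and AU).

Assembles phaseable regions from phase blocks, labels haplotypes A/B against
the reference, and compares each region's best ML tree with the fitted
asex-tree (haplotypes split at the base) and sex-tree (populations split,
haplotypes together).
"""

import warnings

from meselson import build_constraint_topology, delta_statistic
from meselson import oppiella_like_config, simulate_dataset
from meselson.phasing import build_regions, export_alignment, label_haplotypes, mask_low_coverage

warnings.simplefilter("ignore")
cfg = oppiella_like_config("asexual", n_regions=6, region_length_bp=400, seed=2)
ds = simulate_dataset(cfg)
members = set(cfg.lineage_of)

n_neg = n_test = 0
for region in build_regions(ds.blocks):
    region.haplotypes = {k: v for k, v in region.haplotypes.items() if k in members}
    if len(region.haplotypes) < 2:
        continue
    region = mask_low_coverage(region, ds.coverage, min_depth=10)
    if region is None:
        continue
    label_haplotypes(region, ds.reference)
    rows = export_alignment(region)
    parts = sorted(region.haplotypes)
    asex = build_constraint_topology("asex", parts, ds.metadata, "two-lineage")
    sex = build_constraint_topology("sex", parts, ds.metadata, "two-lineage")
    res = delta_statistic(rows, asex, sex, region=region.scaffold,
                          n_rell=1000, seed=9)
    if res.delta is None:
        print(f"{region.scaffold}: untestable (<4 unique sequences)")
        continue
    n_test += 1
    n_neg += res.delta < 0
    print(f"{region.scaffold}: Delta = {res.delta:+.4f}  category = {res.category}")

print(f"\n{n_neg}/{n_test} testable regions with Delta < 0")
# Negative Delta: the unconstrained ML tree resembles the haplotype-
# separating (clonal) topology more than the population topology.
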