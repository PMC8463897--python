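"""Four-signature Meselson-effect pipeline and verdict rules.

Runs, in dependency order over one dataset: (I) MDS + AMOVA with a
population permutation test; (II) heterozygosity, per-individual F_IS within
lineages/populations and shared-heterozygote fold-excess; (III) phaseable
region assembly and per-region constrained-topology tests (Delta statistic,
AU categories); (IV) parallel-divergence tests per lineage. Every verdict is
a documented threshold rule over the stored numbers, never a recomputation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from . import hetstats, paralleldiv, popstruct, sfs, treetests
from .genotypes import (
    GenotypeMatrix,
    SampleMetadata,
    filter_sites,
    partition_by_group,
    read_genotypes,
)
from .phasing import (
    CoverageTrack,
    build_regions,
    export_alignment,
    label_haplotypes,
    mask_low_coverage,
    paralog_flag,
    read_blocks_bed_fasta,
)
from .treemath import build_constraint_topology, root_at_leaf
from .treetests import alignment_distance_matrix, nj_tree, nni_search
from .likelihood import encode_alignment

ASEX_CATEGORIES = ("unconst=asex>sex", "asex>sex")


@dataclass
class PipelineConfig:
    min_depth: int = 10
    parallel_min_depth: int = 5  # relaxed mask for signature IV trees
    group_level: str = "lineage"  # F_IS / constraint grouping level
    species_template: str = "two-lineage"  # or "single-species"
    most_divergent_population: str | None = None
    n_perm: int = 199
    n_rell: int = 2000
    alpha: float = 0.05
    min_overlap: int = 100
    paralog_ratio_threshold: float = 1.5
    parallel_p_threshold: float = 1e-3
    seed: int = 0


@dataclass
class SignatureReport:
    config: PipelineConfig
    amova: popstruct.AmovaResult | None = None
    mds: popstruct.MdsResult | None = None
    het_table: pd.DataFrame | None = None
    fis_table: pd.DataFrame | None = None
    fold_excess: dict = field(default_factory=dict)
    shared_het: dict = field(default_factory=dict)
    region_results: list = field(default_factory=list)
    n_regions: int = 0
    n_paralog_flagged: int = 0
    fraction_delta_negative: float | None = None
    category_counts: dict = field(default_factory=dict)
    asex_significant_site_fraction: float | None = None
    parallel: dict = field(default_factory=dict)
    verdicts: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "verdicts": self.verdicts,
            "signature_I": {
                "percent_variance": self.amova.percentages if self.amova else None,
                "p_population": self.amova.p_population if self.amova else None,
            },
            "signature_II": {
                "mean_pct_het": (
                    float(self.het_table["pct_het"].mean())
                    if self.het_table is not None
                    else None
                ),
                "mean_fis": (
                    float(self.fis_table["fis"].mean())
                    if self.fis_table is not None
                    else None
                ),
                "fold_excess": {
                    k: (v.fold, v.observed, v.n_sites_with_j)
                    for k, v in self.fold_excess.items()
                },
                "shared_het": self.shared_het,
            },
            "signature_III": {
                "n_regions": self.n_regions,
                "n_paralog_flagged": self.n_paralog_flagged,
                "fraction_delta_negative": self.fraction_delta_negative,
                "category_counts": self.category_counts,
                "asex_significant_site_fraction": self.asex_significant_site_fraction,
            },
            "signature_IV": {
                lin: {
                    "n_resolved": r.n_resolved,
                    "n_separating": r.n_separating,
                    "n_matching": r.n_matching,
                    "x_null": r.x_null,
                    "p_value": r.p_value,
                }
                for lin, r in self.parallel.items()
            },
            "details": self.details,
        }
        return out

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1, default=float)
        if path is not None:
            Path(path).write_text(s)
        return s

    def to_text(self) -> str:
        lines = ["Meselson-effect signature report", "=" * 34]
        for sig, v in self.verdicts.items():
            lines.append(f"{sig}: {v}")
        if self.amova:
            pct = self.amova.percentages
            lines.append(
                f"I : variance % pop/ind/within-ind = "
                f"{pct['among_populations']:.1f}/{pct['among_individuals']:.1f}/"
                f"{pct['within_individuals']:.1f}; P_pop = {self.amova.p_population}"
            )
        if self.fis_table is not None:
            lines.append(f"II: mean F_IS = {self.fis_table['fis'].mean():.3f}")
        for k, v in self.fold_excess.items():
            lines.append(f"II: fold-excess {k}: {v.fold if v.fold is not None else 'NA'}")
        if self.fraction_delta_negative is not None:
            lines.append(
                f"III: {100 * self.fraction_delta_negative:.1f}% of "
                f"{sum(self.category_counts.values())} testable regions with Delta < 0; "
                f"categories {self.category_counts}"
            )
        for lin, r in self.parallel.items():
            lines.append(
                f"IV: lineage {lin}: {r.n_matching}/{r.n_separating} matching "
                f"(x = {r.x_null:.3f}, P = {r.p_value})"
            )
        return "\n".join(lines)


@dataclass
class Dataset:
    """The five inputs of a run, already loaded in memory."""

    genotypes: GenotypeMatrix
    metadata: SampleMetadata
    blocks: list
    coverage: dict[str, CoverageTrack]
    genome_coverage: CoverageTrack | None
    reference: dict[str, str]


def load_dataset(directory) -> Dataset:
    """Load a dataset from the on-disk layout written by ``emit_dataset``."""
    from Bio import SeqIO

    d = Path(directory)
    reference = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(d / "reference.fa"), "fasta")
    }
    lengths = {sc: len(seq) for sc, seq in reference.items()}
    gm = read_genotypes(d / "allsites.vcf")
    meta = SampleMetadata.from_tsv(d / "metadata.tsv")
    blocks = []
    coverage = {}
    for ind in meta.individuals:
        bed = d / "blocks" / f"{ind}.bed"
        if bed.exists():
            blocks += read_blocks_bed_fasta(bed, d / "blocks" / f"{ind}.fa", ind)
        cov = d / "coverage" / f"{ind}.bedGraph"
        if cov.exists():
            coverage[ind] = CoverageTrack.from_bedgraph(cov, lengths)
    gc_path = d / "genome_coverage.bedGraph"
    genome_cov = CoverageTrack.from_bedgraph(gc_path, lengths) if gc_path.exists() else None
    return Dataset(gm, meta, blocks, coverage, genome_cov, reference)


def dataset_from_simulation(sim) -> Dataset:
    return Dataset(
        genotypes=sim.genotypes,
        metadata=sim.metadata,
        blocks=sim.blocks,
        coverage=sim.coverage,
        genome_coverage=sim.genome_coverage,
        reference=sim.reference,
    )


def _included_individuals(ds: Dataset, config: PipelineConfig) -> list[str]:
    """Individuals entering signatures II-IV: those with a label at the
    grouping level (lineage-less singletons are excluded, mirroring the
    restriction to individuals that can show the effect)."""
    if config.species_template == "single-species":
        return list(ds.genotypes.individuals)
    out = []
    for ind in ds.genotypes.individuals:
        lab = ds.metadata.lineage(ind)
        if not (pd.isna(lab) or lab == ""):
            out.append(ind)
    return out


def _signature_one(ds, config, report):
    gm, _ = filter_sites(ds.genotypes, min_depth=config.min_depth)
    if gm.n_sites == 0:
        report.verdicts["I"] = "untestable"
        return
    dm = popstruct.allele_hamming_distance(gm)
    report.mds = popstruct.classical_mds(dm)
    p, res = popstruct.amova_permutation_test(
        gm, ds.metadata, n_perm=config.n_perm, seed=config.seed
    )
    report.amova = res
    pct = res.percentages
    report.verdicts["I"] = (
        "yes"
        if pct["within_individuals"] > pct["among_populations"]
        else "no"
    )


def _signature_two(ds, config, report):
    gm_het, _ = filter_sites(ds.genotypes, min_depth=config.min_depth,
                             drop_monomorphic=False)
    report.het_table = hetstats.individual_heterozygosity(gm_het)

    level = config.group_level if config.species_template == "two-lineage" else "population"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        groups = partition_by_group(ds.genotypes, ds.metadata, level)

    def refilter(g):
        out, _ = filter_sites(g, min_depth=config.min_depth)
        return out

    try:
        report.fis_table = hetstats.fis_table(groups, refilter=refilter)
    except hetstats.HetStatsError as exc:
        report.verdicts["II"] = "untestable"
        report.details["II_error"] = str(exc)
        return

    included = _included_individuals(ds, config)
    gm_inc, _ = filter_sites(ds.genotypes.subset_individuals(included),
                             min_depth=config.min_depth)
    report.fold_excess["all_het"] = sfs.fold_excess(gm_inc, included)
    if config.species_template == "two-lineage":
        lineage_of = {i: str(ds.metadata.lineage(i)) for i in included}
        report.shared_het = sfs.shared_het_branch_counts(gm_inc, lineage_of)
        for lin in sorted(set(lineage_of.values())):
            members = [i for i in included if lineage_of[i] == lin]
            report.fold_excess[f"private_{lin}"] = sfs.fold_excess(gm_inc, members)

    fis = report.fis_table["fis"].to_numpy()
    n_neg = int((fis < 0).sum())
    sign_p = binomtest(n_neg, len(fis), 0.5, alternative="greater").pvalue
    fold = report.fold_excess["all_het"].fold
    report.details["II_sign_test_p"] = float(sign_p)
    report.verdicts["II"] = (
        "yes"
        if (fis.mean() < 0 and sign_p < config.alpha and fold is not None and fold > 1)
        else "no"
    )


def _prepare_regions(ds, config, included, min_depth):
    regions = []
    built = build_regions(ds.blocks, min_overlap=config.min_overlap)
    baseline = None
    if ds.genome_coverage is not None:
        allcov = np.concatenate(list(ds.genome_coverage.depths.values()))
        baseline = float(np.median(allcov))
    for region in built:
        region.haplotypes = {
            k: v for k, v in region.haplotypes.items() if k in included
        }
        if len(region.haplotypes) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            masked = mask_low_coverage(region, ds.coverage, min_depth=min_depth)
        if masked is None:
            continue
        label_haplotypes(masked, ds.reference)
        if ds.genome_coverage is not None and baseline:
            paralog_flag(
                masked, ds.genome_coverage, baseline,
                ratio_threshold=config.paralog_ratio_threshold,
            )
        regions.append(masked)
    return regions


def _signature_three(ds, config, report):
    included = _included_individuals(ds, config)
    regions = _prepare_regions(ds, config, included, config.min_depth)
    report.n_paralog_flagged = sum(r.paralog for r in regions)
    regions = [r for r in regions if not r.paralog]
    report.n_regions = len(regions)

    # theoretically phaseable sites: coverage >= min_depth in all included
    idx = [ds.genotypes.individuals.index(i) for i in included]
    phaseable = int((ds.genotypes.depth[:, idx] >= config.min_depth).all(axis=1).sum())
    report.details["n_phaseable_sites"] = phaseable

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(regions))]
    results = []
    sig_sites = 0
    for region, seed in zip(regions, seeds):
        rows = export_alignment(region)
        participants = sorted(region.haplotypes)
        try:
            asex = build_constraint_topology(
                "asex", participants, ds.metadata, config.species_template,
                config.most_divergent_population,
            )
            sex = build_constraint_topology(
                "sex", participants, ds.metadata, config.species_template,
                config.most_divergent_population,
            )
        except Exception as exc:  # missing labels
            report.details.setdefault("III_skipped", []).append(
                f"{region.scaffold}:{region.start}: {exc}"
            )
            continue
        res = treetests.delta_statistic(
            rows, asex, sex, region=f"{region.scaffold}:{region.start}-{region.end}",
            n_rell=config.n_rell, seed=seed, alpha=config.alpha,
        )
        if res.category in ASEX_CATEGORIES:
            sig_sites += region.length
        results.append(res)
    report.region_results = results
    testable = [r for r in results if r.delta is not None]
    counts = {}
    for r in results:
        counts[r.category] = counts.get(r.category, 0) + 1
    report.category_counts = counts
    if testable:
        report.fraction_delta_negative = float(
            np.mean([r.delta < 0 for r in testable])
        )
    report.asex_significant_site_fraction = (
        sig_sites / phaseable if phaseable else None
    )
    if not testable:
        report.verdicts["III"] = "untestable"
        return
    # directional excess among significant regions: asex-favoring vs
    # sex-favoring counts compared by a sign test, which stays calibrated
    # even when the per-region test's false-positive rate drifts from alpha
    # (a single chance hit must never flip the verdict)
    k_asex = sum(r.category in ASEX_CATEGORIES for r in results)
    k_sex = sum(r.category in ("sex>asex", "unconst=sex>asex") for r in results)
    if k_asex + k_sex > 0:
        excess_p = binomtest(
            k_asex, k_asex + k_sex, 0.5, alternative="greater"
        ).pvalue
    else:
        excess_p = 1.0
    report.details["III_asex_excess_p"] = float(excess_p)
    report.verdicts["III"] = (
        "yes"
        if (report.fraction_delta_negative > 0.5 or excess_p < config.alpha)
        else "no"
    )


def _signature_four(ds, config, report):
    if config.species_template != "two-lineage":
        report.verdicts["IV"] = "untestable"
        report.details["IV_note"] = "parallel divergence is tested within lineages"
        return
    included = _included_individuals(ds, config)
    regions = _prepare_regions(ds, config, included, config.parallel_min_depth)
    regions = [r for r in regions if not r.paralog]
    lineage_of = {i: str(ds.metadata.lineage(i)) for i in included}
    verdict = "no"
    for lin in sorted(set(lineage_of.values())):
        members = sorted(i for i in included if lineage_of[i] == lin)
        if len(members) < 2:
            continue
        trees = []
        for region in regions:
            if not set(members) <= set(region.haplotypes):
                continue
            rows = [
                (n, s) for n, s in export_alignment(region) if n[:-2] in members
            ]
            if len({s for _, s in rows}) < 3:
                continue
            try:
                dm = alignment_distance_matrix(rows)
                start = root_at_leaf(nj_tree(dm))
            except treetests.TopologyTestError:
                continue
            enc = encode_alignment(rows)
            best, _, _ = nni_search(start, enc)
            trees.append(best)
        if not trees:
            continue
        res = paralleldiv.parallel_divergence_test(trees)
        report.parallel[lin] = res
        if res.p_value is not None and res.p_value < config.parallel_p_threshold:
            verdict = "yes"
    if not report.parallel:
        verdict = "untestable"
    report.verdicts["IV"] = verdict


def run_pipeline(ds: Dataset, config: PipelineConfig | None = None) -> SignatureReport:
    """Run all four signatures on a dataset and return the aggregated report."""
    config = config or PipelineConfig()
    report = SignatureReport(config=config)
    _signature_one(ds, config, report)
    _signature_two(ds, config, report)
    _signature_three(ds, config, report)
    _signature_four(ds, config, report)
    return report
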