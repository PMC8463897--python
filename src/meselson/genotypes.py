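"""All-sites diploid genotype matrices: VCF I/O, site filters, group partitioning.

Genotype calls are stored as small integer codes per (site, individual):
``HOM_REF=0``, ``HET=1``, ``HOM_ALT=2``, ``MISSING=-1``, together with the
per-genotype read depth. Internal coordinates are 0-based half-open; VCF I/O
is 1-based as per the format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

#: fixed order in which site filters are applied; removal counts attribute
#: each dropped site to the first failing predicate in this order
FILTER_ORDER = ("indel", "multiallelic", "incomplete", "monomorphic")


class GenotypeError(ValueError):
    pass


@dataclass
class SampleMetadata:
    """Individual -> (population, lineage) assignments.

    ``lineage`` may be missing (pd.NA) for individuals that do not belong to
    a recognized lineage, e.g. divergent singletons.
    """

    table: pd.DataFrame  # columns: individual, population, lineage

    def __post_init__(self):
        required = {"individual", "population"}
        if not required.issubset(self.table.columns):
            raise GenotypeError(f"metadata needs columns {sorted(required)}")
        if "lineage" not in self.table.columns:
            self.table = self.table.assign(lineage=pd.NA)
        if self.table["individual"].duplicated().any():
            raise GenotypeError("duplicate individual in metadata")
        self.table = self.table.set_index("individual", drop=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def population(self, individual: str) -> str:
        return self.table.loc[individual, "population"]

    def lineage(self, individual: str):
        return self.table.loc[individual, "lineage"]

    def label(self, individual: str, level: str):
        if level not in ("population", "lineage"):
            raise GenotypeError(f"unknown grouping level {level!r}")
        return self.table.loc[individual, level]

    @property
    def individuals(self) -> list[str]:
        return list(self.table["individual"])


@dataclass
class GenotypeMatrix:
    """Sites x individuals diploid genotype calls with per-genotype depth."""

    sites: pd.DataFrame  # scaffold, pos (0-based), ref, alt (comma str), is_indel, n_alleles
    individuals: list[str]
    calls: np.ndarray  # int8, (n_sites, n_individuals)
    depth: np.ndarray  # int32, same shape

    def __post_init__(self):
        if self.calls.shape != self.depth.shape:
            raise GenotypeError("calls and depth shapes differ")
        if self.calls.shape != (len(self.sites), len(self.individuals)):
            raise GenotypeError("matrix shape inconsistent with sites/individuals")
        if len(set(self.individuals)) != len(self.individuals):
            raise GenotypeError("duplicate individual identifiers")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def subset_individuals(self, names: list[str]) -> "GenotypeMatrix":
        missing = [n for n in names if n not in self.individuals]
        if missing:
            raise GenotypeError(
                f"individuals {missing} not in matrix; available: {self.individuals}"
            )
        idx = [self.individuals.index(n) for n in names]
        return GenotypeMatrix(
            sites=self.sites.copy(),
            individuals=list(names),
            calls=self.calls[:, idx].copy(),
            depth=self.depth[:, idx].copy(),
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            individuals=list(self.individuals),
            calls=self.calls[mask],
            depth=self.depth[mask],
        )

    def is_complete(self) -> bool:
        return bool((self.calls != MISSING).all())


def _classify_gt(gt: tuple) -> int:
    alleles = [a for a in gt if a is not None]
    if len(alleles) < 2:
        return MISSING
    a, b = alleles[0], alleles[1]
    if a != b:
        return HET
    return HOM_REF if a == 0 else HOM_ALT


def _is_snp(ref: str, alts: tuple[str, ...]) -> bool:
    if len(ref) != 1:
        return False
    return all(len(a) == 1 and a in "ACGTacgt" for a in alts)


def read_genotypes(vcf_path, sample_subset=None) -> GenotypeMatrix:
    """Read an all-sites VCF (FORMAT GT and DP) into a :class:`GenotypeMatrix`.

    Multi-allelic records are retained (``n_alleles`` recorded) so downstream
    filters can drop them; genotypes are MISSING when GT is ``./.``. Phase
    separators in GT are ignored: haplotype phase is taken only from the
    dedicated phase-block inputs, never from the VCF.
    """
    vf = pysam.VariantFile(str(vcf_path))
    available = list(vf.header.samples)
    if sample_subset is None:
        samples = available
    else:
        absent = [s for s in sample_subset if s not in available]
        if absent:
            raise GenotypeError(
                f"samples {absent} not in VCF; available samples: {available}"
            )
        samples = list(sample_subset)

    rows = []
    calls = []
    depths = []
    for rec in vf:
        alts = tuple(a for a in (rec.alts or ()) if a != "<NON_REF>")
        n_alleles = 1 + len(alts)
        is_indel = bool(alts) and not _is_snp(rec.ref, alts)
        rows.append(
            (rec.chrom, rec.pos - 1, rec.ref, ",".join(alts), is_indel, n_alleles)
        )
        crow = np.empty(len(samples), dtype=np.int8)
        drow = np.empty(len(samples), dtype=np.int32)
        for j, s in enumerate(samples):
            sd = rec.samples[s]
            crow[j] = _classify_gt(sd.get("GT") or ())
            dp = sd.get("DP")
            drow[j] = 0 if dp is None else int(dp)
        calls.append(crow)
        depths.append(drow)
    vf.close()

    sites = pd.DataFrame(
        rows, columns=["scaffold", "pos", "ref", "alt", "is_indel", "n_alleles"]
    )
    gm = GenotypeMatrix(
        sites=sites,
        individuals=samples,
        calls=np.array(calls, dtype=np.int8).reshape(len(rows), len(samples)),
        depth=np.array(depths, dtype=np.int32).reshape(len(rows), len(samples)),
    )
    order = np.lexsort((gm.sites["pos"].to_numpy(), gm.sites["scaffold"].to_numpy()))
    if not np.array_equal(order, np.arange(len(order))):
        gm = GenotypeMatrix(
            sites=gm.sites.iloc[order].reset_index(drop=True),
            individuals=gm.individuals,
            calls=gm.calls[order],
            depth=gm.depth[order],
        )
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Re-emit a genotype matrix as VCF 4.2 (GT and DP)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for sc in pd.unique(gm.sites["scaffold"]):
        header.add_line(f"##contig=<ID={sc}>")
    for ind in gm.individuals:
        header.add_sample(ind)
    gt_map = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, row in gm.sites.iterrows():
            alts = tuple(a for a in row["alt"].split(",") if a)
            rec = out.new_record(
                contig=row["scaffold"],
                start=int(row["pos"]),
                alleles=(row["ref"],) + (alts if alts else (".",)),
            )
            for j, ind in enumerate(gm.individuals):
                call = int(gm.calls[i, j])
                if call == HET and len(alts) == 0:
                    raise GenotypeError("het call at site without ALT allele")
                rec.samples[ind]["GT"] = gt_map[call]
                rec.samples[ind]["DP"] = int(gm.depth[i, j])
            out.write(rec)


@dataclass
class FilterReport:
    """Per-filter removal counts; sites attribute to the first failing filter."""

    n_input: int
    n_output: int
    genotypes_depth_masked: int
    removed: dict = field(default_factory=dict)

    def __post_init__(self):
        assert self.n_input == self.n_output + sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input_sites", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows += [
            ("output_sites", self.n_output),
            ("genotypes_depth_masked", self.genotypes_depth_masked),
        ]
        return pd.DataFrame(rows, columns=["quantity", "count"])


def filter_sites(
    gm: GenotypeMatrix,
    min_depth: int = 10,
    require_complete: bool = True,
    biallelic_snps_only: bool = True,
    drop_monomorphic: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the standard site filters in a fixed order.

    Order: depth-mask genotypes (< ``min_depth`` set to MISSING), then drop
    indel sites, then >biallelic sites, then sites with any missing genotype,
    then monomorphic sites. "Monomorphic" means every non-missing call is
    hom-ref (an all-hom-alt site is a variant relative to the reference and
    is kept); sites with no non-missing call at all also count as monomorphic.
    """
    if min_depth < 0:
        raise GenotypeError("min_depth must be >= 0")
    calls = gm.calls.copy()
    masked = (gm.depth < min_depth) & (calls != MISSING)
    calls[masked] = MISSING

    keep = np.ones(gm.n_sites, dtype=bool)
    removed = {}
    preds = {
        "indel": gm.sites["is_indel"].to_numpy(dtype=bool)
        if biallelic_snps_only
        else np.zeros(gm.n_sites, bool),
        "multiallelic": (gm.sites["n_alleles"].to_numpy() > 2)
        if biallelic_snps_only
        else np.zeros(gm.n_sites, bool),
        "incomplete": (calls == MISSING).any(axis=1)
        if require_complete
        else np.zeros(gm.n_sites, bool),
        "monomorphic": ((calls == HOM_REF) | (calls == MISSING)).all(axis=1)
        if drop_monomorphic
        else np.zeros(gm.n_sites, bool),
    }
    for name in FILTER_ORDER:
        fails = preds[name] & keep
        removed[name] = int(fails.sum())
        keep &= ~fails

    out = GenotypeMatrix(
        sites=gm.sites.loc[keep].reset_index(drop=True),
        individuals=list(gm.individuals),
        calls=calls[keep],
        depth=gm.depth[keep].copy(),
    )
    if out.n_sites == 0:
        warnings.warn("all sites removed by filtering", stacklevel=2)
    report = FilterReport(
        n_input=gm.n_sites,
        n_output=out.n_sites,
        genotypes_depth_masked=int(masked.sum()),
        removed=removed,
    )
    return out, report


def partition_by_group(
    gm: GenotypeMatrix, metadata: SampleMetadata, level: str = "population"
) -> dict[str, GenotypeMatrix]:
    """Split a matrix into per-population or per-lineage sub-matrices.

    Individuals without a label at the requested level are dropped with a
    warning (e.g. divergent singletons lacking a lineage).
    """
    groups: dict[str, list[str]] = {}
    dropped = []
    for ind in gm.individuals:
        if ind not in metadata.table.index:
            dropped.append(ind)
            continue
        lab = metadata.label(ind, level)
        if pd.isna(lab) or lab == "":
            dropped.append(ind)
            continue
        groups.setdefault(str(lab), []).append(ind)
    if not groups:
        raise GenotypeError(f"no individual carries a {level} label")
    if dropped:
        warnings.warn(
            f"{len(dropped)} individual(s) without {level} label dropped: {dropped}",
            stacklevel=2,
        )
    return {lab: gm.subset_individuals(inds) for lab, inds in sorted(groups.items())}
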