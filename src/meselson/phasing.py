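"""Signature III preprocessing: phaseable regions from per-individual phase blocks.

Read-backed phasing yields, per individual, blocks over which the two
haplotype sequences are resolved. Blocks of different individuals that
overlap by at least 100 bp are chained into maximal "phaseable regions"
(union span); a region needs at least two participating individuals and a
span of at least 100 bp. Within a region each individual contributes two
alignment rows, masked with N outside its own blocks and wherever its read
depth falls below the masking threshold. Haplotypes are labeled A (closer to
the reference) and B (more diverged); regions with roughly doubled read
coverage are flagged as candidate paralogs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

DNA = set("ACGT")


class PhasingError(ValueError):
    pass


@dataclass
class PhaseBlock:
    """One individual's phased interval (0-based half-open) with two haplotypes."""

    individual: str
    scaffold: str
    start: int
    end: int
    hap1: str
    hap2: str

    def __post_init__(self):
        if self.end - self.start < 1:
            raise PhasingError("phase block must span at least one base")
        if len(self.hap1) != self.end - self.start or len(self.hap2) != len(self.hap1):
            raise PhasingError(
                f"haplotype lengths must equal the block span for "
                f"{self.individual} {self.scaffold}:{self.start}-{self.end} "
                "(blocks whose haplotypes differ in length are rejected)"
            )
        self.hap1 = self.hap1.upper()
        self.hap2 = self.hap2.upper()

    @property
    def length(self) -> int:
        return self.end - self.start


class CoverageTrack:
    """Per-base integer read depth per scaffold."""

    def __init__(self, depths: dict[str, np.ndarray]):
        for sc, arr in depths.items():
            if (np.asarray(arr) < 0).any():
                raise PhasingError(f"negative depth on {sc}")
        self.depths = {sc: np.asarray(a, dtype=np.int64) for sc, a in depths.items()}

    @classmethod
    def from_bedgraph(cls, path, scaffold_lengths: dict[str, int]) -> "CoverageTrack":
        df = pd.read_csv(
            path, sep="\t", comment="t", header=None,
            names=["scaffold", "start", "end", "depth"],
            dtype={"scaffold": str},
        )
        depths = {sc: np.zeros(n, dtype=np.int64) for sc, n in scaffold_lengths.items()}
        for row in df.itertuples(index=False):
            if row.scaffold in depths:
                depths[row.scaffold][int(row.start): int(row.end)] = int(row.depth)
        return cls(depths)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for sc in sorted(self.depths):
                arr = self.depths[sc]
                # run-length encode
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(arr)]])
                for s, e in zip(starts, ends):
                    fh.write(f"{sc}\t{s}\t{e}\t{arr[s]}\n")

    def depth(self, scaffold: str, start: int, end: int) -> np.ndarray:
        if scaffold not in self.depths:
            raise PhasingError(f"no coverage for scaffold {scaffold}")
        arr = self.depths[scaffold]
        if end > len(arr):
            raise PhasingError(f"coverage track shorter than {scaffold}:{end}")
        return arr[start:end]


@dataclass
class PhasedRegion:
    """A chained cross-individual phaseable region with a 2-rows-per-individual alignment."""

    scaffold: str
    start: int
    end: int
    haplotypes: dict[str, tuple[str, str]]  # individual -> (hap1, hap2) over [start, end)
    labels: dict[str, tuple[int, int]] = field(default_factory=dict)  # ind -> (A index, B index)
    label_ties: list[str] = field(default_factory=list)
    paralog: bool = False
    coverage_ratio: float | None = None
    median_coverage: float | None = None

    def __post_init__(self):
        if self.length < 100:
            raise PhasingError("phaseable region must span >= 100 bp")
        if len(self.haplotypes) < 2:
            raise PhasingError("phaseable region needs >= 2 participating individuals")
        for ind, (h1, h2) in self.haplotypes.items():
            if len(h1) != self.length or len(h2) != self.length:
                raise PhasingError(f"alignment row length mismatch for {ind}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def participants(self) -> list[str]:
        return sorted(self.haplotypes)

    def alignment(self) -> list[tuple[str, str]]:
        """Deterministic (name, sequence) rows: individual sort, A before B.

        Falls back to hap1/hap2 order (suffixes _A/_B still) when the region
        has not been labeled yet.
        """
        rows = []
        for ind in self.participants:
            h = self.haplotypes[ind]
            ia, ib = self.labels.get(ind, (0, 1))
            rows.append((f"{ind}_A", h[ia]))
            rows.append((f"{ind}_B", h[ib]))
        return rows


def read_blocks_bed_fasta(bed_path, fasta_path, individual: str) -> list[PhaseBlock]:
    """Read one individual's phase blocks from a BED + FASTA pair.

    BED columns: scaffold, start, end, block_id (0-based half-open). The
    FASTA holds two records per block named ``<block_id>/1`` and
    ``<block_id>/2``.
    """
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["scaffold", "start", "end", "block_id"], dtype={"scaffold": str},
    )
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    blocks = []
    for row in bed.itertuples(index=False):
        try:
            h1 = seqs[f"{row.block_id}/1"]
            h2 = seqs[f"{row.block_id}/2"]
        except KeyError as exc:
            raise PhasingError(f"missing haplotype record for block {row.block_id}") from exc
        blocks.append(
            PhaseBlock(individual, row.scaffold, int(row.start), int(row.end), h1, h2)
        )
    return blocks


def write_blocks_bed_fasta(blocks: list[PhaseBlock], bed_path, fasta_path) -> None:
    with open(bed_path, "w") as bed, open(fasta_path, "w") as fa:
        for k, b in enumerate(blocks):
            bid = f"block{k:05d}"
            bed.write(f"{b.scaffold}\t{b.start}\t{b.end}\t{bid}\n")
            fa.write(f">{bid}/1\n{b.hap1}\n>{bid}/2\n{b.hap2}\n")


def read_blocks_phased_vcf(
    vcf_path, reference: dict[str, str], individual: str, min_span: int = 1
) -> list[PhaseBlock]:
    """Derive phase blocks from a phased VCF using PS (phase set) tags.

    Heterozygous phased SNVs sharing a PS value form one block; the block
    interval runs from the first to one past the last phased site and the
    haplotype sequences are the reference with the phased alleles
    substituted.
    """
    import pysam

    vf = pysam.VariantFile(str(vcf_path))
    if individual not in list(vf.header.samples):
        raise PhasingError(f"{individual} not in phased VCF")
    per_ps: dict[tuple[str, object], list] = {}
    for rec in vf:
        sd = rec.samples[individual]
        gt = sd.get("GT")
        if gt is None or None in gt or not sd.phased:
            continue
        if gt[0] == gt[1]:
            continue
        ps = sd.get("PS")
        if ps is None:
            continue
        alleles = rec.alleles
        a1, a2 = alleles[gt[0]], alleles[gt[1]]
        if len(a1) != 1 or len(a2) != 1:
            continue  # SNVs only
        per_ps.setdefault((rec.chrom, ps), []).append((rec.pos - 1, a1, a2))
    vf.close()
    blocks = []
    for (scaffold, _ps), sites in sorted(per_ps.items()):
        sites.sort()
        start, end = sites[0][0], sites[-1][0] + 1
        if end - start < min_span:
            continue
        ref = reference[scaffold][start:end]
        h1, h2 = list(ref), list(ref)
        for pos, a1, a2 in sites:
            h1[pos - start] = a1
            h2[pos - start] = a2
        blocks.append(PhaseBlock(individual, scaffold, start, end, "".join(h1), "".join(h2)))
    return blocks


def _check_no_self_overlap(blocks: list[PhaseBlock]) -> None:
    by_ind: dict[tuple[str, str], list[PhaseBlock]] = {}
    for b in blocks:
        by_ind.setdefault((b.individual, b.scaffold), []).append(b)
    for (ind, sc), bs in by_ind.items():
        bs = sorted(bs, key=lambda b: b.start)
        for prev, cur in zip(bs, bs[1:]):
            if cur.start < prev.end:
                raise PhasingError(
                    f"overlapping phase blocks of the same individual {ind} on {sc} "
                    f"([{prev.start},{prev.end}) vs [{cur.start},{cur.end})): "
                    "phasing inconsistency"
                )


def build_regions(
    blocks: list[PhaseBlock],
    min_overlap: int = 100,
    min_individuals: int = 2,
    min_region_len: int = 100,
) -> list[PhasedRegion]:
    """Chain cross-individual phase blocks into maximal phaseable regions.

    Two blocks are linked when they belong to different individuals and
    overlap by at least ``min_overlap`` bp; a region is the union span of a
    connected component of links. Components with fewer than
    ``min_individuals`` participants or spanning less than ``min_region_len``
    are discarded. Per-individual bases outside that individual's own blocks
    are masked with N. Output is independent of block input order.
    """
    _check_no_self_overlap(blocks)
    regions = []
    by_scaffold: dict[str, list[PhaseBlock]] = {}
    for b in blocks:
        by_scaffold.setdefault(b.scaffold, []).append(b)

    for scaffold in sorted(by_scaffold):
        bs = sorted(by_scaffold[scaffold], key=lambda b: (b.start, b.end, b.individual))
        n = len(bs)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        for i in range(n):
            for j in range(i + 1, n):
                if bs[j].start >= bs[i].end:
                    break
                if bs[i].individual == bs[j].individual:
                    continue
                overlap = min(bs[i].end, bs[j].end) - bs[j].start
                if overlap >= min_overlap:
                    union(i, j)

        comps: dict[int, list[PhaseBlock]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(bs[i])
        for comp in comps.values():
            inds = {b.individual for b in comp}
            start = min(b.start for b in comp)
            end = max(b.end for b in comp)
            if len(inds) < min_individuals or end - start < min_region_len:
                continue
            haplotypes = {}
            for ind in sorted(inds):
                h1 = np.full(end - start, "N", dtype="U1")
                h2 = np.full(end - start, "N", dtype="U1")
                for b in comp:
                    if b.individual != ind:
                        continue
                    s, e = b.start - start, b.end - start
                    h1[s:e] = list(b.hap1)
                    h2[s:e] = list(b.hap2)
                haplotypes[ind] = ("".join(h1), "".join(h2))
            regions.append(PhasedRegion(scaffold, start, end, haplotypes))
    regions.sort(key=lambda r: (r.scaffold, r.start))
    return regions


def mask_low_coverage(
    region: PhasedRegion,
    coverage: dict[str, CoverageTrack],
    min_depth: int = 10,
) -> PhasedRegion | None:
    """Mask both haplotype rows of an individual with N where its depth < ``min_depth``.

    Individuals masked over their whole row are removed; returns None when
    the region no longer satisfies the >= 2 participants rule.
    """
    new_haps = {}
    for ind, (h1, h2) in region.haplotypes.items():
        if ind not in coverage:
            raise PhasingError(f"no coverage track for {ind}")
        d = coverage[ind].depth(region.scaffold, region.start, region.end)
        low = d < min_depth
        if low.all() or all(c == "N" for c in h1):
            continue
        a1, a2 = np.array(list(h1)), np.array(list(h2))
        a1[low] = "N"
        a2[low] = "N"
        if (a1 == "N").all():
            continue
        new_haps[ind] = ("".join(a1), "".join(a2))
    if len(new_haps) < 2:
        warnings.warn(
            f"region {region.scaffold}:{region.start}-{region.end} lost too many "
            "participants after coverage masking",
            stacklevel=2,
        )
        return None
    return PhasedRegion(region.scaffold, region.start, region.end, new_haps)


def label_haplotypes(region: PhasedRegion, reference: dict[str, str]) -> PhasedRegion:
    """Label each individual's haplotypes: A closer to the reference, B more diverged.

    Mismatches are counted only over columns where both the haplotype and the
    reference are unambiguous nucleotides. Ties break lexicographically
    (smaller sequence becomes A) and are flagged in ``label_ties``.
    """
    ref = reference[region.scaffold][region.start: region.end].upper()
    if len(ref) != region.length:
        raise PhasingError("reference does not cover the region")
    labels, ties = {}, []
    for ind, (h1, h2) in region.haplotypes.items():
        d = []
        for h in (h1, h2):
            d.append(
                sum(
                    1
                    for hc, rc in zip(h, ref)
                    if hc in DNA and rc in DNA and hc != rc
                )
            )
        if d[0] < d[1]:
            labels[ind] = (0, 1)
        elif d[1] < d[0]:
            labels[ind] = (1, 0)
        else:
            labels[ind] = (0, 1) if h1 <= h2 else (1, 0)
            ties.append(ind)
    region.labels = labels
    region.label_ties = ties
    return region


def paralog_flag(
    region: PhasedRegion,
    genome_read_coverage: CoverageTrack,
    singlecopy_baseline_median: float,
    ratio_threshold: float = 1.5,
) -> tuple[bool, float]:
    """Flag a region as a candidate paralog by doubled read coverage.

    True duplicates are expected at about twice the single-copy coverage;
    the region is flagged when median(region coverage) / baseline >= the
    threshold (default 1.5, midway between the single-copy and duplicate
    coverage classes).
    """
    if singlecopy_baseline_median <= 0:
        raise PhasingError("baseline median must be > 0")
    d = genome_read_coverage.depth(region.scaffold, region.start, region.end)
    if d.size == 0:
        raise PhasingError("empty coverage over region")
    med = float(np.median(d))
    ratio = med / singlecopy_baseline_median
    region.paralog = ratio >= ratio_threshold
    region.coverage_ratio = ratio
    region.median_coverage = med
    return region.paralog, ratio


def export_alignment(region: PhasedRegion, path=None) -> list[tuple[str, str]]:
    """Alignment rows named ``<individual>_<A|B>``; optionally written as FASTA."""
    rows = region.alignment()
    if path is not None:
        with open(path, "w") as fh:
            for name, seq in rows:
                fh.write(f">{name}\n{seq}\n")
    return rows


def phased_site_fraction(regions: list[PhasedRegion], n_phaseable_sites: int) -> float:
    """Fraction of theoretically phaseable sites covered by emitted regions."""
    spanned = sum(r.length for r in regions)
    return spanned / n_phaseable_sites if n_phaseable_sites else float("nan")
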