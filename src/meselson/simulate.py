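"""Synthetic clonal and sexual diploid datasets with known truth.

The generator emulates the statistical structure of a multi-population
transcriptome-resequencing study of a clonal species and its sexual
relative: ~9 individuals in 3 populations, two divergent clonal lineages
plus highly homozygous singletons, per-site heterozygosity around 0.5-1.5%,
read-backed phase blocks of a few hundred bp, coverage of order 100x with
occasional double-coverage (paralogous) regions.

Clonal (asexual) mode builds, per region, a genealogy in which the two
haplotypes of every individual split at the deepest node (depth ``t_hap``)
and each haplotype clade repeats the same lineage -> population -> tip
history — parallel divergence by construction. Sexual mode draws Kingman
coalescent genealogies within populations joined by a population split tree
(via msprime), so haplotype divergence follows population divergence.
Heterozygosity erosion by gene conversion / loss-of-heterozygosity is
modeled as random homogenization tracts.

All times are expressed directly in expected substitutions per site; an
extra reference individual ("REF", excluded from the emitted sample) donates
one haplotype as the reference sequence, mirroring a conspecific reference
assembly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genotypes import GenotypeMatrix, SampleMetadata
from .phasing import CoverageTrack, PhaseBlock
from .treemath import to_newick

BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    mode: str = "asexual"  # asexual | sexual
    population_names: tuple = ("H", "KF", "SA")
    individuals_per_population: int = 3
    # individual -> lineage label; individuals absent from the map are
    # lineage-less singletons (their haplotypes still split at t_hap)
    lineage_of: dict = field(default_factory=dict)
    # divergence times, expected substitutions/site
    t_hap: float = 0.007
    t_lin: float = 0.0038
    t_pop: float = 0.0028
    t_tip: float = 0.0002
    het_target: float = 0.0065  # sexual mode within-population diversity
    # lognormal sigma of the per-region substitution-rate multiplier
    # (mean 1); transcriptome loci differ strongly in evolutionary rate
    rate_heterogeneity_sigma: float = 1.0
    n_regions: int = 40
    region_length_bp: int = 500
    loh_rate: float = 0.0
    loh_rate_of: dict = field(default_factory=dict)  # per-individual override
    loh_tract_mean_bp: float = 200.0
    coverage_mean: float = 100.0
    low_coverage_rate: float = 0.02
    low_coverage_window_bp: float = 100.0
    paralog_fraction: float = 0.0
    phase_block_mean_bp: float = 450.0
    phase_dropout: float = 0.1
    reference_population: str = "KF"
    reference_lineage: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("asexual", "sexual"):
            raise SimulationError("mode must be 'asexual' or 'sexual'")
        for name, v in (("t_hap", self.t_hap), ("t_lin", self.t_lin),
                        ("t_pop", self.t_pop), ("t_tip", self.t_tip)):
            if v < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.mode == "asexual" and not (
            self.t_hap >= self.t_lin >= self.t_pop >= self.t_tip
        ):
            raise SimulationError(
                "divergence times must be nested: t_hap >= t_lin >= t_pop >= t_tip"
            )
        if self.region_length_bp < 100:
            raise SimulationError("region_length_bp must be >= 100")
        for p in (self.loh_rate, self.paralog_fraction, self.phase_dropout,
                  self.low_coverage_rate):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("probabilities must lie in [0, 1]")

    @property
    def individuals(self) -> list[str]:
        return [
            f"{pop}{i + 1}"
            for pop in self.population_names
            for i in range(self.individuals_per_population)
        ]

    def population(self, ind: str) -> str:
        if ind == "REF":
            return self.reference_population
        for pop in sorted(self.population_names, key=len, reverse=True):
            if ind.startswith(pop):
                return pop
        raise SimulationError(f"cannot place {ind} in a population")

    def metadata(self) -> SampleMetadata:
        rows = [
            (ind, self.population(ind), self.lineage_of.get(ind, pd.NA))
            for ind in self.individuals
        ]
        return SampleMetadata(
            pd.DataFrame(rows, columns=["individual", "population", "lineage"])
        )


def oppiella_like_config(mode: str = "asexual", **overrides) -> SimConfig:
    """Preset emulating the study structure: 3 populations x 3 individuals.

    In clonal mode, lineage I spans populations H and SA (4 individuals),
    lineage II spans H and KF (3), and KF3/SA2 are lineage-less singletons
    whose heterozygosity has been eroded by strong loss of heterozygosity.
    Time defaults target heterozygosity around 1.4% for lineage members of
    the clonal species (~0.5% for the eroded singletons) and ~0.65% for the
    sexual species.
    """
    if mode == "asexual":
        cfg = dict(
            mode="asexual",
            lineage_of={
                "H1": "I", "H2": "I", "SA1": "I", "SA3": "I",
                "H3": "II", "KF1": "II", "KF2": "II",
            },
            loh_rate_of={"KF3": 0.92, "SA2": 0.92},
            t_hap=0.007, t_lin=0.0038, t_pop=0.0028, t_tip=0.0002,
            reference_lineage="II",
        )
    else:
        cfg = dict(mode="sexual", het_target=0.0065, t_pop=0.004)
    cfg.update(overrides)
    return SimConfig(**cfg)


# ------------------------------------------------------------- genealogies


def _merge_single(children: list[tuple[TreeNode, float]], depth_top: float):
    """Attach children (node, its depth) under a new node at depth_top."""
    node = TreeNode(length=None)
    for child, depth in children:
        child.length = depth_top - depth
        if child.length < 0:
            raise SimulationError("inconsistent divergence times")
        node.append(child)
    return node


def _asexual_hap_clade(config: SimConfig, individuals: list[str], suffix: str):
    """One haplotype clade: lineages -> populations -> individual tips."""
    lineages: dict[str, list[str]] = {}
    for ind in individuals:
        if ind == "REF" and config.reference_lineage is not None:
            lin = config.reference_lineage
        else:
            lin = config.lineage_of.get(ind, f"singleton:{ind}")
        lineages.setdefault(lin, []).append(ind)
    lin_nodes = []
    for lin in sorted(lineages):
        members = lineages[lin]
        pop_nodes = []
        for pop in sorted({config.population(i) for i in members}):
            inds = sorted(i for i in members if config.population(i) == pop)
            tips = [(TreeNode(name=f"{i}_{suffix}"), 0.0) for i in inds]
            if len(tips) == 1:
                pop_nodes.append(tips[0])
            else:
                pop_nodes.append((_merge_single(tips, config.t_tip), config.t_tip))
        if len(pop_nodes) == 1:
            lin_nodes.append(pop_nodes[0])
        else:
            lin_nodes.append((_merge_single(pop_nodes, config.t_pop), config.t_pop))
    if len(lin_nodes) == 1:
        node, depth = lin_nodes[0]
    else:
        node, depth = _merge_single(lin_nodes, config.t_lin), config.t_lin
    return node, depth


def simulate_genealogy(config: SimConfig, region_index: int) -> TreeNode:
    """True haplotype genealogy of one region; tips ``<ind>_h1``/``<ind>_h2``.

    Clonal mode: deterministic nested template, both haplotype clades
    identical in shape. Sexual mode: msprime coalescent under a population
    split demography scaled so within-population diversity matches
    ``het_target`` (genealogies vary by region).
    """
    individuals = config.individuals + ["REF"]
    if config.mode == "asexual":
        c1, d1 = _asexual_hap_clade(config, individuals, "h1")
        c2, d2 = _asexual_hap_clade(config, individuals, "h2")
        root = _merge_single([(c1, d1), (c2, d2)], config.t_hap)
        return root
    return _sexual_genealogy(config, region_index)


def _sexual_genealogy(config: SimConfig, region_index: int) -> TreeNode:
    import msprime

    ne = config.het_target / 4.0  # 4 Ne mu = pi with mu = 1 per unit time
    demography = msprime.Demography()
    for pop in config.population_names:
        demography.add_population(name=pop, initial_size=ne)
    demography.add_population(name="ANC", initial_size=ne)
    demography.add_population_split(
        time=config.t_pop, derived=list(config.population_names), ancestral="ANC"
    )
    samples = []
    names = []
    for ind in config.individuals + ["REF"]:
        pop = config.population(ind) if ind != "REF" else config.reference_population
        samples.append(msprime.SampleSet(1, population=pop, ploidy=2))
        names.append(ind)
    seed = (config.seed * 100003 + region_index * 7919 + 1) % (2**31 - 1) + 1
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=1,
        ploidy=2,
        random_seed=seed,
    )
    tree = ts.first()
    node_name = {}
    for k, ind_id in enumerate(ts.individuals()):
        for h, node in enumerate(ind_id.nodes):
            node_name[node] = f"{names[k]}_h{h + 1}"

    def build(u):
        kids = tree.children(u)
        if not kids:
            node = TreeNode(name=node_name[u])
        else:
            node = TreeNode()
            for v in kids:
                node.append(build(v))
        node.length = tree.branch_length(u) if tree.parent(u) != -1 else None
        return node

    return build(tree.root)


# --------------------------------------------------------- sequence evolution


def evolve_sequences(
    genealogy: TreeNode, region_length: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """JC69 sequence evolution along a genealogy (branch lengths in subst/site).

    The root sequence is uniform over {A,C,G,T}; each branch applies the
    exact JC69 transition kernel site-independently. Returns integer-coded
    sequences (0..3) for every tip.
    """
    root_seq = rng.integers(0, 4, size=region_length, dtype=np.int8)
    out: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray):
        for child in node.children:
            t = child.length or 0.0
            child_seq = seq
            if t > 0:
                stay = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
                change = rng.random(region_length) >= stay
                if change.any():
                    child_seq = seq.copy()
                    shift = rng.integers(1, 4, size=int(change.sum()), dtype=np.int8)
                    child_seq[change] = (child_seq[change] + shift) % 4
            if child.children:
                descend(child, child_seq)
            else:
                out[child.name] = child_seq.copy() if child_seq is seq else child_seq
        return

    descend(genealogy, root_seq)
    if genealogy.name is not None and not genealogy.children:
        out[genealogy.name] = root_seq
    return out


def apply_loh(
    hap1: np.ndarray,
    hap2: np.ndarray,
    loh_rate: float,
    tract_mean: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int]]]:
    """Homogenization tracts: within each tract one haplotype overwrites the other.

    Tracts have geometric lengths (mean ``tract_mean``) seeded uniformly, at
    a density such that the expected fraction of sites covered is
    ``loh_rate``; the donor haplotype is chosen at random per tract. Returns
    the modified pair and a (start, end, donor) tract log.
    """
    if len(hap1) != len(hap2):
        raise SimulationError("haplotype lengths differ")
    h1, h2 = hap1.copy(), hap2.copy()
    n = len(h1)
    if loh_rate <= 0:
        return h1, h2, []
    n_tracts = rng.poisson(n * loh_rate / tract_mean)
    log = []
    for _ in range(n_tracts):
        start = int(rng.integers(0, n))
        length = int(rng.geometric(1.0 / tract_mean))
        end = min(n, start + length)
        donor = int(rng.integers(0, 2))
        if donor == 0:
            h2[start:end] = h1[start:end]
        else:
            h1[start:end] = h2[start:end]
        log.append((start, end, donor))
    return h1, h2, log


# ---------------------------------------------------------------- dataset


@dataclass
class RegionTruth:
    name: str
    genealogy: str  # newick
    paralog: bool
    haplotypes: dict  # ind -> (h1, h2) strings
    block_orientation: dict  # (ind, block start) -> 0/1 (0: emitted order = truth)


@dataclass
class SimulatedDataset:
    config: SimConfig
    metadata: SampleMetadata
    reference: dict[str, str]
    genotypes: GenotypeMatrix
    blocks: list[PhaseBlock]
    coverage: dict[str, CoverageTrack]
    genome_coverage: CoverageTrack
    truth: list[RegionTruth]

    @property
    def region_names(self) -> list[str]:
        return [t.name for t in self.truth]


def _decode(seq: np.ndarray) -> str:
    return "".join(BASES[seq])


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full in-memory dataset (genotypes, blocks, coverage, truth).

    One scaffold per region; deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    inds = config.individuals
    L = config.region_length_bp
    n_regions = config.n_regions

    paralog = rng.random(n_regions) < config.paralog_fraction

    site_rows = []
    call_rows = []
    depth_rows = []
    truths = []
    blocks: list[PhaseBlock] = []
    cov_arrays: dict[str, dict[str, np.ndarray]] = {ind: {} for ind in inds}
    genome_cov: dict[str, np.ndarray] = {}
    reference: dict[str, str] = {}

    for r in range(n_regions):
        scaffold = f"region{r:04d}"
        tree = simulate_genealogy(config, r)
        if config.rate_heterogeneity_sigma > 0:
            sig = config.rate_heterogeneity_sigma
            rate = float(rng.lognormal(-0.5 * sig**2, sig))
            for node in tree.traverse(include_self=False):
                if node.length is not None:
                    node.length *= rate
        seqs = evolve_sequences(tree, L, rng)
        haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for ind in inds + ["REF"]:
            h1, h2 = seqs[f"{ind}_h1"], seqs[f"{ind}_h2"]
            rate = config.loh_rate_of.get(ind, config.loh_rate)
            if ind != "REF" and rate > 0:
                h1, h2, _ = apply_loh(
                    h1, h2, rate, config.loh_tract_mean_bp, rng
                )
            haps[ind] = (h1, h2)
        ref_seq = haps["REF"][0]
        reference[scaffold] = _decode(ref_seq)

        # per-individual sequencing depth with dropout windows
        depth = {}
        for ind in inds:
            d = rng.poisson(config.coverage_mean, size=L)
            n_win = rng.poisson(L * config.low_coverage_rate / config.low_coverage_window_bp)
            for _ in range(n_win):
                s = int(rng.integers(0, L))
                w = int(rng.geometric(1.0 / config.low_coverage_window_bp))
                d[s: s + w] = rng.poisson(config.coverage_mean * 0.05, size=len(d[s: s + w]))
            depth[ind] = d
            cov_arrays[ind][scaffold] = d
        factor = 2.0 if paralog[r] else 1.0
        genome_cov[scaffold] = rng.poisson(config.coverage_mean * factor, size=L)

        # genotypes relative to the reference haplotype
        for pos in range(L):
            ref_base = int(ref_seq[pos])
            alleles = [ref_base]
            gts = []
            for ind in inds:
                b1, b2 = int(haps[ind][0][pos]), int(haps[ind][1][pos])
                for b in (b1, b2):
                    if b not in alleles:
                        alleles.append(b)
                gts.append((b1, b2))
            alts = alleles[1:]
            site_rows.append(
                (
                    scaffold,
                    pos,
                    BASES[ref_base],
                    ",".join(BASES[a] for a in alts),
                    False,
                    1 + len(alts),
                )
            )
            crow = np.empty(len(inds), dtype=np.int8)
            drow = np.empty(len(inds), dtype=np.int32)
            for j, (b1, b2) in enumerate(gts):
                if b1 != b2:
                    crow[j] = 1
                elif b1 == ref_base:
                    crow[j] = 0
                else:
                    crow[j] = 2
                drow[j] = depth[inds[j]][pos]
            call_rows.append(crow)
            depth_rows.append(drow)

        # phase blocks with dropout and random orientation
        orientation = {}
        for ind in inds:
            pos0 = 0
            while pos0 < L - 1:
                blen = max(60, int(rng.geometric(1.0 / config.phase_block_mean_bp)))
                end = min(L, pos0 + blen)
                if end - pos0 >= 60 and rng.random() >= config.phase_dropout:
                    flip = int(rng.integers(0, 2))
                    h1, h2 = haps[ind]
                    pair = (h1[pos0:end], h2[pos0:end])
                    if flip:
                        pair = (pair[1], pair[0])
                    blocks.append(
                        PhaseBlock(
                            ind, scaffold, pos0, end,
                            _decode(pair[0]), _decode(pair[1]),
                        )
                    )
                    orientation[f"{ind}:{pos0}"] = flip
                pos0 = end

        truths.append(
            RegionTruth(
                name=scaffold,
                genealogy=to_newick(tree),
                paralog=bool(paralog[r]),
                haplotypes={
                    ind: (_decode(haps[ind][0]), _decode(haps[ind][1]))
                    for ind in inds
                },
                block_orientation=orientation,
            )
        )

    sites = pd.DataFrame(
        site_rows, columns=["scaffold", "pos", "ref", "alt", "is_indel", "n_alleles"]
    )
    gm = GenotypeMatrix(
        sites=sites,
        individuals=list(inds),
        calls=np.vstack(call_rows),
        depth=np.vstack(depth_rows),
    )
    coverage = {ind: CoverageTrack(tracks) for ind, tracks in cov_arrays.items()}
    return SimulatedDataset(
        config=config,
        metadata=config.metadata(),
        reference=reference,
        genotypes=gm,
        blocks=blocks,
        coverage=coverage,
        genome_coverage=CoverageTrack(genome_cov),
        truth=truths,
    )


def emit_dataset(config: SimConfig, outdir) -> SimulatedDataset:
    """Simulate and write the dataset in the formats the pipeline consumes.

    Layout: reference.fa, allsites.vcf, metadata.tsv, blocks/<ind>.{bed,fa},
    coverage/<ind>.bedGraph, genome_coverage.bedGraph, truth/*.json(+.nwk).
    """
    from .genotypes import write_vcf
    from .phasing import write_blocks_bed_fasta

    ds = simulate_dataset(config)
    out = Path(outdir)
    (out / "blocks").mkdir(parents=True, exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    with open(out / "reference.fa", "w") as fh:
        for sc in sorted(ds.reference):
            fh.write(f">{sc}\n{ds.reference[sc]}\n")
    write_vcf(ds.genotypes, out / "allsites.vcf")
    ds.metadata.to_tsv(out / "metadata.tsv")
    for ind in config.individuals:
        mine = [b for b in ds.blocks if b.individual == ind]
        write_blocks_bed_fasta(mine, out / "blocks" / f"{ind}.bed", out / "blocks" / f"{ind}.fa")
        ds.coverage[ind].to_bedgraph(out / "coverage" / f"{ind}.bedGraph")
    ds.genome_coverage.to_bedgraph(out / "genome_coverage.bedGraph")
    for t in ds.truth:
        with open(out / "truth" / f"{t.name}.json", "w") as fh:
            json.dump(
                {
                    "name": t.name,
                    "genealogy": t.genealogy,
                    "paralog": t.paralog,
                    "haplotypes": t.haplotypes,
                    "block_orientation": t.block_orientation,
                },
                fh,
                indent=1,
            )
    with open(out / "sim_config.json", "w") as fh:
        json.dump(asdict(ds.config), fh, indent=1, default=str)
    return ds
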