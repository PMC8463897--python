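# Methods

`meselson` tests multi-individual diploid polymorphism data for the four
population-genomic signatures of long-term clonal (asexual) evolution — the
Meselson effect — and ships a generator of synthetic clonal and sexual
datasets with known truth so that every stage of the pipeline can be
validated without external data.

## The four signatures and how they are computed

**I. Within-individual divergence exceeds between-population divergence.**
Genotypes pass the standard site filters (per-genotype depth ≥ 10 set to
missing, then indels, >biallelic sites, sites with any missing genotype and
monomorphic sites removed — in that fixed order, so removal counts are
well-defined). "Monomorphic" means every non-missing call is homozygous
reference; an all-hom-alt site is a variant relative to the reference and is
kept. Individuals are ordinated by classical (Torgerson) MDS of the raw
allele-sharing Hamming distance d(i,j) = Σ|dosage_i − dosage_j| (equal to
the identity-by-state mismatch count for biallelic diploid genotypes; a
strict genotype-mismatch variant is available behind a flag). Variance is
partitioned by a three-level AMOVA over pseudo-haplotypes: each genotype is
split into two binary allele rows (the within-site assignment is arbitrary —
all AMOVA quantities are phase-invariant because every cross-row allele pair
enters the sums; asserted by test). The Hamming count between binary allele
rows *is* the squared Euclidean distance, so it enters the Excoffier-style
sums of squares directly. Method-of-moments variance components use the
general unbalanced-design coefficients (which reduce to 2 and 2I_p for two
rows per individual); negative components are truncated to zero and flagged
before percentages. The population component is tested by permuting whole
individuals (both allele rows together) across populations, with the add-one
p-value estimator p = (1 + #{σ²_perm ≥ σ²_obs})/(n_perm + 1). Ties from
permutations that reproduce the observed partition are counted, so a
perfectly differentiated toy dataset yields p ≈ (1 + #ties)/(n_perm + 1),
not 1/(n_perm + 1).

**II. Heterozygosity excess.** Per-individual heterozygosity is the
percentage of heterozygous genotypes among all retained sites (monomorphic
sites kept for this recipe, so all individuals share one denominator).
F_IS follows the vcftools `--het` method-of-moments estimator inside a
reference group (lineage for the clonal species, population for the sexual
one): F = (O_hom − E_hom)/(n − E_hom) with E_hom = Σ[1 − 2p(1−p)·2n/(2n−1)],
p the group non-reference allele frequency including the focal individual.
Sites monomorphic within the group are dropped (they carry no information),
which is why reported site counts differ between groups. Group comparisons
use an exact Mann–Whitney test: W counts pairs (a > b) with mid-rank ties,
and the two-sided p doubles the smaller tail over complete enumeration of
all C(nA+nB, nA) label assignments (limited to ≤ 25 values total).

The shared-heterozygote excess conditions on the observed non-reference
allele count j at a site: assigning the j alternate and 2m − j reference
alleles uniformly at random into m diploid genotypes gives
P(profile | j) = 2^{#het}/C(2m, j) for an ordered genotype configuration
(validated against complete enumeration for m ≤ 4). Fold-excess is the
observed frequency of a profile among sites with the same j divided by this
probability. This finite-sample conditioning is exact at any m and
sidesteps allele-frequency estimation noise; it is a fixed, documented
convention that may differ in detail from tools that condition on an
estimated continuous frequency. Sites where any individual is homozygous
alternate are excluded from the three shared-het categories (het in all;
het private to each lineage) but retained in the SFS.

**III. Haplotype-separating topologies.** Per-individual phase blocks
(read-backed phasing output, consumed as BED + FASTA pairs or as a phased
VCF with PS tags) are chained into *phaseable regions*: maximal unions of
blocks linked by cross-individual overlaps of ≥ 100 bp, requiring ≥ 2
participants and ≥ 100 bp span. Region span is the union of the chained
blocks; each individual is masked with N outside its own blocks and wherever
its per-base depth falls below the masking threshold (10; 5 for the
signature-IV rerun). Haplotypes are labeled A (fewer mismatches to the
reference over unambiguous columns) and B (more diverged); ties break
lexicographically and are flagged. Candidate paralogs — regions whose median
genomic read coverage is ≥ 1.5× the single-copy baseline — are excluded
(true duplicates sit near 2×; 1.5 splits the two coverage classes; the
threshold is configurable).

For each region, the unconstrained tree is fitted by neighbor joining on
JC69 pairwise distances (pairwise deletion of ambiguous columns) followed by
NNI hill-climbing; constrained trees resolve the asex/sex constraint
polytomies deterministically and restrict NNI moves to those preserving
every constraint bipartition. The likelihood engine is Felsenstein pruning
under JC69 on pattern-compressed alignments; branch lengths are optimized
coordinate-wise — the single-edge log-likelihood is concave in e^{−4t/3}, so
each edge is solved by safeguarded Newton — with a per-sweep exact-recompute
fallback that keeps the log-likelihood trace non-decreasing (asserted by
test). The model is fixed to JC69: at the ~1% divergences of within-species
haplotype data, model choice is immaterial, and a closed-form engine can be
oracle-checked end to end. Δ = d(best, asex-tree) − d(best, sex-tree), with
d the Kuhner–Felsenstein branch-score distance (square root of summed
squared branch-length differences over the union of bipartitions, external
edges included; bipartitions absent from one tree contribute zero length;
cross-checked against dendropy on random trees).

Tree comparisons use the approximately unbiased (AU) test on RELL-resampled
per-site log-likelihoods: at scales r ∈ {0.5, …, 1.4}, ⌈rL⌉ sites are drawn
with replacement (multinomial weights; no refitting); the bootstrap
proportions are mapped through the normal quantile and fitted by weighted
least squares to z(σ) = d/σ + cσ with σ = 1/√r (the signed distance grows
with the square root of the resample size; the curvature term shrinks),
giving p_AU = 1 − Φ(d − c). Degenerate cases (all proportions 0 or 1) give
p = 0/1 with a flag; identical per-site log-likelihood vectors make a region
untestable, as do regions with fewer than four unique aligned sequences.
Calibration: over 200 alignments simulated on the generating topology, the
AU test rejects that topology at α = 0.05 in ≤ 7.5% of regions (asserted).
Regions are classified into the five topology categories (unconst = asex >
sex; asex > sex; no difference; sex > asex; unconst = sex > asex) by the
pairwise p-values at α = 0.05, evaluated most-clonal-first.

**IV. Parallel divergence.** Trees are rebuilt from regions masked at the
relaxed depth 5 within each clonal lineage. A tree is *resolved* when, after
collapsing internal branches shorter than ε = 10⁻⁶ substitutions/site, the
unrooted topology is fully binary; *haplotype-separating* when some edge
bipartitions all A from all B leaves; and shows *parallel divergence* when
the two rooted subtrees at that edge are topologically identical after
stripping the A/B suffixes (exact leaf-labeled isomorphism via canonical
forms; branch lengths ignored). Matching counts are tested against the
uniform-topology null x = 1/(2k − 3)!! with an exact binomial upper tail in
rational arithmetic.

**Verdicts** are explicit threshold rules over stored stage outputs, all
configurable: I — within-individual % exceeds among-population % (the
permutation p is reported alongside); II — mean F_IS negative with a
one-sided sign test at α and all-het fold-excess > 1; III — the majority of
testable regions have Δ < 0, or the count of asex-significant regions
exceeds the α-level false-positive expectation (binomial test; a single
chance hit among many regions must not flip the verdict); IV — binomial
p < 10⁻³ in at least one lineage.

## The synthetic-data generator

The generator emulates the statistical structure of a two-species
transcriptome study: three populations (H, KF, SA) × three diploid
individuals, all-sites VCF with per-genotype depths, per-individual phase
blocks (mean 450 bp, 10% dropout, random per-block phase orientation),
per-base coverage tracks (Poisson around 100×, with occasional low-coverage
dropout windows), a fraction of regions emitted at doubled genomic coverage
(paralog mimics), and an extra "REF" individual — excluded from the sample —
whose first haplotype is the reference sequence, mirroring a conspecific
reference assembly. One scaffold per region; all times directly in expected
substitutions/site (no mutation-rate calendar dating is attempted, as none
is available for these taxa).

*Clonal mode* builds a deterministic genealogy template per region: the two
haplotypes of every individual split at depth `t_hap` (0.007), and each
haplotype clade repeats the same lineage (`t_lin` = 0.0038) → population
(`t_pop` = 0.0028) → tip (`t_tip` = 0.0002) history — parallel divergence by
construction. The preset assigns lineage I to {H1, H2, SA1, SA3}, lineage II
to {H3, KF1, KF2}, and makes KF3/SA2 lineage-less singletons with strong
loss of heterozygosity (rate 0.92), reproducing the structure of a clonal
species with eroded sublineages. LOH/gene conversion is modeled
phenomenologically as homogenization tracts: Poisson-seeded, geometric
lengths (mean 200 bp), random donor haplotype per tract; with seeding
intensity ρ the expected untouched fraction is e^{−ρ} (tract overlap), so
realized heterozygosity retention is checked against that expectation rather
than 1 − ρ. The cytological mechanism (e.g. inverted meiosis) is not modeled
mechanistically. *Sexual mode* draws, per region, a Kingman coalescent
genealogy under a three-population split demography via msprime, scaled so
within-population diversity matches `het_target` (0.0065) with the split at
0.004; haplotype divergence then follows population divergence. Sequences
evolve along either genealogy by the exact JC69 kernel from a uniform root
sequence. Per-region substitution rates are lognormal (σ = 1, mean 1),
reflecting the orders-of-magnitude rate variation among transcriptome loci —
without it, essentially no region carries enough within-lineage signal to
yield a resolved tree, whereas the real study found resolved trees in a
minority of its 281 regions.

Two preset choices deserve note. Clonal lineage-member heterozygosity lands
near 1.4%, slightly above the 0.4–1.3% envelope of the motivating data: the
A/B labeling margin per region scales with (t_hap − t_lin) × region length,
and at 500 bp regions a smaller haplotype split makes labels too noisy for
the separation analysis that the study performed on longer effective
regions. Second, signature IV is run at 100 regions in the acceptance
script while the other stages use 40–60: the binomial tail over resolved,
separating, matching trees simply cannot reach p < 10⁻³ from the handful of
resolved trees a 40-region dataset yields (the motivating study used 281
regions for the same reason). These sizes are the package's choices of
problem scale.

What passing tests on synthetic data do *not* show: the generator has no
sequencing/genotyping error (the depth filter is exercised via coverage
dropout instead; an error toggle is off by default), no recombination or
selection within regions, no indels, free-floating region boundaries rather
than exon structure, and a single global phase-block process. Real
transcriptome data add mapping artifacts, allele-specific expression and
reference bias that the pipeline's filters address but the generator does
not produce.

## Numerical choices and degenerate inputs

- Branch lengths live in [10⁻⁹, 10]; JC69 distances saturate at mismatch
  fraction ≥ 3/4 (+∞ sentinel, region excluded with a warning).
- Branch optimization stops when a full sweep improves lnL by < 10⁻⁸
  (≤ 20 sweeps); NNI search accepts moves improving lnL by > 10⁻⁴ and stops
  after 50 iterations; candidate moves are screened with a single sweep and
  the winner re-optimized fully.
- The AU regression clips bootstrap proportions to [1/(2B), 1 − 1/(2B)]
  before the quantile transform.
- Polytomy resolution ladders children ordered by smallest descendant tip
  name — deterministic, constraint-preserving.
- Empty filter results warn rather than raise; a region losing all but one
  participant to masking is dropped with a warning.
- All randomness (permutations, RELL resampling, simulation) flows through
  seeds derived from a single per-run seed via numpy SeedSequence; identical
  seeds give bit-identical reports.

## Known limitations

- JC69 only; no rate heterogeneity within regions (Γ) or GTR. Immaterial at
  ~1% divergence, wrong for deep comparisons.
- The AU implementation is the two-tree pairwise form; multi-tree joint
  selection bias (the full tree-set test) is not implemented.
- Exact subtree isomorphism is a strict reading of "parallel divergence";
  partial congruence on larger trees counts as non-matching.
- The exact rank-sum enumerates up to 25 values; larger groups need the
  normal approximation (scipy) instead.
- AMOVA assumes two allele rows per individual (diploids only).
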