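# Methods

`gbsfoil` re-implements, as a tested library, a genotyping-by-sequencing
(GBS) workflow from demultiplexed short reads to introgression
inference: de novo locus construction, locus/individual filtering and
working-dataset assembly, and an exhaustive, tree-constrained five-taxon
D-statistic scan with pair-level aggregation. A synthetic-data module
generates whole GBS experiments with known ground truth so that every
stage is verifiable without sequencing data. This note records the
models, the parameters that matter, and the design choices made where
the procedure was genuinely open.

## The synthetic GBS generator

The generator emulates a reduced-representation study of a small plant
clade: an ultrametric species tree (the packaged default has 13 taxa in
three major clades plus an outgroup, root depth 1 time unit), several
populations per taxon and five individuals per population, and a few
hundred short restriction-site-anchored loci.

**Sequence evolution.** Each locus draws a uniform-random root sequence
and evolves down the species tree under Jukes–Cantor: a site on a branch
of length *b* substitutes with probability 1 − exp(−μ·b), the new base
uniform over the other three. JC is the simplest model that makes the
divergence arithmetic testable in closed form; no claim is made that it
matches the real mutation process, and the downstream statistics only
consume polarized biallelic patterns, which are model-agnostic at this
level.

**Individuals.** Individuals are diploid: two allele sequences per
locus, each the taxon haplotype plus Poisson(θ·L) private mutations
(θ = `pop_theta` per site). Populations matter for grouping and unit
selection; they do not carry extra divergence of their own.

**Introgression.** A gene-flow event (donor, recipient, γ, t_admix) hits
each locus independently with probability γ; a hit locus is re-simulated
on a genealogy in which the recipient lineage is detached and re-attached
to the donor's terminal branch at t_admix (for a population-level
recipient, an extra tip is grafted and only that population uses it).
Locus-wise genealogy replacement, rather than a per-site mosaic, matches
the locus-scale signal that D-statistics aggregate. t_admix must be more
recent than both lineages' divergences.

**Artifacts.** Each (individual, locus) read stack is deleted with
probability `dropout`; a fraction `paralog_rate` of loci is merged in
random disjoint pairs under one locus id, creating the hypervariable
composite loci that the IQR filter targets. Reads are full-locus length
(restriction-site anchored, no shearing) with Poisson(`coverage`) reads
per allele and uniform per-base error ε. PCR duplicates are not modelled
and not removed downstream, mirroring the fact that they are
indistinguishable in this design.

**Default calibration.** Defaults are fixed to the published study
design and dataset characteristics, not to any test outcome: 13 taxa,
5 individuals/population, 500 loci of 30 bp (mean locus lengths in the
study's datasets are 26.6–30.5 bp), dropout 0.2 (observed missing-data
proportions 15.4–24.1%), μ = 0.02 per site per unit depth and
θ = 0.0005 per site, which together reproduce the study's per-locus SNP
densities (≈2 SNPs/locus at the taxon level, ≈5–7 at the individual
level, against printed values of 2.02 and 5.08). θ deserves a remark: at
θ = 0.005, 130 sampled diploids put a private variant in nearly every
column of a 30-bp locus, which both contradicts the printed SNP
densities and saturates the variability metric below. Coverage 10×,
ε = 0.001, paralog rate 0.05 are desk-scale choices.

**What the generator does not emulate.** Real Illumina error profiles,
indels, barcode/adapter artifacts, coverage biases, incomplete lineage
sorting (the no-ILS fixed-genealogy model makes the null slightly
*cleaner* than coalescent data; the msprime cross-check covers the ILS
case), and paralogs that are similar enough to co-assemble from reads
(merging is imposed at the locus-table level; truly divergent merged
read stacks would simply be re-split by de novo clustering). Passing
tests therefore demonstrate correctness of the pipeline's logic and
calibration of its statistics, not robustness to every real-data
pathology.

## Locus assembly

A two-step protocol, as in the original workflow: (1) the unique reads
of a small representative set of individuals are single-linkage
clustered at ≥ τ_id identity (gap-free positional identity — the
fragments are equal-length and restriction-site anchored); clusters with
summed depth < `min_depth` are dropped; consensus is per-column majority
with ties to the alphabetically smallest base; clusters whose consensi
are themselves ≥ τ_id identical are merged until stable. (2) Every
individual's unique reads are assigned to the reference locus of maximal
identity, requiring identity ≥ τ_assign and a winner margin ≥ δ over the
runner-up; within a locus, exact sequences of depth ≥ `min_depth` seed
the alleles, shallower sequences within `correct_radius` mismatches are
corrected onto their nearest seed, and the `a_max` deepest alleles are
kept (more than two alleles can be retained deliberately: higher ploidy,
residual error and paralogy all produce them, and the SNP reduction
handles >2 states per site downstream).

Defaults τ_id = τ_assign = 0.90, δ = 0.02, min_depth = 3, a_max = 4 are
conservative and configurable; the original pipeline's thresholds are
not published, so exact reproduction of the published locus counts is
out of reach by construction. The replacement of the original clustering
pipeline and BLASTn search by these specified contracts is intentional:
at 30–40 bp, vectorised exact identity is both faster and strictly
better-defined than a seeded heuristic aligner.

A note on monotonicity: raising τ_id can only split clusters, so the
reference locus count is non-decreasing in τ_id at min_depth ≤ 1; with a
depth floor, splitting a borderline cluster can push both halves below
the floor, so the property is guaranteed (and tested) at min_depth = 1.

## Filtering and working datasets

**Variability.** The per-locus variability is the proportion of
alignment columns with ≥ 2 distinct non-missing states, over all alleles
of all individuals. The source procedure leaves the metric undefined;
the proportion makes the outlier rule length-invariant across loci.

**Hypervariability filter.** Loci with v > mean(v) + k·IQR(v) (default
k = 3) are removed as likely multi-copy regions. The unusual mean/IQR
pairing is kept deliberately, as is the linear-interpolation quartile
convention (the hand-checked fixture: v ∈ {0.02×10, 0.04×10, 0.90×1}
gives cutoff 0.0714 + 3·0.02 = 0.131, removing only the 0.90 locus).

**Missingness filter.** One pass, in order: individuals holding fewer
than θ_ind = 10% of the current loci are dropped, then loci present in
fewer than θ_loc = 70% of the remaining individuals. Boundaries are
strict ("fewer than"): an individual at exactly 10% and a locus at
exactly 70% survive. No iteration to a fixpoint: because the locus pass
runs second, the emitted dataset already satisfies the per-locus
presence guarantee.

**Datasets.** Three working datasets per taxon subset: *Individual*
(everyone surviving the filters), *Population* (the best individual per
population), and *Taxon* (one composite individual per taxon, seeded
from the best individual and filled in locus-by-locus from members of
the same population; the Albanian *C. capillacea* population is its own
taxon). "Best" is undefined in the source; here it is most retained
loci, then most total reads, then smallest id. Filters are re-applied
to each selected subset (hypervariability, then missingness), so subset
datasets are internally consistent rather than pruned views of a master
alignment.

**Reformatting.** For sequence-based analyses, one allele per unit per
locus is drawn uniformly (missing loci become N) and concatenated with a
1-based inclusive partition map. For SNP-based analyses the same
haploidised view is reduced per column: monomorphic columns drop; at
columns with more than two states, two are retained uniformly at random
and the rest become missing; coding is 0/1 anchored to the first retained
unit carrying a retained state. Bootstrap replicates resample loci, not
sites, and rebuild concatenation and partitions. Writers cover FASTA,
relaxed PHYLIP, NEXUS, RAxML-style partitions, SNP TSV, a STRUCTURE-like
two-row format, and the RADpainter tag-haplotype matrix (samples as
columns, one locus per row).

## The five-taxon D statistics

For a quintet (P1, P2, P3, P4, O) on a symmetric tree with the (P1,P2)
divergence no older than the (P3,P4) divergence, each column with no
missing data and at most two states is polarized against the outgroup
allele into a pattern b₁b₂b₃b₄ (1 = derived); columns with three or more
states cannot be polarized and are skipped. Four statistics — DFO, DIL,
DFI, DOL — take the form D = (L − R)/(L + R), where L and R are sums of
pattern counts chosen so that, under the null species tree, every left
term is mirrored by a right term of equal expectation (by the terminal
depth equality of an ultrametric tree or by exchange symmetry). The
pattern subsets are:

| | L | R |
|---|---|---|
| DFO | BABA BBBA ABAB AAAB | BAAB BBAB ABBA AABA |
| DIL | ABBA BBBA BAAB AAAB | ABAB BBAB BABA AABA |
| DFI | BABA BABB ABAB ABAA | ABBA ABBB BAAB BAAA |
| DOL | BABA BAAA ABAB ABBB | ABBA ABAA BAAB BABB |

DFO/DIL exchange under P1↔P2; DFI and DOL are each antisymmetric under
P1↔P2 and map to each other's negation under P3↔P4. Significance uses
χ² = (L − R)²/(L + R) against a 1-df upper tail — the normal
approximation to an equal-split binomial test — at α = 0.01 by default;
a statistic's sign is ±1 only when significant, else 0. With L + R = 0
the statistic is 0 by convention.

**Sign table.** First-order in μ, the expected count of a pattern on a
fixed genealogy is proportional to the summed length of the branches
producing it. Working this out for every locus-replacement gene-flow
scenario on the canonical quintet gives distinct sign signatures for all
eight directed tip events and the two ancestral events:

| DFO DIL DFI DOL | event |
|---|---|
| + + + 0 | P1 → P3 |
| + 0 + − | P3 → P1 |
| + + − 0 | P2 → P3 |
| 0 + − + | P3 → P2 |
| − − 0 − | P1 → P4 |
| − 0 + − | P4 → P1 |
| − − 0 + | P2 → P4 |
| 0 − − + | P4 → P2 |
| + + 0 0 | anc(P1,P2) ↔ P3 (direction not resolvable) |
| − − 0 0 | anc(P1,P2) ↔ P4 |
| 0 0 0 0 | none |

Any other vector is *ambiguous*. Direction resolves because a recipient
carries the donor's stem mutations (e.g. P1 receiving from P3 acquires
the (P3,P4)-stem pattern BABB), while a donor does not. The table is
locked by three independent routes in the test suite: the analytic
branch-length expectations above, end-to-end simulation on the package's
own generator, and coalescent simulation with a pulse of admixture in
msprime (which adds incomplete lineage sorting the derivation ignores —
the signatures survive it).

**Modes.** The alternate mode (`dfoil_alt`) removes the four
singleton-derived patterns (BAAA, ABAA, AABA, AAAB) from the sums; these
are the patterns most inflated by sequencing error. The automatic mode
chooses it when the total singleton count falls below a configurable
minimum (default 20), a minimum-count stand-in for the original
software's parameter-priming step, whose exact behaviour is not
described in the source. The sign table is derived for the full mode;
at intermediate γ some of a signature's cells can miss significance and
the call honestly degrades to *ambiguous* rather than guessing.

## The exhaustive scan

Units are the tips of a supplied rooted tree, validated (or repaired) to
ultrametric: `require` checks root-to-tip spans within 10⁻⁶ (relative to
tree height); `equal_terminals` re-assigns terminal branches so tip
depths equalize given the internal lengths (the deepest terminal gets a
configurable pad, default 1.0); `mean_path` smooths node ages to mean
path lengths with monotonicity enforced. All pairs-of-pairs
{{P1,P2},{P3,P4}} of distinct ingroup tips are enumerated such that both
pair ancestors are strictly younger than the joint ancestor of the four,
the two pair lineages are disjoint, and depth(P1,P2) ≤ depth(P3,P4);
equal-depth pairs are included by default with the lexicographically
smaller pair first (configurable, since the original tool's convention
is unknown and the published test count may depend on it). Disjointness
is decided via the equality of all four cross-pair MRCA depths — and
checked against a literal clade-set filter on random trees.

Each test consumes five supermatrix rows and yields the four statistics
plus a call. Aggregation lifts calls to taxon pairs via the grouping
map: a pair's *eligible* tests are those in which it could have been
called (one member in the near pair, the other in the far pair — or an
ancestral pseudo-taxon anc(X,Y) with a far-side partner); its event
count is the tests whose call involves it; the proportion is their
ratio, flagged at ≥ 5% of eligible tests and at ≥ 50 events (the
reporting thresholds used in the study). When the near pair is a single
taxon, the ancestral pseudo-taxon collapses to that taxon. Per-unit
reports give each unit's share of significant tests, mirroring the
study's per-individual screening. Ancestral pseudo-pairs have far fewer
eligible tests than species pairs, so their proportions are reported
alongside but not ranked against species pairs.

**Identifiability.** Two properties of the statistics shape what a scan
can attribute, and both are visible in the package's simulations exactly
as in the study's real data. First, a recipient carries the donor's
entire ancestry, so tests pairing the recipient with the donor's *sister*
or with ancestral pseudo-taxa also light up (the study's
"common ancestor of *C. parnonia* and *C. wettsteinii*" calls are this
effect). Second, the strength of the directed signature scales with the
length of the shared introgressed lineage, so gene flow between taxa of
different major clades is far easier to polarize at moderate γ than flow
between close relatives, where the weakest signature cell drops below
significance and the call degrades to ambiguous. The parameter-recovery
experiment therefore uses a donor with a long terminal branch and no
close sister (the Albanian *capillacea* lineage) and a recipient in a
different major clade (*langii*); recovery of the true pair with correct
polarity is then stable across seeds at γ = 0.3.

## Problem sizes and numerical conventions

The shipped experiments run on one CPU in minutes: 500 loci × 30 bp ×
130 individuals for scan-level checks (205 tests on the default
13-taxon tree), 100 loci for the assembly round trip, 24 strong-γ
quintet replicates for polarity, 500 multinomial draws for null
calibration, and ≥ 200 random fixtures for the brute-force oracles.
Determinism: every stochastic step takes a `numpy` Generator; identical
seeds give byte-identical outputs (including FASTQ). Ties are broken
lexicographically throughout (consensus bases, best-unit selection,
allele ordering, pair ordering) so outputs are stable across platforms.
Floating-point comparisons in enumeration use the tree's ultrametricity
tolerance; identity thresholds are applied with a 10⁻¹² slack so that
exact-boundary reads are kept.

## Known limitations

The null calibration of the scan is slightly conservative (the observed
any-significant fraction sits below the independence expectation
1 − (1 − α)⁴ because the four statistics share pattern classes and the
χ² is mildly under-dispersed on no-ILS data); block-jackknife standard
errors and allele-frequency D statistics are out of scope, as are
f-statistics. Assembly assumes equal-length, indel-free fragments;
reads with indels should be trimmed or discarded upstream. The
published real-data locus counts and the published total comparison
count depend on unpublished clustering/search parameters and on the
original tie conventions, and are not reproducible from the method
description alone.
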