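# Methods

This note documents the models, estimators and design choices behind
`garrupop`, in the order the pipeline runs.

## Synthetic cohorts (`simdata`)

The generator emulates a two-species resequencing design: a high-diversity
focal group ("GCO", 14 diploids, 10 males / 4 females, θ = 2.5×10⁻³ per bp,
F = 0) and a low-diversity, more inbred comparison group ("GSA",
11 diploids, θ = 3×10⁻⁴, F = 0.1), at ~20× coverage on a female-
heterogametic (ZW) genome. These defaults are the study conditions the
package targets; every parameter is a `SimConfig` field.

**Sites and genotypes.** Per autosomal scaffold and group, the number of
segregating sites is Poisson(θ·L·a_n) with a_n = Σ 1/i over i = 1..2n−1
(the Watterson correction), and derived-allele counts follow the neutral
equilibrium spectrum p(i) ∝ 1/i. For a group with F = 0, genotypes are
assigned by randomly placing exactly i alt alleles among the group's 2n
chromosome slots and pairing slots into diploids; the sample then carries
the neutral site-frequency spectrum *exactly*, which makes E[π] = θ per bp
and E[Tajima's D] ≈ 0 analytic calibration points rather than approximate
ones. For F > 0 genotypes are drawn per sample from the inbreeding
mixture P(het) = 2pq(1−F), P(hom alt) = p² + Fpq. Union sites not
segregating in a group are homozygous reference there. There is no
recombination or linkage model: sites are exchangeable within scaffolds,
so LD between distinct simulated sites is pure finite-sample noise
(E[r²] ≈ 1/n). Consequently LD-decay *curves* on simulated data are flat;
the decay-length machinery is exercised through its interpolation and
binning logic, not through a realistic haplotype structure.

**Planted features.**

- *Sweeps* are phenomenological: inside a sweep region the focal group's
  allele frequencies are pushed toward alt fixation by
  p → s + (1−s)·p with s = `divergence_shift`, heterozygosity is
  suppressed by drawing genotypes with an inbreeding-like parameter
  1 − `diversity_scale`, and a `1 − diversity_scale` fraction of sites is
  fixed outright (density thinning). This reproduces what a completed hard
  sweep looks like to an Hp/F_ST scan without simulating selection
  dynamics, which is all the scan test needs.
- *Relatives* are built by Mendelian gamete draws: a parent transmits a
  random allele per site, the other founder is a latent Hardy–Weinberg
  individual. Parent–offspring, full-sib and half-sib configurations are
  supported (expected PI_HAT 0.5 / 0.5 / 0.25).
- *Runs of homozygosity* are forced by drawing one allele per site inside
  the block and doubling it. Flanking sites remain homozygous by chance,
  so the *true* maximal homozygous run extends slightly past the planted
  edges; recovery tests therefore compare the caller against a direct
  enumeration of the genotype vector, not against the planted interval.
- *Depth* is truncated-Normal(coverage × copy ratio, CV 0.1), with copy
  ratios 1 (autosome), 1/0.5 (Z in males/females), 0/0.5 (W). W scaffolds
  in males are exactly zero.
- *STRs* follow a stepwise model (lengths = unit × k). W-linked loci are
  hemizygous: recorded as two equal allele lengths in females and missing
  in males. Kinship loci (4-bp unit, ≥ 5 distinct alleles, complete calls)
  are planted explicitly so panel-selection recovery is exact.
- *Effect labels* are drawn per site from a category multinomial, either
  one mix for all sites or one mix per origin group (the group a site
  segregates in); the per-group form is how group differences in
  deleterious load are planted. The default mix (44% synonymous,
  38% missense, 10% strongly deleterious, 8% other) is a realistic
  exome-wide blend.
- *VCF INFO fields* (QD, FS, MQ, SOR, MQRankSum, ReadPosRankSum) are drawn
  from passing distributions, except a configurable fraction of records
  (default 10%) that receive exactly one violating value, uniformly over
  the six criteria — so the hard filter's removal count has a known truth.

One global seed expands into per-stage child streams via
`SeedSequence(seed, spawn_key=(stage,))` with fixed stage indices
(genotypes 0, depth 1, STR 2, effects 3); identical configs reproduce
byte-identical outputs.

## Variant handling (`vario`)

Only biallelic SNVs enter any statistic; multiallelic records and indels
are counted and dropped at read time (cyvcf2). Genotypes are unphased alt
dosages; phased input is treated identically. Internal coordinates are
0-based half-open, converted at the VCF boundary; a variant at 1-based
position p belongs to the window containing p−1. The hard filter removes a
site iff *any* criterion fires (QD < 2, FS > 20, MQ < 40, SOR > 3,
MQRankSum < −2, ReadPosRankSum < −5); an absent INFO key never fires,
so annotation-free records survive. LD pruning is greedy left-to-right in
50-SNP windows stepping by 5 (a common convention; the r² > 0.5 rule
itself is the fixed part), never spanning scaffolds.

## Diversity and inbreeding (`popdiv`)

π uses the unbiased per-site form 2p̂(1−p̂)·m/(m−1) (m = called alleles,
site-wise), summed over a window and divided by window size; this equals
the mean pairwise difference over chromosome pairs, which the tests verify
by brute-force enumeration. Tajima's D uses the 1989 constants with
n = the site-wise minimum of called allele counts over the window's
segregating sites, and is undefined (NaN, not an exception) for S < 3 or
n < 4. The ROH caller is a deterministic run-grower honoring the three
thresholds (min 10 SNPs, min 40 kb, ≤ 2 missing, 0 hets by default) —
deliberately not a reimplementation of any scanning-window heuristic whose
internals are undocumented; segments end at their last homozygous site.
F_ROH divides by the total assembly length. The LD decay length is the
first linear-interpolation crossing of mean binned r² through 0.3 from
above, NaN if the curve never straddles 0.3. The inbreeding coefficient is
the method-of-moments F with expected homozygosity from group allele
frequencies including the sample; negative values (heterozygosity excess)
are meaningful and preserved.

## Kinship and gene flow (`kinship`)

IBS classes come directly from dosage differences (IBS = 2 − |d_a − d_b|).
The IBD moments estimator computes expected IBS-class counts under IBD
state 0/1/2 by drawing a pair's founding alleles *without replacement*
from the cohort's observed allele pool (the exact hypergeometric form of
the usual small-sample bias correction), then solves sequentially for
P0 → P1 → P2, clamps to [0,1], renormalizes, and reports
PI_HAT = P2 + P1/2. Cohort frequencies include the pair, matching common
tool behavior. Related-sample pruning removes the lower-quality member of
the worst pair repeatedly until no kept pair exceeds the PI_HAT threshold
(default 0.2; quality ties remove the lexicographically larger id, for
determinism). Neighbor joining is the standard Saitou–Nei agglomeration
with Q-matrix ties broken toward the smallest index pair and negative
branch lengths clamped to zero with a warning; the last three nodes use
the closed-form star solution. The ABBA-BABA statistic is
frequency-weighted (ABBA = Σ(1−p₁)p₂p₃(1−p₄)), so multi-sample
populations work without phasing; its Z-score is a delete-one block
jackknife over consecutive 5000-SNP blocks.

## Sweep scan (`sweep`)

Hp uses allele *observation counts* (not frequencies) summed over the
window, the convention of the statistic's origin; windows need more than
10 SNPs. A tie between major and minor counts makes the alphabetically
smaller allele major, for determinism. σ in zHp is the sample standard
deviation (n−1), with a relative floor to catch constant-Hp degeneracy.
F_ST is the Weir–Cockerham (1984) two-population ratio-of-sums
Σa / Σ(a+b+c) over the window's polymorphic sites; per-site components are
oracle-tested to 1e-12. The dual-threshold procedure takes empirical
quantiles with linear interpolation and *inclusive* comparisons, so a
window sitting exactly on a printed threshold passes. Gene annotation uses
half-open any-overlap semantics (≥ 1 bp).

## Sexing and STR panels (`sexstr`)

Depth normalization is two-pass: per-sample medians over all scaffolds,
then W-like scaffolds (male ratio < 0.1) are excluded and finally only
provisionally autosomal scaffolds feed the normalizer. The W-spotting step
uses the male side because W scaffolds contribute nothing to male depth;
the scheme assumes autosomes are the majority scaffold class, as in any
real assembly. Classification thresholds (W: male < 0.1 and female in
[0.3, 0.7]; Z: male in [0.8, 1.2] and female in [0.3, 0.7]; autosome:
both in [0.8, 1.2]) are not standardized anywhere; they follow ZW
copy-number expectation with generous noise margins and are configurable,
as is the 50-kb minimum scaffold length below which calls are forced
ambiguous. An optional per-scaffold mapping-rate table (from an external
alignment verification) can veto depth-based Z/W calls at the 20% rate
bound. "Allele types greater than four" is read strictly as ≥ 5 distinct
alleles, and "non-missing" as fully called genotypes (both alleles).
PIC is the Botstein closed form. Major/minor allele difference breaks
frequency ties toward the smaller length.

## Load and mutation rate (`mutload`)

Severity classes: strong = {frameshift, stop-gain, stop-loss, splicing},
slight = {missense, synonymous}, everything else unclassified; annotation
spellings are normalized through a synonym map. Load proportions are per
sample and per zygosity (dosage 2 vs 1), with the denominator = classified
alt-carrying genotypes of that zygosity — the base is configurable because
"proportion" is ambiguous between site- and genotype-counting. The group
comparison is a two-sided Wilcoxon rank-sum (exact null for combined
n ≤ 20, continuity-corrected normal otherwise; Welch's t available as an
alternative), chosen as the standard distribution-free test for per-group
sample sizes near 10. One caveat the synthetic experiments expose: samples
within a group share sites, so per-sample proportions are positively
correlated and the rank-sum's independence assumption is optimistic —
p-values for between-group contrasts should be read as descriptive, here
and in any analysis with this structure. The mutation rate is
μ = d·g/(2T) (divergence fraction × generation time / twice the
divergence time), mutations per site per generation; on the example inputs
d = 0.0324, g = 3 y, T = 10.96 My it evaluates to 4.4343×10⁻⁹.

## Problem sizes

Test and acceptance runs use scaled-down genomes chosen to keep every
statistic well inside its asymptotic regime: ~10⁴ independent sites for
kinship recovery (PI_HAT standard error ≈ 0.02), 500 10-kb windows for
the neutral Tajima's D calibration, 50-Mb genomes (1250 40-kb windows)
for top-1% sweep-threshold stability in the acceptance suite and 30-Mb
replicates in the acceptance script, and 20k sites for the ABBA-BABA
jackknife (20 blocks). Sex calling is deterministic at 20× with CV 0.1
given the thresholds, so ten replicates suffice to demonstrate it.

## Known limitations

- No recombination/haplotype structure: LD-based conclusions transfer only
  at the level of estimator correctness, not of realistic decay curves.
- Sweeps, ROH and introgression are planted phenomenologically; the tests
  show the *detectors* work, not that the generator mimics the processes.
- The depth model has no GC/mappability structure, and STR genotypes have
  no stutter or allele dropout beyond uniform missingness.
- Window "polishing" applied by some external tools between window counts
  is undefined and not implemented; window counts are plain tilings.
- Effect annotation is consumed, not computed; transcript-model logic is
  out of scope.
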