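# Methods

## Scope and model

`sweepscan` detects recent positive selection in unphased diploid SNP data
through three complementary signals: multisite-genotype homogeneity (G12),
pairwise identity-tract length (H), and localized population
differentiation (windowed Weir–Cockerham Fst). It then ranks candidate
loci, relates them to gene annotations, and tests functional enrichment.
This note records the statistical definitions, the defaults and why they
were chosen, the behaviour of the synthetic-data generator, and the design
decisions taken where more than one reading was defensible.

## Genotype substrate

Biallelic SNP genotypes are encoded per individual per site as one of four
codes: hom-ref (0), het (1), hom-alt (2), missing (−1). The three called
states are the *pseudo-alleles*: at a biallelic SNP an unphased diploid has
at most three distinguishable genotypes, so identity of genotype vectors
over a window substitutes for haplotype identity without phasing. All
internal coordinates are 1-based (VCF convention); BED input/output is
converted at the I/O boundary.

Site filters at load: only biallelic SNPs; FILTER must be PASS or "."
(configurable); sites with more than 10% missing calls are dropped
(configurable ceiling, `max_missing_fraction`). The 10% default assumes
moderate-to-high coverage data where missingness is rare; a hard ceiling
keeps windows comparable along the genome. Remaining missing calls are
retained and handled per-statistic.

**Missing-data rule for both homogeneity statistics:** a missing state
matches nothing, including another missing state. A sample with any
missing call in a window is a singleton genotype class, and a missing call
in either member of a pair terminates a tract. This is deliberately
conservative — missingness can only shrink a homogeneity signal, never
fabricate one.

## G12

With class counts c₁ ≥ c₂ ≥ … ≥ c_k (summing to n) in a window,

    G12 = ((c₁ + c₂)² + Σ_{i≥3} c_i²) / n² ,

and G12 = 1 when k = 1. The implementation computes the integer numerator
exactly and divides once, so the scan is bitwise-identical to any
per-window recomputation of the same formula — float summation order can
never cause divergence. Ties among equal class counts need no tie-break:
equal frequencies contribute identically whichever is called "second".

The scan uses a symmetric window of 201 SNPs (default) centred on each
focal SNP. Focal SNPs closer than 100 SNPs to a chromosome end receive no
score; chromosomes shorter than the window are skipped with a warning.
Bounds: (n+2)/n² ≤ G12 ≤ 1, the floor attained when all n multisite
genotypes are distinct (for n ≥ 2), the ceiling when at most two classes
remain.

## H

For samples i and j at focal SNP s, h_ij is the number of consecutive SNPs
in the maximal run of identical non-missing pseudo-alleles containing s
(0 if they differ at s). H(s) is the mean of h_ij over all n(n−1)/2 pairs.
Distance is measured in SNPs, not base pairs, so SNP-density fluctuations
do not masquerade as selection. H needs no fixed window: tracts extend
until broken and truncate at chromosome ends, so every SNP is scored.
Near-telomeric truncation slightly depresses H at chromosome edges; this
is accepted rather than skipping edge SNPs, since candidate calling uses
the genome-wide extreme tail where the effect is immaterial.

The implementation marks, per pair, every mismatch position as a
breakpoint and derives all tract lengths from the nearest breakpoint on
either side (vectorised over pairs); it is exactly the per-focal
definition, verified bitwise against a literal per-focal recomputation.

## Weir–Cockerham Fst

Per shared SNP (matched on chromosome, position and alleles; swapped
ref/alt reconciled by mirroring genotype codes, incompatible alleles
dropped with a logged count), the two-population diploid θ estimator is
computed from per-population non-missing sample sizes nᵢ, alt-allele
frequencies pᵢ and observed heterozygote proportions hᵢ:

    a = (n̄/n_c) [ s² − (p̄(1−p̄) − s²/2 − h̄/4) / (n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄) ]
    c = h̄/2
    θ = a / (a + b + c)

with n̄, p̄, h̄ the sample-size-weighted means, n_c the effective sample-size
correction, and s² the weighted among-population variance of p. θ is
undefined (and excluded from windows) when a + b + c = 0, i.e. the pooled
sample is monomorphic. Fixed differences give exactly 1; negative
estimates are retained — truncating them at zero would bias window means
upward. The estimator was checked against an exact-rational hand
transcription on seven genotype-count configurations, including unequal
sample sizes and heterozygote excess/deficit.

Windows are half-open bp intervals of 10 kb anchored at position 1 and
stepping by 1 kb. The summary is the arithmetic **mean of per-SNP ratios**
("mean per-SNP Fst" read literally); a ratio-of-sums variant
(Σa / Σ(a+b+c)) is available behind `ratio_of_sums=True`. Windows with
fewer than 5 defined SNPs (default `min_snps`) are emitted as undefined —
a guard against single-SNP windows dominating outlier lists. Window
candidates are represented by their midpoints.

## Candidate calling

Greedy with iterative masking: take the global maximum among unmasked
scored positions, emit it, mask ±`mask_radius_bp` (default 100 kb) around
it on its chromosome, repeat until k = 100 loci or exhaustion. The default
radius comfortably exceeds the ~29 kb physical extent of a 201-SNP window
at the default SNP density, where linkage is already weak. Ties in score
break by canonical genomic order (sorted chromosome name, then position),
making the candidate list independent of the order tracks are supplied. A
SNP-count masking mode (`mask_mode="snps"`) is provided as an alternative;
bp is the default. The greedy loop is verified against a brute-force
restatement on random tracks, and the output satisfies the spacing
invariant (all same-chromosome candidate pairs further apart than the
radius) by construction.

## Annotation and the distance null

Each candidate maps to its single closest gene: distance 0 inside the gene
interval, else the gap to the nearer boundary; ties break by smaller gene
start. Candidates farther than 20 kb (inclusive boundary) from any gene
are set aside when building gene-level candidate lists.

The permutation null for candidate-to-gene distances redraws the same
number of loci uniformly **among scored focal positions** (not uniform in
bp — candidates can only arise at scored positions), re-imposing the same
mask-radius spacing by greedy rejection, for each of ≥100 permutations.
Observed distances are compared against the pooled permuted distances with
a two-sided Wilcoxon rank-sum test (exact when the smaller sample has ≤20
observations, normal approximation with continuity correction otherwise).

Gene scores are the maximum statistic over focal SNPs inside the gene
interval; genes without a scored focal SNP are unscored. Ranks descend in
score with gene-id tie-breaks.

The coding-effect report classifies each in-gene SNP as intronic (outside
all CDS segments) or, inside the CDS, synonymous/nonsynonymous by
translating the reference codon and the alternate-substituted codon with
the standard nuclear code, reverse-complementing on minus-strand genes.
Ref-allele mismatches with the supplied reference sequence and CDS lengths
not divisible by 3 are hard errors. Classification is invariant to strand
convention (verified by the reverse-complement construction).

## Enrichment and permutation FDR

Genes are walked in rank order. A category becomes a **discovery** the
first time ≥3 (`min_genes`) of the genes seen so far belong to it; its
contributing genes are its first 3 seen members by rank. After each
discovery, genes whose interval lies within 30 kb (`mask_kb`) of a
*different* contributing gene are excluded from the surviving list and the
seen set, and subsequent ranks are recomputed over the survivors.

The "different contributing gene" qualifier is the package's resolution of
a genuinely open design point. Masking every gene in the ±30 kb regions
including the contributing genes themselves would make *any* second
category shared by the same trio undiscoverable, even for three mutually
distant genes with genuinely shared biology. Restricting the mask to
neighbours of *other* contributing genes still silences the motivating
failure mode — a tight paralog cluster (e.g. cytochrome-P450-like
tandem arrays) whose members share both the local sweep signal and their
annotations, and would otherwise convert one signal into many discoveries
— while leaving distant co-annotated trios able to support further
categories. When several categories reach the threshold at the same rank
they are processed one at a time in sorted category-id order, re-checking
membership after each mask, so a cluster masked by its first category
cannot yield its second.

Expected false discoveries per rank r are estimated by shuffling which
gene carries which score (annotation geometry and category membership
fixed), re-running the full discovery walk, and averaging the cumulative
discovery count at each r over 100 permutations (default). The estimate is
deterministic given a seed; per-permutation counts can be returned for
Monte-Carlo error assessment. Calibration was verified by checking that
discovery counts under independently score-shuffled inputs match the
estimate within Monte-Carlo error, and an exhaustively enumerable fixture
(one 3-gene category among 10 genes, r_max = 5) reproduces the
combinatorial expectation C(5,3)/C(10,3) = 1/12.

For an a-priori category (e.g. olfactory receptors), `category_test`
permutes candidate locus positions as in the distance null, re-derives
nearest-gene sets, and reports both a Fisher exact two-sided p on the
observed 2×2 table against permutation-calibrated margins and a pure
permutation p (fraction of permutations reaching the observed in-category
count, with the +1 correction). The Fisher construction is one defensible
reading of an ambiguous procedure; the permutation p is the more direct
quantity and both are always emitted.

## Cross-population comparison

Each candidate from population A is matched to the nearest scored focal
position in population B on the same chromosome (within 5 kb — the two
cohorts may segregate different SNPs). The candidate is **elevated** in B
when its matched value reaches B's genome-wide empirical 95% quantile
(α = 0.05 default). The elevated fraction across candidates reads on sweep
timing: post-split sweeps in A leave B unelevated, shared ancestral sweeps
elevate both. The empirical-quantile rule is a transparent stand-in for
any particular significance recipe; α is configurable. Percentiles are
computed with mean ranks against B's own genome-wide distribution, making
them invariant to monotone transformations of the statistic.

## Synthetic cohorts

The generator is a founder-copying mosaic (Li–Stephens-style): each of the
2n haplotypes starts from a uniformly chosen founder out of K and switches
to a uniformly chosen founder with probability `switch_probability` at
each successive SNP. Founder alleles are drawn per SNP from Bernoulli(f)
with f ~ Beta(0.5, 0.5), one founder flipped at pool-monomorphic sites so
every site is polymorphic in the pool. Genotypes are the unordered sums of
the two haplotype alleles. Positions accumulate exponential gaps.

Defaults — 29 individuals, 10,000 SNPs per chromosome, K = 40 founders,
switch rate 0.02/SNP, mean spacing 144 bp — were chosen so that a 201-SNP
window spans ≈29 kb and neutral windows essentially never contain two
identical multisite genotypes (the G12 background sits at its
all-singleton floor, with no window at 1). This emulates the regime of a
moderately diverse wild cohort scanned at full genome density.

Sweeps are injected by segment replacement, not forward simulation:
⌈carrier_frequency · 2n⌉ haplotypes (or, with `whole_individuals=True`,
both haplotypes of ⌈carrier_frequency · n⌉ individuals, giving homozygous
carriers) have their states over the span overwritten by 1 (hard) or ≥2
(soft) novel founder segments. This gives exact, seed-stable truth tables
for recovery tests. The `whole_individuals` mode exists because unphased
genotype classes only coalesce when both haplotypes match: it produces the
clean "one frequent multisite genotype" pattern a hard sweep leaves in
genotype space, and is used by the recovery tests; haplotype-level
selection remains the default.

Two-population cohorts share one founder pool per chromosome; each
population redraws founder-choice weights from Dirichlet(1/drift, …,
1/drift), so drift → 0 gives statistically identical populations and
larger drift raises baseline Fst genome-wide without creating local peaks.
Sweeps carry a population index; listing the same sweep for both
populations emulates a shared pre-split sweep.

Everything is bit-reproducible from (config, seed), including VCF, BED,
FASTA, category-map and truth-table outputs.

**What the generator does not emulate:** coalescent genealogies and their
variance, recombination-rate heterogeneity, mutation-model realism, allele
frequency spectra of real demographies, background selection, and
genotyping error. Passing recovery tests therefore demonstrates that the
statistics and pipeline respond correctly to the haplotype-block and
sweep geometry they were designed for — not that power estimates transfer
to any particular organism.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 10–29 individuals and
800–10,000 SNPs, with rate estimates over 10–20 simulation seeds and
permutation procedures at 100–300 iterations — sizes chosen so the full
verification cycle completes in minutes on one core while leaving the
Monte-Carlo error of each asserted rate well below its margin. Scan
outputs are checked *bitwise* against naive per-focal recomputations
(possible because G12 uses exact integer numerators and H averages exact
integer tract lengths). The pipeline derives per-stage seeds from the
global seed by hashing stage names, so stage reruns are reproducible
regardless of execution order. Degenerate inputs are defined behaviour:
monomorphic windows give G12 = 1, pooled-monomorphic SNPs give undefined
θ, chromosomes shorter than a window are skipped with a warning, and
candidate exhaustion returns fewer than k loci with a warning.

## Known limitations

- G12's fixed-SNP window leaves (window−1)/2 SNPs unscored at each
  chromosome end; H is scored everywhere but attenuated near ends.
- The distance-null spacing resampler uses greedy rejection; on genomes
  barely larger than candidates × mask radius it may fail where a
  backtracking sampler would succeed (it raises rather than biasing).
- `category_test`'s Fisher variant collapses the permutation null into
  expected margins; treat the permutation p as primary.
- The simulator's truth is segment-replacement truth: carrier haplotypes
  are exactly homogeneous over the span, so recovery rates are upper
  bounds relative to forward-simulated sweeps with recombination during
  the sweep.
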