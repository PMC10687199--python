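# Methods

This note documents the statistical models and estimators implemented in
`breedpanel`, the design decisions taken where conventions diverge, and what
the synthetic-data generator does and does not emulate.

## Genotype model and quality control

Genotypes are diploid biallelic dosages d ∈ {0, 1, 2} (count of the
alternate allele) with an explicit missing sentinel. When reading PLINK
text, the alternate allele is defined as the pooled minor allele (ties
resolved toward the lexicographically later allele) and recorded in the
locus metadata, so downstream frequencies are reproducible regardless of
file ordering. VCF input keeps the file's REF/ALT orientation. Every
statistic in the package is invariant to the orientation choice except the
sign convention of allele frequencies themselves.

QC runs as a single fixed-order pass — SNP call rate ≥ 0.99, pooled MAF
≥ 0.05 (missing genotypes excluded), sample call rate ≥ 0.99, then IBS
pruning at IBS > 0.95 (the pair member with the lower call rate is dropped;
ties drop the later sample) — rather than an iterative scheme. Iterative QC
converges to a similar set on clean data and is harder to audit; the report
records exactly what each stage removed. All thresholds are configurable
and each filter can be disabled.

IBS between two individuals is the mean over shared typed loci of
1 − |dᵢ − dⱼ|/2, which is invariant under allele relabelling.

## Diversity

H_O is the observed heterozygote proportion; H_E is Nei's gene diversity
2p(1−p) in its plug-in form. The small-sample factor 2n/(2n−1) is available
behind a flag but off by default: the package's Hill-number output relates
to H_E through ²D = 1/(1−H_E) exactly only for the plug-in form, and at
n = 100 the correction is below the reporting precision.

The multilocus fixation index is combined as a ratio of sums,
F_IS = 1 − ΣH_O/ΣH_E over loci with H_E > 0. This weights loci by their
diversity and is stable when near-monomorphic loci are present; the
mean-of-per-locus-ratios alternative is exposed as an option because some
toolkits report it.

Hill numbers are computed per locus from the two allele frequencies:
⁰D counts segregating alleles, ¹D = exp(−Σ p ln p), ²D = 1/Σp². Summaries
are arithmetic means of per-locus ^qD, reported per population and pooled
(both, since either convention appears in the literature). ^qD is
non-increasing in q, with equality only at p = 0.5 or fixation.

## Exact Hardy–Weinberg test

The test conditions on observed allele counts and enumerates every
heterozygote count h of the correct parity in [0, n_rare]. Probabilities
follow the recurrence P(h+2)/P(h) = 4·n_AA(h)·n_BB(h)/((h+1)(h+2)),
evaluated in log space and normalized by log-sum-exp, so sample sizes in
the hundreds are handled without overflow. The p-value sums outcomes with
P(h') ≤ P(h_obs), with a 1e−9 log-tolerance guarding floating-point ties;
the mid-p variant subtracts half the observed outcome's mass. The
implementation is verified against brute-force enumeration in exact
rational arithmetic for every configuration with 2n ≤ 40.

The default scan tests within each population (HWE is only meaningful
inside a panmictic unit) and counts a locus as deviating when it is
significant in at least one population, with raw exact p-values at
α = 0.05; Bonferroni and Benjamini–Hochberg corrections are optional.
Being an exact test on discrete data it is conservative: the realized
type-I rate at α = 0.05 sits near 0.04 for n = 100 and balanced
frequencies.

Ternary (de Finetti) coordinates place genotype frequencies in the
triangle with vertices AA = (0,0), BB = (1,0), AB = (1/2, √3/2); HWE
proportions trace the parabola y = √3·x(1−x).

## Weir–Cockerham θ and the other distances

Per locus, with r populations of sizes nᵢ, alt frequencies pᵢ and observed
het proportions hᵢ, the estimator uses n̄, n_c, p̄ (sample-size weighted),
s² (the weighted among-population variance of p with r−1 in the
denominator), h̄, and the standard variance components

    a = (n̄/n_c)·[s² − (p̄q̄ − s²(r−1)/r − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))·[p̄q̄ − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
    c = h̄/2 ,

with θ = a/(a+b+c). Multilocus and pairwise values combine as ratio of
sums Σa/Σ(a+b+c) (mean-of-ratios optional). The implementation matches an
independently coded scalar transcription of the formulas to 1e−12 and
reproduces θ = 0.39636 on the two-population counts (60/30/10 vs
10/30/60, n = 100 each).

The outlier scan uses an uncorrected variant θ₀ in which the finite-sample
correction terms are dropped: a₀ = (n̄/n_c)s², b₀ = p̄q̄ − s²(r−1)/r − h̄/2,
c₀ = c. θ₀ is upward-shifted but nearly sample-size-free, which makes the
pooled empirical distribution suitable for a one-shape null fit.

Nei G_ST for a pair uses unweighted pooling: H_S is the mean of the two
within-population gene diversities, H_T = 2p̄(1−p̄) at the unweighted mean
frequency, combined over loci as Σ(H_T−H_S)/ΣH_T. Note that on
Balding–Nichols data a pairwise G_ST sits near F/2 while θ targets F —
the two matrices agree in ranking but not in scale, which is the expected
behaviour of the two estimands, not an estimation error.

Euclidean distance is computed on alt-allele frequencies, 0–1 scale, one
coordinate per locus (a scale multiplier accommodates percent-scale
conventions), loci untyped in either population excluded pairwise.

## F_ST-outlier scan

Loci with H_E (at the weighted mean frequency) below 0.1 are excluded;
non-positive θ₀ values cannot carry the χ² model and are excluded from
fitting (they receive p ≈ 1). The lowest and highest 5% quantiles of the
remaining θ₀ are trimmed, and (df, F̄ST) are fitted by maximizing the
likelihood of θ₀ ~ (F̄ST/df)·χ²(df) truncated to the kept range — a log
grid over df with the scale profiled numerically per candidate, then
Nelder–Mead refinement at 1e−8 tolerance. Right-tail p-values come from
the fitted untruncated distribution; p < 0.05 flags an outlier. On neutral
three-population simulations the fitted df lands near K−1 = 2 and the
flagged fraction near the nominal right-tail level; loci spiked to F ≈ 0.5
over an F = 0.03 background are flagged with ≥ 80% power.

## DAPC

PCA is an SVD of the column-centered dosage matrix with missing values
imputed by locus means (unit-variance scaling optional, off by default —
dosages share a scale, and scaling inflates the weight of low-MAF loci).
A tiny ridge (1e−8 × mean within-variance) stabilizes the generalized
eigenproblem of between- versus within-group covariance on the retained
PC scores unconditionally; it is far below estimation noise. K−1
discriminant axes are kept.

The number of retained PCs is chosen by the a-score: observed
self-reassignment minus mean self-reassignment over 10 label-permuted
fits (seeded), maximized over a grid defaulting to 1..min(100, n−K), ties
to the smaller candidate. In-sample reassignment under permuted labels
overfits upward as n_pca/n grows, which is exactly the penalty the score
exploits.

Per-SNP contributions to axis j are (Σ_pc loading[snp,pc]·coef[pc,j])²,
normalized so each axis column sums to 1. The informative panel takes
every SNP whose contribution reaches the threshold (default 0.01) under an
axis policy — default "max over axes"; "axis1" and eigenvalue-weighted
alternatives are provided because the thresholding axis is a genuine
convention choice.

Group membership probabilities are Gaussian in discriminant space with
axis-wise pooled within-group variances: posterior_k ∝
exp(−½ Σⱼ (yⱼ − c_kj)²/varⱼ). "Assignment accuracy" is reported as the
proportion of individuals assigned to their true group; the mean posterior
of the true group is reported alongside, since both conventions exist.
`compare_panels` refits the whole chain (a-score included) on the reduced
panel rather than re-projecting through the full-panel model — the use
case is genotyping only the reduced panel, so the reduced model must not
borrow information from markers it will not see.

## Synthetic-data generator

Each locus draws an ancestral frequency p ~ Uniform(0.45, 0.5); each
population draws p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–Nichols:
E[p_k] = p, Var[p_k] = F·p(1−p)); each individual draws a genotype from
inbreeding-adjusted proportions with coefficient F_IS (negative values
produce heterozygote excess). Missingness is i.i.d. Defaults: K = 3
populations × 100 individuals × 300 loci, F = 0.04, F_IS = −0.03,
missing rate 0 — a deliberately assembled, highly polymorphic panel of
near-balanced markers, typical of a curated breed-assignment panel (mean
minor-allele frequency ≈ 0.45, per-population Hill profile ≈ (2, 1.95,
1.91), pairwise θ ≈ 0.04). For a chip-like spectrum pass a wider ancestral
range such as (0.05, 0.5).

With F_IS < 0 the genotype probabilities are valid only for
p_k ∈ [f/(1+f), 1−f/(1+f)] with f = −F_IS; drifted frequencies outside
this interval are clipped just inside it by default (`clip_freqs=False`
raises instead, naming the locus). At the default parameters clipping is
rare and its effect on realized F_ST is far below sampling error.

The generator emulates allele-frequency structure only: loci are
unlinked, populations drift independently (no admixture or migration),
there is no genotyping-error model, and missingness is completely at
random. Tests passing on this generator therefore validate the estimators
under the stated sampling model, not robustness to linkage, relatedness,
or informative missingness in real panels.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full emulated design
(3 × 100 × 300) for parameter recovery and panel comparison, 1000-locus
single-population simulations for HWE calibration, and 1000-locus
three-population simulations for outlier-scan calibration; these sizes
give binomial/Monte-Carlo error comfortably inside the asserted bands.
All simulations are seeded; the a-score permutations and panel comparisons
derive their randomness from the caller's seed, and identical
configuration plus seed reproduces byte-identical pipeline outputs.

## Known limitations

* Exact HWE testing and the estimators assume biallelic loci; multiallelic
  VCF records are skipped (or rejected on request).
* The outlier scan's χ² null is a heuristic for moderate K and
  near-neutral architectures; with very few loci (< 20 after filtering) it
  refuses to fit.
* G_ST and θ answer slightly different questions (see above); users
  comparing to other toolkits should check which multilocus combining rule
  (ratio of sums vs mean of ratios) and which H_E convention those use.
* a-score selection is greedy on a single grid; cross-validated PC
  selection is out of scope.
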