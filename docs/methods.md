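# Methods

This note records the models, the synthetic-data assumptions, the
numerical choices, and the limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic genotypes

Genotypes follow a haplotype-level threshold model: each sample carries
two independent latent standard-Gaussian haplotypes; along each
chromosome the latent values form an AR(1) chain with parameter
`ld_rho`, restarted at chromosome boundaries; a haplotype carries the
alternate allele where its latent value falls below Φ⁻¹(maf), and the
dosage is the sum of the two haplotypes. This yields Hardy–Weinberg
genotype proportions by construction — the reason for modelling
haplotypes rather than discretizing a single Gaussian per genotype.

Two consequences matter for interpretation:

- The dosage-scale correlation is attenuated relative to the latent
  `ld_rho` (threshold attenuation). At `ld_rho = 0.9` and maf 0.5 the
  adjacent-variant dosage r² is ≈ 0.51, a constant computed by Monte
  Carlo before the tests were written and frozen there.
- Dosage r² between variants with different allele frequencies is capped
  below 1, as in real data. Studies that need the full r² range up to 1
  (the LD-bin diagnostic) therefore use a narrow MAF band.

Defaults: MAF uniform on (0.05, 0.5], 5 kb spacing, explicit integer
seeds everywhere; there is no global random state.

## QTL phenotypes and effect sizes

Each simulated feature has one causal cis variant drawn uniformly within
±1 Mb of its anchor. Effect patterns mix four categories: fully shared
(identical β in all conditions), group-shared (identical β within a
designated condition group, zero outside), condition-specific (non-zero
in exactly one condition) and null. Residual noise is unit Gaussian per
condition, independent across conditions, with β scaled so the causal
variant explains `qtl_h2` of phenotype variance where active.

For panel-level simulations (feeding the shrinkage model directly),
non-null effect magnitudes follow a shifted folded normal,
`beta_min + |N(0, beta_scale)|` with defaults 0.2 + |N(0, 0.5)|. The
floor encodes the position that "has a regulatory effect" versus "null"
is a categorical distinction: an unbounded half-normal would label
effects far below any measurement scale as "shared signal" while they
are statistically and biologically indistinguishable from null, which
makes recovery statements about shared effects meaningless. Real
effect-size distributions for regulatory QTLs are not identified well
enough to prefer a specific unbounded family here; both parameters are
exposed.

GWAS summary statistics come from two interchangeable paths: an
individual-level path (fresh cohort drawn from the same variant
frequencies and AR(1) LD, per-variant OLS; the default for n ≤ 50,000)
and an analytic path (marginal effects r·β with correlated sampling
noise whose correlation equals the LD matrix). Their agreement at the
causal variant is tested. The expected causal z-statistic is
√(n·h²/(1−h²)).

## Preprocessing

Variant QC applies, in order: missingness ≤ 5%, MAF ≥ 5%, exact
conditional Hardy–Weinberg test p ≥ 1e-5 (computed on hard calls; the
exact test, not chi-square, for robustness at low counts). Missing
dosages are mean-imputed after filtering for regression use.

Expression normalization optionally rescales each sample to a common
total, then maps each feature through a rank-based inverse-normal
transform with offset (rank − 0.5)/n and average ranks for ties.
Constant features become all-zero rows with a logged warning.

Intron clusters quantified separately per dataset are merged by
connected components over shared splice-site coordinates (donor or
acceptor; 1-based inclusive internally, converted to 0-based half-open
on BED export). Counts are outer-joined over samples (absent = 0 reads)
and summed per intron, and usage is recomputed against the merged
cluster totals, so within-cluster usages sum to 1 per sample wherever
the cluster total is positive. An intron whose strand contradicts an
already-recorded strand at a shared splice site is dropped and logged.

## Cis-QTL scan and permutation pass

Covariates (plus an intercept) are projected out of both phenotypes and
dosages once, by QR; the per-variant OLS then runs on residuals with
n − k − 2 degrees of freedom (k = number of covariate columns), making
z = β̂/se reproducible from the published contract. Permutations permute
the residualized phenotype rows — genotype LD is untouched — and because
minimal p corresponds to maximal |correlation| at fixed df, all
permutations are evaluated with one matrix product per feature. The
Beta(a, b) fit to the permutation minima uses maximum likelihood with a
moment-matching start (`floc=0, fscale=1`); on failure the empirical
permutation p is used with a logged warning. Permutation count defaults
to 1000, fixed (no adaptive early stopping — determinism first).

Storey's π0 is estimated from the grid π0(λ) = #{p>λ}/(m(1−λ)),
λ = 0.20…0.95, by a precision-weighted (w ∝ 1−λ, the inverse variance)
linear extrapolation to λ = 1; for m < 100, the single-point estimate at
λ = 0.5 is used. The weighted linear tail fit was chosen over cubic
extrapolation because it has both smaller bias and smaller variance in
Monte-Carlo comparison; the q-value step-up is the usual
π0·m·p/rank with monotone enforcement. Phenotype-PC counts are chosen to
maximize features at q < 0.05 (three genotype PCs always included), ties
toward fewer PCs.

## Multivariate shrinkage (EE mode)

The model and its estimation are described in the README. Numerical
choices:

- Scale grid: 10-point geometric sequence on [0.05·s, 2·s] where s is
  the largest noise-adjusted magnitude √max(β̂² − se², 0) in the strong
  set; components are normalized to unit maximum diagonal so the grid
  carries the magnitude.
- Null correlation: correlation of z-scores across random-set tests with
  |z| < 2 in every condition; identity fallback (logged) below 10 such
  tests.
- Data-driven components: top-5 eigenvector rank-1 patterns of the
  strong-set z covariance plus its full empirical covariance, negative
  eigenvalues clipped at zero (logged).
- EM updates only the mixture weights; the per-test likelihood matrix is
  computed once (tests sharing a standard-error row share a Cholesky
  factor), so each iteration is a closed-form reweighting and the
  log-likelihood is non-decreasing by construction — asserted exactly in
  the tests.
- LFSR counts the null point mass against both signs (conservative): a
  fully symmetric posterior with point mass has LFSR > 0.5.
- Sharing denominators are features significant in either member of the
  pair; share-by-magnitude additionally requires equal signs and a
  magnitude ratio within the fold factor (default 2; 1.5 is a common
  alternative and is exposed). Region exclusion (e.g. an HLA band) is a
  first-class argument so its effect on sharing is directly reportable.
- Cell grouping: average-linkage hierarchical clustering on 1 − sharing,
  cut at k = 6 by default.

## Colocalization

Greedy clumping sorts by p (ties broken toward the smaller coordinate),
takes leads while p < 1e-7, and removes ±500 kb around each; leads
inside exclusion regions (default chr6:25–35 Mb) are kept in the output
but flagged excluded with the reason, and never count toward rates.
Windows of nearby leads are treated independently. Features are
ascertained at bpval < 0.01 with anchors within ±1 Mb of the lead.

All hypothesis sums are log-sum-exp; the two-distinct-causals term uses
log(Σᵢ Σⱼ − Σᵢ₌ⱼ) via `log1p(−exp(·))`, which degrades gracefully to
PP3 = 0 for single-variant loci. W defaults to 0.15 for quantitative
traits (0.2 on the log-odds scale would be the binary-trait choice);
p12 = 0 is permitted and forces PP4 = 0. Variant harmonization matches
on (chrom, pos, unordered allele pair), flips β on ref/alt swaps, and
drops strand-ambiguous (A/T, C/G) variants by default. The locus-level
call is the maximum-PP4 feature; all feature-level rows are retained.
Traits with ≤ 10 loci are flagged underpowered. Known limitation
(documented, by design of the single-causal-variant framework): with two
distinct causal variants in very high LD (r² > 0.95), PP4 inflates.

## Diagnostics

LD-bin profiles use squared Pearson dosage correlation in an explicit
reference panel, bins (0,0.25], (0.25,0.5], (0.5,0.75], (0.75,1]; empty
bins are reported missing and skipped by the monotonicity check, and
profiles whose best QTL variant is not in close LD with the lead
(r² ≤ 0.8) are dropped from display, mirroring the ascertained
population the diagnostic is meant to show. π1 bootstrap resamples the
discovery entries with replacement (1000 draws; < 20 entries flags the
CI unstable). Targeted lead-SNP tests Bonferroni-correct within locus by
the number of eligible genes and exclude pairs already tested in
colocalization; loci with no eligible gene leave the denominator.
Peak overlap places the 1-based lead position into 0-based half-open BED
intervals (pos − 1); the Fisher test is two-sided by the
sum-of-smaller-probabilities convention, zero cells get the Haldane 0.5
correction for the odds ratio only, and the CI bootstraps the
uncolocalized loci.

## Study sizes and what passing shows

The benchmark studies use desk-scale problem sizes chosen to estimate
each property with useful precision: 200 loci per colocalization
condition (GWAS n = 10,000 at h² = 0.004; QTL n = 300 at h² = 0.1;
AR(1) ρ = 0.9; distinct causals at r² < 0.05); three pooled 500-feature
all-null permutation studies (1000 permutations each, 10,000-permutation
empirical oracle); a 1000-feature × 6-condition shrinkage panel at
se = 0.1; 100 LD-bin replicates per pattern (n = 300, 200 variants,
ρ = 0.99, MAF 0.4–0.5, h² = 0.5 — the strong ascertained tail that the
diagnostic displays); and π1 mixtures of m = 2000 averaged over six
draws, since a single Storey estimate carries irreducible sampling noise
of ~0.02–0.04 and the λ→1 limit identifies π1 = 0.45 (not 0.50) for the
50/50 U + Beta(0.1,1) mixture.

The generators emulate the statistical structure the methods assume —
LD, effect sharing patterns, compositional intron usage, GWAS/QTL causal
configurations — and none of the biological texture they do not:
no demography or selection, no imputation uncertainty, no
mapping/alignment artifacts, no expression count noise (phenotypes are
Gaussian on the normalized scale), and conditions share samples with
independent residuals. Passing therefore certifies the statistical
machinery (exactness against oracles, calibration, recovery under the
assumed model), not performance on any particular real cohort.
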