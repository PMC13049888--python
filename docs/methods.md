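# Methods

This note documents the statistical models implemented in `admixmeth`,
the defaults of the synthetic-data generator, the numerical choices that
matter, and the limitations a user should know before trusting results
on real data.

## Count model

All methylation analyses model methylated reads *y* out of *n* at a CpG
as beta-binomial with mean mu and intraclass correlation phi. The
mixing distribution is Beta(mu(1−phi)/phi, (1−mu)(1−phi)/phi), so the
count variance is n·mu(1−mu)(1+(n−1)phi) and phi = 0 is *exactly* the
binomial — the likelihood code special-cases it rather than taking a
limit. The mean is logit-linear in the design.

Fitting maximizes the likelihood jointly over coefficients and
log-precision t = log((1−phi)/phi) with analytic gradients (L-BFGS-B,
t bounded in [−2.2, 25]; the upper bound is numerically binomial). The
start is a binomial Newton–Raphson fit plus a method-of-moments
dispersion; a second start at moderate dispersion guards against the
moment start stalling near the binomial boundary, which otherwise breaks
the nesting of profile likelihoods in likelihood-ratio tests. A pure
binomial fit is kept whenever it attains the higher likelihood.
Convergence is declared from the size of the Newton step (scale
invariant), not the optimizer's status flag, and reported honestly:
non-converged sites are flagged and excluded from q-value computation
with a count.

Wald standard errors come from the observed information (finite
differences of the analytic gradient for the beta-binomial branch). The
mixed-effects relatedness term used by count-based methylation tools on
real pedigreed cohorts is deliberately absent: global ancestry and any
caller-supplied covariates (batch, conversion rate, principal
components) are the only structure adjustment. This is a documented
simplification — on kin-structured data the scans here will be
miscalibrated unless the permutation null absorbs the structure.

## Empirical-null FDR

Every scan converts p-values to q-values against a permutation pool:
FDR(t) = pi0 · (#{p_perm ≤ t}/B) / max(1, #{p_obs ≤ t}), with the
q-value of a site the minimum FDR over thresholds at or above its p.
pi0 uses the single-lambda estimator #{p > 0.5}/(0.5·m), capped at 1 —
simpler and more stable than spline smoothing at the pool sizes used
here (default B = 10 permutations, configurable). Permutations move
*labels only*: ancestry dosage vectors (local scan), the global-ancestry
vector (global scan), taxon labels (species contrast), genotypes plus
heterozygote read-allele assignments (meQTL), RNA/DNA labels within
replicate pairs (reporter activity), condition labels across replicate
pairs (reporter interaction). Counts and covariates never move.

Two reporter-stage specifics. First, because observed reporter data are
asymmetric (most windows produce far more DNA than RNA) while permuted
effects are symmetric, each activity permutation's p-value pool is
subsampled to the observed number of positive-effect windows before
q-value estimation. Second, both reporter FDRs fix pi0 = 1: the tested
sets (positive-effect windows; the active set) are enriched for true
signal, which simultaneously depresses the single-lambda pi0 estimate
and — through inflated within-group variance when truly
methylation-dependent windows are permuted — thins the pool's small
p-values. The default estimator is anti-conservative in exactly this
situation; pi0 = 1 restores calibration (verified by the null-calibration
suite, which requires ≤ 2% of units at q < 0.1 under global nulls).

## meQTL joint likelihood

A SNP–CpG pair is tested by a composite likelihood over rows (k, n, w)
where the beta-binomial mean is (1−w)·p0 + w·p1 with p0 = expit(mu0),
p1 = expit(mu0 + beta): individual-level rows use w = dosage/2 (the
read-level mixture over an individual's two haplotypes is linear on the
proportion scale), heterozygote reference-allele read rows use w = 0 and
alternate-allele rows w = 1. One dispersion is shared. The meQTL test is
a 1-df likelihood ratio of beta = 0, with the alternative warm-started
at the null solution so nesting holds by construction. Reads that cover
the SNP inside a heterozygote appear only in the allele-specific rows
(the individual-level counts exclude them); homozygotes contribute all
reads at the individual level. The reported `delta` = p1 − p0 is the
per-allele effect on the proportion scale, the quantity that composes
with parental frequency differences.

Boundary cases are real data, not failures: a CpG-disrupting allele has
methylation ~0, driving mu0 or beta to the box bound. Convergence is
therefore judged on the *projected* gradient, so such fits are kept.
With no heterozygotes (or no allele-assignable reads) the model degrades
to the individual-level component alone, flagged via
`has_allele_specific`.

The meQTL permutation shuffles genotypes across individuals, then
re-draws each original heterozygote's assignable read labels uniformly
(methylated and unmethylated reads independently at probability 1/2).
Individuals newly labelled heterozygous by the shuffle have no
assignable read pool and contribute individual-level counts only; every
individual's (meth, total) marginals are preserved exactly.

## Effect scales

Logit-scale coefficients are converted to the proportion scale as the
difference in model-predicted mean methylation between homozygous states
at covariate means; per-allele effects are half the state difference.
This makes the species contrast, the ancestry scan and the meQTL
`delta` commensurable, which the composition comparison requires. Both
axes of the predicted-vs-observed comparison are per allele.

## Synthetic cohorts

The generator emulates the study design the analyses target, and its
defaults are the study conditions, not tuning knobs:

| parameter | default | rationale |
| --- | --- | --- |
| n_individuals | 256 | cohort size of the motivating hybrid population |
| divergence_F | 0.28 | middle of the reported F_ST range (0.23–0.33) between the parental taxa |
| admix_alpha | 0.37 | mean anubis admixture fraction of the population |
| mean_coverage | 20 reads/site | RRBS-scale depth; negative-binomial (shape 5) because RRBS coverage is overdispersed |
| mean_tract_bp | 1 Mb | megabase-scale tracts, consistent with admixture over tens of generations |
| bb_dispersion | 0.05 | mild extra-binomial noise typical of population bisulfite data |
| frac_meqtl / frac_disrupted | 0.5 / 0.1 | half the CpGs carry a linked meQTL; a tenth of those are CpG-disrupting |
| effect_sd_logit | 1.5 | large-effect cis meQTL (SD of the allelic effect on the logit scale) |

Parental allele frequencies follow the Balding–Nichols model (ancestral
frequency uniform on [0.05, 0.95], taxon frequencies Beta-drawn with
variance F·p(1−p)), under which a Hudson-style two-population F_ST
estimator recovers F. Ancestry tracts are a two-state Markov process per
haplotype with stationary anubis probability alpha and count-weighted
mean segment length mean_tract_bp; generations and recombination maps
are not modeled — the tract *pattern* is what downstream code consumes.
Methylation reads pick a haplotype uniformly, then a methylation state
from the haplotype allele's probability perturbed by a beta-distributed
individual-by-haplotype effect; reads cover a linked SNP (becoming
allele-assignable) with probability 1 − distance/100, a linear
read-overlap geometry for 100 bp reads. Disrupting alleles force
methylation to 0.01.

The reporter generator draws DNA counts negative-binomially around a
lognormal window propensity; RNA expectation is the propensity times a
baseline RNA/DNA ratio of 0.3 (most windows emit less RNA than their DNA
input) times an activity multiplier, uniform on [4, 8] for active
windows and condition-specific for methylation-dependent ones, 87% of
which are more active unmethylated — the direction split reported for
methylation-sensitive enhancers.

What the generator does *not* emulate: kinship and cryptic relatedness,
chromosome-scale recombination and selection against introgression,
sequence-context-dependent coverage (RRBS fragment bias), bisulfite
conversion error, and cell-type heterogeneity. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to those real-data complications.

## Other numerical choices

* Logit-scale linear predictors are clipped at ±30 and means at
  [1e-12, 1−1e-12]; coefficient boxes at ±15.
* The species-contrast Fisher test is two-sided by the minimum-likelihood
  rule, with a Woolf (log-scale normal) 95% CI and a Haldane 0.5
  correction only when a cell is zero (the exact p is computed on the
  uncorrected table).
* Reporter normalization: per-sample scale = library size × a
  median-of-ratios composition factor computed on counts-per-million
  against a leave-one-out geometric-mean reference, with the 0.5
  pseudo-count added *after* scaling. This makes abundances exactly
  invariant to rescaling any single sample and keeps zeros finite.
* Minor alleles in the variance-gain analysis are defined in the
  yellow-homozygous subset and held fixed for the full-sample estimate,
  so a positive shift is admixture-introduced frequency change rather
  than a re-folding artifact. Paired t-tests are on raw (not log) SDs.
* CpG islands: 100 bp windows stepped by 1 marked when GC > 0.5 and
  observed/expected CpG (n_CpG·100/(n_C·n_G), dinucleotides fully inside
  the window) > 0.6; bases covered by any marked window are merged and
  maximal runs longer than 200 bp reported. Shores are 2 kb flanks
  clipped at sequence ends and excluding island bases. The
  implementation is validated against a position-wise string-counting
  oracle. Gene windows for expression integration span TSS−10 kb to
  TES+10 kb, widened symmetrically to 50 kb for short genes; promoters
  are the strand-aware 10 kb upstream of the 5'-most TSS.
* Pipeline randomness flows from one root seed through named
  SeedSequence substreams per stage; identical configs produce
  byte-identical outputs.

## Design decisions that were genuinely open

* **Permutation granularity in the ancestry scan**: one individual-level
  permutation per replicate applied to every site (rather than per-site
  independent shuffles), which preserves cross-site correlation in the
  null pool and is cheaper; both are valid nulls for the per-site test.
* **Interaction test statistic for reporter data**: a pooled-variance
  linear contrast across the four assay×condition groups stands in for
  precision-weighted linear modeling. It loses some power on
  heteroskedastic replicates but is dependency-free, exactly
  permutation-compatible, and calibrated by the null suite.
* **Top-stratum definitions** (e.g. "strongest associations") are by
  p-value, not effect size.
* **Species effect axis**: whether concordance correlations are Pearson
  or Spearman is reported both ways, as the two can diverge under heavy
  tails.

## Problem sizes used by the test suite

The suite exercises cohort-scale recovery at n = 300 individuals with
~500 meQTL CpGs at 20× coverage, null calibrations at 1,000
sites/pairs and 10 permutations per scan, and reporter recovery at
5,000 windows with six replicates per assay and condition — sizes at
which the permutation machinery is fully engaged while a complete run
stays in the minutes range on one core.

## Known limitations

* No relatedness random effect (see above): scans assume exchangeable
  individuals given covariates.
* Composite-likelihood p-values for the joint meQTL test are slightly
  conservative at small n; the empirical-null FDR absorbs this because
  observed and permuted statistics share the conservativeness.
* The allele-assignment probability model (1 − d/100) is a geometric
  idealization of read overlap; real assignability depends on fragment
  length distributions.
* Trans (genome-wide) meQTL, imputation-based genotype expansion and
  bisulfite alignment/genotype calling are out of scope; the package
  starts from counts, genotypes and ancestry calls.
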