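# Methods

This note records the statistical models the package implements, the
conventions and defaults it fixes where several choices were
defensible, and what the synthetic data generator does and does not
emulate.

## Weighted burden association

All aggregation tests share one primitive.  For an analysis set of
bi-allelic SNVs with minor allele frequency below `maf_max` (default
0.05, computed on the union of the two compared groups after sample
selection, since genotypes are jointly called and the test is
symmetric in the groups), each individual's burden over a variant set
is the dosage sum weighted by the Beta(1, 25) density at the variant's
MAF, `w(m) = 25 (1 − m)^24`.  Weights near 25 for singletons decay to
~7 at m = 0.05, so rarer variants dominate.  Indels are excluded from
the default analysis set (`snv_only`), as are variants overlapping the
excluded-regions track.  Missing genotypes count as zero alt alleles;
per-variant missingness above 5% is reported.

The test regresses group status (case/control, or study/study for
control-group comparisons) on the burden by maximum-likelihood
logistic regression with covariates: ten genetic PCs, sex, sequencing
batch (only when both groups come from the internally sequenced
study), the per-sample *total* weighted burden over the whole analysis
set (a variant-load normaliser), and optionally the first four
sequencing-metadata PCs.  The reported p-value is the two-sided Wald
test on the burden coefficient (a likelihood-ratio option exists).  A
Jeffreys-prior-penalised (Firth) refit replaces the MLE when the fit
fails to converge in 50 Newton iterations or the coefficient exceeds
15 in absolute value — the symptoms of (quasi-)separation that rare
categories produce.  A burden with zero variance yields a flagged
degenerate result (p = 1), not an exception.  Rank-deficient covariate
designs are rejected with the offending columns named; categorical
covariates are one-hot coded within the analysed sample subset with
the reference level dropped.

Scan-level inflation is summarised by the genomic-control factor
λ_GC = median(χ²₁-quantiles of the p-values) / 0.4549.  Note that λ
over only 200 category tests has an irreducible sampling SD of ≈ 0.17
even for a perfectly calibrated scan (the median of 200 χ² draws is
noisy); λ estimates from window scans (~1,900 windows) or
single-variant scans (tens of thousands) are correspondingly tighter.
This matters when interpreting a single scan's λ, and it is why the
calibration tests pool p-values across replicate null phenotypes.

## Category scans

Chromatin states and conservation states are treated as genome
partitions (a variant gets exactly one label per system; overlapping
intervals in a partition track are an input error).  Repeat categories
may overlap, as RepeatMasker annotations do: a variant contributes to
every repeat label covering it and once to the `any_repeat` union, so
21 labels yield 22 tested categories.  Variants covered by no state
("unassigned", e.g. assembly gaps) remain in the total-burden
covariate but belong to no tested category.  VCF positions are 1-based
and BED intervals 0-based half-open; a variant at position p is
assigned the interval containing p − 1.  Indels are annotated by their
anchor position.

Bonferroni thresholds are computed as exact rationals before float
conversion: 0.05/200 = 2.5×10⁻⁴ for the state family, 0.05/22 ≈
2.3×10⁻³ for repeats, with stricter across-comparison versions
dividing additionally by the seven comparison groups (six case/control
pairs plus the control/control contrast — a single constant,
`pipeline.N_COMPARISONS`, feeds every such threshold).

## Sequencing-metadata PCs

Per-sample QC metrics (mean depth, contamination, insert size, base
quality by default) are mean-imputed, z-standardised (constant columns
dropped), and decomposed by SVD; the top k = 4 scores are exposed as
covariates `mpc1..mpc4`.  Scores are deterministic up to sign; the
convention that each component's largest-magnitude loading is positive
makes output platform-reproducible.  With the default four metrics the
four PCs span the full metric space, so conditioning on them is
conditioning on the metrics themselves — the regime in which a
depth-driven artifact can be fully absorbed.  Users adding more
metrics than PCs should expect only partial absorption.

## Sliding-window scan

Windows of 5, 10, 15, 20, 25 and 50 kb tile each chromosome with a
step of half the window size (the conventional overlap compromise;
configurable).  The last window of a chromosome is clipped.  Windows
with fewer than two analysis-set variants are skipped.

Per-window tests use the logistic *score* statistic against the
covariate-only null model — the standard fast-scan formulation; the
score, Wald and LRT tests agree to first order, and the score form
turns a genome scan into a single matrix product.  Reported effects
use the one-step approximation β ≈ U/V, se ≈ V^(−1/2).

The family-wise threshold is permutation-calibrated: null residuals
are permuted within deciles of the covariate-only linear predictor
(naive label permutation would break the covariate structure and
mis-calibrate under confounding), the genome-wide minimum p is
recorded per permutation (default 5,000), and the effective number of
tests is n_eff = 0.05 / (empirical 5th percentile of the minima),
capped at the number of tested windows.  The genome-wide threshold is
0.05/n_eff; a cross-analysis threshold divides 0.05 by the summed
effective tests over all comparison groups.  The estimator is
validated against its two analytic limits — independent windows
(n_eff ≈ window count) and fully duplicated windows (n_eff ≈ half) —
rather than against any particular genome's value, which depends on
real LD and variant density.  At 5,000 permutations the 5th-percentile
estimate carries ≈ 6% relative Monte-Carlo error and a ≈ 2.5%
conservative finite-sample bias.

The secondary dissection of a chosen window runs (a) the burden test
on its non-repeat variants, (b) a two-sided Fisher's exact test
(minimum-likelihood rule) on each variant's 2×2 allele-count table,
and (c)/(d) burden tests on the Fisher-nominal (p < 0.05) subset and
its complement.  Because (c) selects variants by their association
with the outcome on the same data, its p-value is exploratory, not a
calibrated test — the point of the procedure is to localise which
variants carry a window's signal.

## Singleton PTV tests

Singletons are variants whose alt allele appears exactly once among
the designated unrelated samples (copies among relatives do not
disqualify a site).  PTVs are the frameshift, stop-gained,
splice-acceptor and splice-donor consequence classes, consumed from an
input table; a variant annotated to several genes counts once per
gene.  Genes with more than 10 singleton PTVs are tested by logistic
regression of case status on the per-sample count, adjusting for ten
genetic PCs, sex and the individual's *total* genome-wide singleton
allele count (all singletons, not only PTVs — the stronger control for
per-sample call-rate differences).  Gene sets sum counts over member
genes first.  Wald p-values are reported; thresholds are 0.05/1045 for
the gene family of the emulated design and 0.05/3 (0.05/6 stricter)
for the three-set family.  At the sparse end of eligibility (~a dozen
carriers) the Wald test is mildly conservative; calibration is nominal
from a few dozen carriers upward.

## Single-variant tests

Variants with MAC > 20 in the tested individuals (recomputed per
comparison) are score-tested for dosage association with the same
covariate logic; ORs use the reference-genome allele as reference.
One-step estimates provide OR and Wald 95% CI; variants passing a
reporting threshold (default p < 10⁻⁴) are refitted by Firth logistic
regression so near-separated rare variants get finite, reportable
estimates.  Fisher's exact allele-count tests (Haldane-corrected OR
when a cell is zero) serve counts below the score test's comfort zone.
Genome-wide significance is 5×10⁻⁹, conservatively 5×10⁻⁹/7 ≈
7.1×10⁻¹⁰ across the seven comparisons.  Relatedness modelling and
saddlepoint corrections for extreme imbalance are out of scope; the
score test's calibration on the synthetic cohorts (which contain no
relatedness) is verified in the test suite.

## Analytic power

The power model: risk-allele frequency p under HWE, per-allele odds
ratio r multiplicative on the odds scale, baseline genotype odds
solved so the population-average risk equals the prevalence; case
genotype frequencies follow by Bayes; controls are population-based
(unscreened), carrying population frequencies.  Power for the 1-df
allelic test uses the normal approximation of the case/control allele
frequency difference with the variance under the alternative, against
a one-tailed critical value at α — the design-stage convention of
classic epidemiological detectable-effect calculations (the direction
of a hypothesised risk allele is prespecified); a two-tailed option is
exposed.  The detectable OR is reported on the allelic
(cross-product) scale — the quantity a 2×2 table estimates — which is
slightly attenuated relative to the model's per-allele OR because
unscreened controls include affected individuals; both scales are
returned.  Inversion is by bisection to |Δpower| < 10⁻⁶.

The simulation cross-check draws case genotype counts from the
multinomial case frequencies and control allele counts from the
population binomial, and applies the *design-variance* statistic the
formula models; its rejection rate matches the analytic power to
Monte-Carlo accuracy.  A practical caveat, verified empirically: the
everyday estimated-SE Wald z test is anti-conservative at extreme
tails (α ≈ 5×10⁻⁹) for rare alleles — its true power at the solved OR
exceeds the nominal 80% by several points — so the analytic numbers
are design-stage approximations, not guarantees about any specific
test statistic.

## The synthetic cohort generator

The generator emulates the *structure* that the tests assume, at a
desk scale (defaults: 300 + 600 cases, 500 internal and 2,600 external
controls, two 1-Mb chromosomes, 40,000 variants):

* **Site-frequency spectrum:** MAFs from Beta(0.2, 2) truncated to
  (1/2N, 0.5), putting most mass below 0.05; genotypes are
  binomial(2, MAF), i.e. no LD, HWE everywhere.
* **Annotation tracks:** repeat categories with genome fractions and
  element lengths loosely following the human repeat landscape (SINE
  16%, simple repeats ~1%, etc.); chromatin- and conservation-state
  tracks whose segment labels are drawn *conditionally on local repeat
  content*, so states differ sharply in repeat composition.  This
  heterogeneity is essential: a repeat-specific calling artifact
  inflates state-level tests only because states overlap repeats
  unevenly, and it is why the total-burden covariate alone cannot
  absorb a repeat artifact while state tests still detect it.
* **Depths and QC metrics:** per-sample mean depth from the two
  studies' distributions (26.8 ± 5.5 internal, 36.8 ± 4.7 external); a
  latent calling-quality score defined as a fixed affine transform of
  depth, with the other QC metrics noisy linear functions of it.
* **Differential-calling artifact:** for each configured repeat
  category, every sample gains spurious alt alleles at category
  variants with probability rate × softplus(quality).  Because quality
  is a smooth function of depth, the deeper external study carries a
  ~4× higher artifact intensity — yet conditioning on depth (via the
  metadata PCs) removes the study association entirely.  This
  "quality-modulated" mechanism is one plausible emulation of a
  depth-driven calling difference whose true cause (library prep,
  depth, center pipelines) is not identifiable from the emulated
  study's data; a "study_specific" mode restricts artifacts strictly
  to the external study for tests of artifact containment, at the cost
  of the absorbability property.  The default artifact rate (0.005
  per category variant at softplus = 1) is set so the SINE differential
  is decisively detectable at fixture scale — per-state shifts of a
  few null SDs, a state-scan λ well above 1.2, mirroring an
  overwhelmingly significant real-data SINE difference — while leaving
  single-variant control/control scans near λ ≈ 1.
* **Phenotype:** a liability model on the log-odds scale; implanted
  window effects act per unit of the window's weighted burden, and
  gene-set effects per singleton PTV carried.  Cases are the top-n
  liabilities among internal-study samples (exact requested counts),
  split randomly into the two diagnoses; external samples are all
  controls.  Genetic PCs are pure noise columns (no population
  structure is simulated).
* **Reproducibility:** one seed feeds named spawned streams (tracks,
  positions, MAFs, genotypes, artifact, metrics, phenotype), so a
  fixed seed yields byte-identical outputs and changing, say, the
  artifact rate leaves genotypes untouched.

Not emulated: LD and recombination, population structure and
relatedness, sex chromosomes, indel-specific artifacts, variant-level
QC annotations.  Consequently, passing tests demonstrate the
machinery's correctness and calibration under the stated generative
assumptions — they do not certify behaviour under real LD, cryptic
relatedness, or artifact mechanisms uncorrelated with the measured QC
metrics (the last being exactly the failure mode the sensitivity
report exists to surface).

## Problem sizes in the test suite

The suite runs the full machinery at the scales the fixtures define:
the canonical cohort at ~4,000 × 40,000, a null cohort at
~4,000 × 25,000 for calibration, small cohorts (~470 × 4,000) for
module tests, 200 replicate cohorts (~800 × 5,000) for gene-set
recovery, and 3,000/2,500-replicate null simulations for test-size
checks — sizes chosen so Monte-Carlo noise is small relative to the
bands being asserted.

## Known limitations

* Wald burden p-values at very sparse carrier counts are conservative;
  the Firth fallback guarantees finiteness, not exact size.
* The window-scan effect sizes are one-step approximations; refit the
  top windows with `burden_logistic_test` when exact MLEs matter.
* λ_GC from a single 200-category scan is a noisy diagnostic (SD
  ≈ 0.17 under the null); judge calibration from pooled or replicated
  scans where possible.
* The power module's one-tailed, allelic-OR reporting convention is a
  design-stage choice; switch `tails=2` and read `or_per_allele` for
  the stricter two-sided, model-scale convention.
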