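# wgsburden

Rare- and low-frequency-variant association testing and sequencing
batch-effect QC for whole-genome-sequencing case-control studies that
combine jointly called cohorts — the analysis setting of psychiatric
WGS studies (bipolar disorder / schizophrenia cases with internal
controls) augmented by deeper-sequenced external controls.

When two studies are sequenced at different centers and depths, burden
tests that aggregate millions of rare variants are exquisitely
sensitive to differential variant calling: excess non-reference calls
concentrated in repeat-rich genomic regions masquerade as association.
`wgsburden` implements both the association machinery and the
diagnostics that detect and absorb such artifacts.

## What it computes

* **Weighted burden tests.** For a variant set *S*, each individual's
  burden is `b_i = Σ_{v∈S} w(m_v) g_iv` with dosage `g_iv ∈ {0,1,2}`
  and the Beta-density weight `w(m) = Beta(m; 1, 25) = 25(1−m)^24`
  upweighting rarer variants (the SKAT/WGScan convention).  Case or
  study status is regressed on `b` by logistic regression with genetic
  PCs, sex, batch and the total weighted variant load as covariates; a
  bias-reduced (Firth) fit takes over under separation.  Scans report
  the genomic-control inflation factor
  `λ_GC = median(χ²₁)/0.4549`.
* **Annotation-category scans** over 100 chromatin states, 100
  conservation states, and 21 repeat categories plus their union (22),
  with Bonferroni thresholds 0.05/200 and 0.05/22 and stricter
  across-comparison variants.
* **Sequencing-metadata PCs.** Principal components of per-sample QC
  metrics (mean depth, contamination, insert size, base quality); the
  first four serve as nuisance covariates that can absorb depth-driven
  differential calling.
* **Genome-wide sliding-window scans** at 5/10/15/20/25/50 kb with
  half-window steps, permutation-estimated effective number of tests
  *n*, and a 0.05/*n* genome-wide threshold; plus a secondary
  dissection of a top window (non-repeat subset, per-variant Fisher's
  exact tests, nominal/non-nominal partition).
* **Singleton PTV burden tests** at gene (>10 singleton PTVs) and
  gene-set level, with the per-sample total singleton count as
  covariate.
* **Single-variant score tests** (MAC > 20) with Firth refits and a
  Fisher's-exact small-count fallback.
* **Analytic power:** the per-allele odds ratio detectable at 80%
  power under a multiplicative model with prevalence scaling and
  population-based (unscreened) controls.
* **A synthetic two-study cohort generator** that emulates all of the
  above: a rare-variant-dominated site-frequency spectrum, repeat-aware
  state annotations, depth distributions of ~27x vs ~37x, depth-driven
  excess calls in chosen repeat categories, and implantable window and
  gene-set signals with a truth file.

## Worked example

Detecting — and then absorbing — differential calling between two
control groups on a simulated cohort (~4,000 samples, 40,000 variants,
an excess-call artifact in SINE elements):

```python
import wgsburden as wb
from wgsburden.burden import BurdenDesign, run_category_scan
from wgsburden.metadata_pcs import build_metric_matrix, compute_metadata_pcs
from wgsburden.pipeline import DEFAULT_METRIC_COLUMNS

cohort = wb.simulate_cohort(wb.DEFAULT_FIXTURE_CONFIG)
annotation = cohort.annotate()

metrics = build_metric_matrix(cohort.samples, DEFAULT_METRIC_COLUMNS)
pcs = compute_metadata_pcs(metrics, k=4)
for col in pcs.scores.columns:
    cohort.samples.df[col] = pcs.scores[col].to_numpy()

design = BurdenDesign(
    covariates=[f"pc{i}" for i in range(1, 11)] + ["sex"],
    metadata_pc_columns=["mpc1", "mpc2", "mpc3", "mpc4"],
)
comparison = ("controls_internal", "controls_external")
base = run_category_scan(cohort.variant_table, annotation, cohort.samples,
                         comparison, design, with_metadata_pcs=False)
adj = run_category_scan(cohort.variant_table, annotation, cohort.samples,
                        comparison, design, with_metadata_pcs=True)
print(f"state-scan lambda_GC without metadata PCs: {base.lambda_gc:.2f}")
print(f"state-scan lambda_GC with    metadata PCs: {adj.lambda_gc:.2f}")

repeats = run_category_scan(cohort.variant_table, annotation, cohort.samples,
                            comparison, design, systems=("repeat",))
sine = repeats.results.set_index("category").loc["SINE"]
print(f"strongest repeat category: {repeats.min_p_category()} "
      f"(p={sine['p']:.1e}, enriched in the external controls)")

from wgsburden import PowerQuery, or_for_power
q = PowerQuery(prevalence=0.01, n_case=1500, n_control=11_000,
               maf=0.01, alpha=5e-9)
print(f"detectable OR at 80% power: {or_for_power(q).or_at_target:.2f}")
```

prints

```
state-scan lambda_GC without metadata PCs: 1.42
state-scan lambda_GC with    metadata PCs: 1.06
strongest repeat category: SINE (p=3.1e-73, enriched in the external controls)
detectable OR at 80% power: 3.21
```

Read: the 200 state-level burden tests comparing the two control
groups are strongly inflated (λ = 1.42) because the deeper-sequenced
external study carries excess non-reference calls in SINE elements,
which partition unevenly across states; the scan pinpoints SINE as the
driver.  Adding the four sequencing-metadata PCs as covariates — which
capture the depth factor modulating the artifact — restores a
calibrated scan (λ = 1.06).  The last line is the analytic design
calculation: with 1,500 cases, 11,000 controls, a 1% risk allele and
genome-wide α = 5×10⁻⁹, only per-allele effects around OR ≈ 3.2 are
detectable at 80% power.

A command-line interface mirrors the library
(`wgsburden simulate | power | run-plan | report`); try
`wgsburden power --table` for the full detectable-OR design grid.

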