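# Methods

## Pipeline model and assumptions

The analysis treats each tumor stage as a condition to be contrasted with
a common normal group. Its core assumptions are:

* **DE filter.** Expression values are non-negative and roughly
  log-normal; comparisons are made on log2(x + pseudocount) with a Welch
  (unequal-variance) t-test. The fold change is the difference of group
  means of log2 values. A gene is DE iff |log2FC| ≥ `log2fc_threshold`
  (default 1, ties kept) **and** p < `p_threshold` (default 0.05,
  strict). No multiple-testing correction is applied inside the filter —
  this reproduces a raw-p screening design and is a documented
  limitation; a BH-adjusted column is emitted alongside for users.
  Genes with zero variance in both groups get p = 1 and are retained,
  never dropped.
* **Correlation filter.** The ceRNA mechanism predicts negative
  miRNA-target correlation. Edges require sample Pearson r strictly
  below `correlation_threshold` (default −0.1) computed on the stage's
  tumor samples (`correlation_sample_scope="stage_tumor"`; the
  alternative `"tumor_plus_normal"` is available because which samples
  enter the correlation is a genuinely open design point). Pairs are
  matched by sample-id intersection of the two matrices; pairs with a
  missing gene or a constant vector are skipped and counted, never fatal.
* **Partition.** CCEN = miRNAs in all stage networks plus their incident
  edges taken as the union over stages (a stage-agnostic object;
  `intersection_edges` is available); UCEN-s = miRNAs in exactly stage
  s plus their stage-s edges. miRNAs in 2–3 stages are a deliberately
  discarded middle class, reported as "shared" in the membership table.
  Node identity is the whitespace-trimmed gene-id string; no alias
  resolution is attempted.
* **Enrichment.** Upper-tail hypergeometric p per term (k ≥ 1 terms
  only; the empty-overlap upper tail is identically 1), computed via the
  scipy survival function and clamped to (0, 1]. The efficiency
  η = −log10(p)/n normalises by the **query-list size**: comparing lists
  of different sizes per gene is the statistic's purpose, and dividing
  by the fixed background size would make the comparison a monotone
  relabelling of −log10 p. `eta_norm="background_size"` restores the
  alternative reading.
* **Survival.** Kaplan–Meier product-limit estimate implemented directly
  from the recurrence (deaths processed before censorings at tied
  times); the unweighted log-rank test is delegated to lifelines and
  verified against a hand-coded observed-minus-expected oracle. The
  high/low split is at the median with ties to low (mean and quantile
  rules available; the split rule is not uniquely determined by the
  screening design, so it is configurable and recorded in output).
  Classification: "pan-stage" = p ≤ α in every evaluable stage (≥ 2
  evaluable), "stage-specific:s" = p ≤ α in s only; stages with < 4
  subjects are not evaluable and are excluded. α defaults to 0.05 and
  the classification is advisory — the full p-value matrix (including a
  pooled all-stages test) is always the primary output.

## Synthetic-data generator

`SimConfig`/`generate_dataset` emulate the structure the pipeline
assumes, not any particular cohort:

* **Expression**: per-gene baseline ~ N(class mean, 1) on the log2 scale
  (class means 7/9/10 for lncRNA/miRNA/mRNA), plus N(0, `noise_sd`²)
  noise; values are 2^x − 1 clipped at 0, so the downstream log2(x+1)
  recovers the Gaussian exactly (baselines sit far enough above 0 that
  clipping is negligible).
* **Planted triples**: in its active stages, a triple's miRNA is shifted
  by +`planted_log2fc` and its lncRNA/mRNA targets by
  −`planted_log2fc`; target noise additionally contains
  −slope × (miRNA noise) with slope = |r|/√(1−r²), which makes the
  population miRNA-target Pearson correlation exactly
  `planted_correlation` (default −0.6). `frac_stage_specific` of the
  triples are active in exactly one stage (round-robin over I–IV), the
  rest in all four — this is what makes CCEN/UCEN recovery testable.
* **Interaction table**: all planted pairs, plus `db_decoy_pairs` decoys
  drawn **only from genes with no planted effects** and deduplicated.
  Decoys are therefore true negative controls: the fraction of decoys
  surviving the full pipeline estimates its false-positive rate. (Pairs
  of two planted genes would instead measure the chance rate of the
  correlation filter among DE genes, which is bounded below by
  P(r̂ < −0.1 | r = 0) ≈ 22% at n = 60 and says nothing about
  specificity.)
* **Annotation**: `n_terms` GMT terms of `term_size` genes; the first
  `n_enriched_terms` are drawn from planted mRNAs (recorded as the
  enriched truth), the rest uniformly from all mRNAs.
* **Survival**: exponential event times with hazard
  `baseline_hazard` × exp(Σ_j β z_j), β = `hazard_coefficient` (default
  0.8 per SD), z_j the within-stage standardised log2 expression of each
  planted prognostic miRNA (pan markers act in all stages,
  stage-specific markers in theirs). Censoring times are uniform on
  (0, u) with u solved numerically so the expected censored fraction at
  baseline equals `censoring_rate` (default 0.3). Baseline hazard
  1/1000 per day puts median survival near 700 days, a realistic scale
  for an adenocarcinoma cohort.

Defaults (120/60/200 genes, 60 samples per group, 30 triples, log2FC 2,
r −0.6, noise SD 1) are chosen as a down-scaled but statistically
faithful stand-in for a TCGA-sized cohort: per-stage sample counts match
the smaller stages of such cohorts, and effect sizes are typical of
genes passing a |log2FC| ≥ 1 screen. What the generator does **not**
emulate: count-based noise (negative binomial, library-size effects),
batch effects, correlated co-expression modules beyond the planted
pairs, competing risks, or informative censoring. Passing recovery
tests therefore demonstrates correctness of the pipeline's logic and
calibration under its stated assumptions — not robustness to real-data
artefacts.

## Numerical and degenerate-input choices

* Hypergeometric p is computed by `scipy.stats.hypergeom.sf` (log-space
  internals) and clamped into (0, 1]; exactness is enforced by test
  against rational-arithmetic enumeration for all N ≤ 25.
* The η scaling identity η(p, c·s) = η(p, s)/c holds to machine
  precision (a few ulps); IEEE division is not associative, so bit-exact
  equality across operand orderings is not claimed.
* Welch test with both groups constant, or groups smaller than 2: p = 1
  with a warning flag.
* Constant expression vectors make Pearson r undefined: the pair is
  excluded and counted, not imputed.
* Median splits where every value above the cut is empty (heavy ties)
  fall back to a strict-inequality split so both groups are non-empty;
  fully constant vectors raise a "degenerate split" error.
* Ties at thresholds: |log2FC| = 1 is DE (inclusive); r = −0.1 exactly
  is **not** an edge (strict); survival ties at the split go to low.
* All writes are atomic (temp file + rename); two runs of the same
  configuration and seed produce byte-identical bundles (the manifest
  echoes the configuration except for the output directory itself).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline at
deliberately compact sizes chosen to give stable statistics while
keeping the whole suite fast on one CPU: the edge-recovery experiment
uses 50 planted triples, 500 decoys and 60 samples per group (planted
recovery 100%, decoy rate 0–1%); null calibrations use 1000 genes × 50
samples (DE) and 500 replicates × 50 subjects per arm (log-rank); the
survival screen uses 150 subjects per stage and 50 replicates; partition
invariants are fuzzed over 100 random configurations. These sizes are
the package's own reference conditions and are asserted in
`tests/test_acceptance.py`.

## Known limitations

* The raw-p DE filter and raw-p enrichment reporting inflate false
  positives by design; use the emitted BH columns for inference-grade
  claims.
* CCEN edge inheritance (union versus intersection over stages) changes
  CCEN edge counts on real data; both are implemented, union is the
  default, and the choice is recorded in the manifest.
* The UCEN "miRNA-linked mRNA" set equals the full UCEN mRNA set on any
  network this package builds (every node enters via an edge); the
  helper exists because externally supplied or manually edited networks
  can contain isolated mRNAs, and both counts are reported.
* The log-rank screen tests each miRNA and stage marginally; no
  multivariate adjustment (e.g. Cox models with covariates) is offered.
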