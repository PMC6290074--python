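# Methods

## The cross-cohort enrichment model

The package compares two log2 expression cohorts, A and B, measured on the
same platform but processed as separate datasets. The working model for a
raw value is

    x_ij = b_i + batch_d(j) + c_j + s_ij + e_ij

with probe baseline `b_i`, a dataset-level effect `batch_d` (location and
scale), a per-sample offset `c_j`, a biological signal `s_ij`, and noise.
The pipeline removes the nuisance terms in two steps:

* **Joint quantile normalization.** All samples of both datasets are pooled
  and mapped to one target distribution (per-rank mean of the sorted
  columns). Because the map depends only on within-sample ranks, any
  monotone per-sample or per-dataset transformation — location shifts,
  dynamic-range (scale) distortions, per-sample offsets — is removed
  entirely, while within-sample rank order is preserved. Ties receive the
  mean of the target values over their rank span; this keeps tied inputs
  tied and the output deterministic. Joint (rather than per-dataset)
  normalization is deliberate: only a shared target guarantees the two
  datasets end on compatible value ranges. Per-dataset normalization would
  leave the cross-dataset gap in place and is not offered.

* **Difference from a per-sample reference.** Probes whose mean and
  variance both lie at or below within-dataset quantile thresholds in both
  datasets form the reference set; `r_j` is the mean of these probes in
  sample j, and all downstream testing operates on `d_ij = x_ij − r_j`.
  The subtraction makes the statistic exactly invariant (in real
  arithmetic) to any per-sample additive offset; in floating point the
  invariance holds to ~1e-14 because the reference is recomputed from the
  shifted values. A *single* reference probe would make every result
  hostage to one measurement; the mean over the set is the robust
  realization of a per-sample anchor.

"Low variance and mean" is read as *both low*, i.e. at or below the q_v and
q_m quantiles within each dataset (defaults 0.25/0.25; scale-free, so no
absolute thresholds are needed). An alternative reading — variance low and
the two datasets' means *close* (|mean_A − mean_B| small) — is available as
`mode="matched"` in `select_reference_probes` for platforms whose absolute
intensities are not comparable, but is not the default. Selection requires
at least `min_reference` (default 10) qualifying probes and fails with
advice to enlarge the quantiles otherwise.

## Enrichment testing

The murine DEG list (consumed as input; its provenance thresholds |LFC| ≥
1.5 and adjusted p < 0.05 are recorded and re-applicable as a view) is
mapped mouse symbol → human ortholog(s) → probes annotated to that symbol in
*both* datasets. Mapping is purely table-driven: symbols are never
case-folded, because silent Title-case/UPPER-case conversion manufactures
false orthology. Genes lost at the ortholog or probe step are reported with
the failing stage.

Per probe, a two-sided Welch t-test compares the cohort-A and cohort-B
difference values. Welch rather than pooled variance is the default because
cohort sizes in the motivating application are badly unbalanced (hundreds
vs hundreds of samples in unequal proportion) and equality of variances is
unverified; a pooled mode exists behind a flag. Degenerate inputs follow
fixed conventions: both cohorts constant and equal → t = 0, p = 1; both
constant but unequal → p = 0 with flag "degenerate". Benjamini–Hochberg
q-values are always reported; the significance call defaults to raw
p < alpha (alpha = 0.05) with an `--fdr` switch, since a fixed ~150-probe
scan at nominal alpha is the convention the pipeline mirrors. Probe-level
results are retained verbatim; the gene-level signature uses the
any-concordant-probe rule (≥1 significant probe enriched in A, none in B;
genes significant in both directions are flagged discordant and excluded),
sorted by best probe p.

## Downstream statistics

* **Gene-set overrepresentation**: one-sided upper-tail hypergeometric
  P(X ≥ k) via the survival function (log-space internally; matches direct
  enumeration to better than 1e-10 for N ≤ 1000), BH-corrected across sets.
  The universe is always explicit and defaults to the measured genes (the
  probe annotation), not the genome — overlap p-values are meaningless
  without a declared universe, and web-tool defaults differ.
* **Subtype tests**: one-way ANOVA across all groups plus, per group, a
  one-sample t of the group's values against the mean of all *other*
  samples treated as a fixed constant (the "base-mean of the rest"). The
  constant-μ0 reading is the default; a two-sample alternative can be had
  by calling the enrichment test utilities directly.
* **Quartile survival**: the floor(n/4) highest-expression patients form
  the high stratum and the floor(n/4) lowest the low stratum (n = 150 →
  37 vs 37); middle patients are excluded from the comparison. Ties are
  broken by stable input order, with a warning when tied values straddle a
  cut. Kaplan–Meier curves come from the product-limit estimator
  (lifelines); the two-group log-rank uses the standard hypergeometric
  variance at each distinct event time, zero variance contribution when
  only one subject is at risk, no continuity correction, and returns
  per-group observed/expected counts. Zero total variance yields p = 1
  with a flag.

## Synthetic data generator

`simulate_two_cohort_expression` draws, per probe i and sample j,

    x_ij = mu_i + batch_d(j) + c_j + delta * 1[i in signature, cohort = A] + eps_ij

with `mu_i ~ U(baseline_mean_range)` for ordinary probes and
`N(reference_mean, reference_sd)` for the housekeeping pool (whose noise SD
is also `reference_sd`), `batch_A = 0`, `batch_B = batch_offset_B`,
`c_j ~ N(0, sample_offset_sd)`, `eps_ij ~ N(0, noise_sd)`; dataset B is
afterwards scaled about its grand mean by `batch_scale_B`, mimicking a
dynamic-range difference without moving the location twice. Defaults — 200
genes × 2 probes, 100 housekeeping probes, 40 + 40 samples, delta 1.0,
noise 0.5, batch offset 2.0, scale 1.15, sample-offset SD 0.3, baselines
U(6, 12) against a reference level of 4.0 ± 0.15 — are the study conditions
under which the pipeline is exercised and characterized: effect and noise
magnitudes typical of a planted microarray signature, and batch distortions
large relative to the effect so that harmonization is doing real work.

Each artifact (structure, matrix A, matrix B, DEG list, survival cohort)
draws from an independent substream keyed by `(master_seed, fixed_offset)`,
so outputs are reproducible without cross-artifact coupling. Mouse symbols
are Title-case (`Gene0001`), human upper-case (`GENE0001`), mapped 1→1 by
default with an optional 1→many fan-out to exercise the mapping stage.

The DEG simulator emits every signature gene plus the requested decoys,
all satisfying the provenance thresholds. The survival simulator draws
expression ~ N(0, 1), exponential event times with median
`baseline_median_days` and the hazard multiplied by `hazard_ratio` in the
top expression quartile, and independent exponential censoring whose
per-patient rate is calibrated so the expected censored fraction equals
`censor_rate` exactly.

What the generator does *not* emulate: probe-level (PM/MM) structure,
intensity-dependent variance, correlated probe blocks, missing values,
RNA-seq counts, or confounding of subtype with cohort. Passing tests
therefore demonstrate correctness of the computations and calibration under
a location/scale batch model with independent Gaussian noise — not
robustness to every artefact of real microarray data.

## Numerical and design choices

* Quantile normalization tie policy: mean of target values over the rank
  span (deterministic; tied inputs stay tied).
* Reference selection is permutation-invariant in probe order; quantiles
  are computed with the default linear interpolation.
* All TSV output is UTF-8, tab-delimited, '.' decimal, `\n` line endings;
  identical inputs give byte-identical outputs. GCT support is restricted
  to the 1.2 dialect.
* Readers fail fast on duplicate ids, non-numeric cells, missing and
  non-finite values; nothing is imputed.
* BH q-values via statsmodels; Welch p via the Student-t survival function
  at Welch–Satterthwaite df.
* Problem sizes in the test suite and acceptance script (e.g. 132-probe /
  12 + 12-sample fixtures; 2,400 aggregated null probes; 20 recovery
  seeds; 500 null survival cohorts of n = 100) are chosen so the full
  statistical characterization of the method runs in seconds while keeping
  binomial/Monte-Carlo error bars well inside the asserted bounds.

## Known limitations

* The reference-anchored statistic removes per-sample and per-dataset
  location effects but assumes the reference probes are unaffected by the
  biological contrast; a signature overlapping the housekeeping pool would
  bias `r_j`.
* Joint quantile normalization forces identical marginal distributions; a
  true global shift in expression between cohorts is removed along with the
  batch effect and cannot be detected by design.
* The probe→gene and mouse→human maps are explicit inputs; results inherit
  whatever annotation release the user supplies.
* Survival analysis is a two-stratum comparison; no Cox modelling or
  covariate adjustment is provided.
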