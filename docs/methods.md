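# Methods

This note records the statistical procedures, parameter defaults and
design choices behind `metaboclass`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Preprocessing

**Filter semantics.** "Present in a QC" means a non-missing cell in the
deconvolved table — the only reading available once peak picking is done
upstream. The presence threshold (default 0.10) is inclusive (a feature
seen in exactly 10 % of QCs is kept); the RSD threshold (default 40 %) is
strict (exactly 40 % is removed); RSD uses the sample (n−1) standard
deviation. RSD and %CV denote the same quantity here, so a single 40 %
threshold is applied. The blank-ratio threshold is a package default of
3-fold — common practice rather than a universal constant — and is
inclusive; a feature with zero blank signal is kept. Filters run in the
order presence → RSD → blank ratio and are idempotent on their survivors.

**Drift correction (QC-RLSC).** Per feature and batch, a degree-1 LOESS
curve (span default 0.75 of the batch's QCs, `statsmodels` lowess) is
fitted to QC intensity versus injection order; every injection in the
batch is divided by the curve linearly interpolated at its own injection
order, then the batch is rescaled so its QC median equals the feature's
grand QC median, which simultaneously restores the raw intensity scale
and aligns batches. The correction is feature-wise, the standard QC-RLSC
formulation. Batches with fewer than 4 usable QCs for a feature fall back
to a median-ratio correction with a warning; features whose interpolated
divisor is nonpositive are flagged and left uncorrected rather than
producing negative intensities. On an exactly linear drift with noiseless
QCs and full span the fit is exact, so corrected QC RSD is numerically
zero — the regression test for the implementation.

**Imputation.** Missing cells are filled per feature by a natural cubic
spline over a batch-major global injection index, so imputation follows
acquisition time on the drift-corrected scale; cells outside the observed
range take the nearest observed value and imputed values are clipped at
zero. Features with fewer than 4 observations fall back to their median.
Imputation runs after drift correction and before the log transform so
the spline operates on corrected, untransformed intensities.

**Transform and scaling.** Zeros are replaced by half the feature's
minimum positive value before log10 (the standard half-minimum surrogate,
avoiding −∞). Pareto scaling divides the centred feature by the square
root of its standard deviation; afterwards every feature has mean 0 and,
for nonconstant features, variance equal to its own pre-scaling SD — the
defining property the tests assert. Zero-variance features are set to 0
with a warning.

## PLS-DA and validation

**Model.** NIPALS PLS2 on mean-centred X and centred one-hot Y, X (and Y)
deflated each component, inner-loop convergence tolerance 1e−12, sign
fixed by making the largest-magnitude weight element positive. Prediction
uses B = W(PᵀW)⁻¹Cᵀ and the argmax rule; exact ties resolve to the
lexicographically first class label. Score vectors are mutually
orthogonal and weight vectors unit-norm (asserted). Predictions agree
with an independently implemented reference PLS to better than 1e−6 on
random small problems.

**Bootstrap validation.** Each of `n_boot` iterations draws n samples
with replacement as the training set; the out-of-bag (OOB) samples are
that iteration's test set, the natural reading of "test sets" in a
bootstrap-validated design. Degenerate draws (empty OOB, single-class
training) are redrawn. The component count A is selected per training set
by inner cross-validation minimising misclassification (defaults: 7-fold,
A ≤ 15; ties go to the smaller A). The desk-scale presets use 3-fold and
A ≤ 5, which on the synthetic tables loses nothing measurable and keeps
the 200-iteration runs to seconds. Setting `inner_cv_folds=0` fixes
A = `max_components`. Classwise rates and macro-averaged one-vs-rest
sensitivity/specificity are pooled over all OOB predictions; the paper
trail for a run is the full observed and null CCR vectors.

**Permutation null.** Each of `n_perm` null models permutes the labels
and runs one full bootstrap cycle (fresh training draw, OOB scoring), so
the null distribution reflects the same pipeline variance as the observed
one. Empirical p = (1 + #{null ≥ observed mean})/(n_perm + 1). A small
finite-sample caveat: because a class over-drawn into the bootstrap
training set is under-represented in its OOB set, the null mean CCR sits
slightly below 1/k (a percent or two at n = 60); the chance-level tests
therefore compare against 3 Monte-Carlo standard errors rather than an
exact equality.

**SMOTE.** Minority classes are upsampled to the majority size; each
synthetic point interpolates between a minority point and one of its k
(default 5) nearest minority neighbours, so synthetic points stay inside
the minority convex hull. Applying SMOTE globally before resampling leaks
synthetic copies of test information into training; the leak-free option
applies it inside each bootstrap training set only, and the default is
off. All three modes are exposed.

**Multiclass averaging.** Sensitivity and specificity are macro-averaged
one-vs-rest; single reported values for a multiclass model are not
well-defined otherwise, and macro averaging weights classes equally in an
imbalanced cohort.

## VIP and annotation

VIP is computed from a single full-data refit (not per-bootstrap), giving
one ranking per model; the mean-square-1 identity is asserted for every
fitted model. Selection modes are the conventional strict VIP > 1 rule
and the top 10 % of the descending ranking (ties broken by feature id for
determinism). Annotation is accurate-mass only against positive-mode
adducts at a default tolerance of 5 ppm (a package default; tighter
tolerances can only remove candidates — monotonicity is tested), so
candidates are putative (MSI level 3 at best). Fragment-spectrum library
matching for GC features is out of scope; GC annotations made by accurate
mass against the bundled table carry `msi_level="unknown"`. Plausibility
rules (e.g. a minimum retention time for lipid-class candidates on a
reversed-phase gradient) relabel failing candidates as
"unknown/unidentified" but never drop them.

## Enrichment

The enrichment chain is a compound-level simplification of mummichog:
feature→compound mapping keeps every candidate within tolerance, a
feature mapping to several compounds contributes each compound once
(deduplication prevents multi-adduct double counting), and the pathway
test is a one-tailed (enrichment-direction) Fisher's exact test on the
2×2 membership × significance table over the reference universe, the only
direction that makes an over-representation claim. Expected hits are
pathway_size·|sig|/|reference|; the enrichment ratio is
observed/expected. The resampling adjustment draws `n_resamples`
(default 1000) random feature sets of the observed significant size from
the full ranked list, repeats the identical mapping, and reports
(1 + #{null hits ≥ observed})/(n_resamples + 1). Isotope/empirical-
compound grouping and network-topology scoring of full mummichog are
deliberately not implemented. Fisher p-values match a brute-force
hypergeometric-sum oracle on every table with reference ≤ 30; under a
global null the BH-FDR hit rate stays within binomial noise of the
nominal level across repeated synthetic runs.

The bundled compound/pathway model (12 metabolites with exact
monoisotopic masses, 4 pathways) is a deliberately small built-in
reference for tests and demos, not a curated biological database; real
analyses should supply their own compound TSV and pathway JSON.

## Synthetic data: what it emulates and what it does not

The generator reproduces the downstream statistical structure the
analysis assumes: a three-group cohort (287/143/142 by default, ages
truncated-normal on [40, 86] with group-specific means, BMI and lifestyle
covariates), log-normal baseline intensities (baseline log10 means
uniform on [3.5, 6]), between-subject biological spread of 0.20 log10
units, pooled QCs as the cohort mean profile with 5 % technical CV,
blanks at 2 % of the median sample signal, per-batch multiplicative cubic
drift (amplitude default 0.15, positive-clipped) — smooth and low-order,
i.e. exactly LOESS-correctable — and logistic detection-limit
missingness calibrated to the requested overall rate (default 5 %).
Planted discriminative features receive a fixed log10 mean shift in one
group each, assigned round-robin, so every group carries its own
signature. Batch count (default 4; 2 in the small preset) and QC cadence
(every 10 injections) are presets, not facts about any particular study.

It does **not** model chromatographic peak shapes, isotope patterns,
correlated metabolite modules, retention-time drift, heteroscedastic
technical noise, or non-monotone batch effects. Passing recovery tests on
these tables shows the pipeline is correct and well-calibrated under its
own assumptions; it does not certify performance on any real cohort,
where effect sizes, correlation structure and drift are less benign.

**Problem sizes.** The "small" preset (300 features, 15 planted at a
0.3 log10 shift, 2 batches) with 200 bootstrap and 200 permutation
iterations is the package's desk-scale working configuration; the
"paper"-sized preset (1758 features, 4 batches) runs the same code and is
available where more realism is wanted. The acceptance script uses the
small preset throughout.

## Numerical conventions

Ratios in demographic summaries are rounded to a caller-chosen number of
decimals, since published tables are not consistent about precision; a
zero denominator reports `inf` with a warning rather than raising.
Welch's (unequal-variance) t-test is used for pairwise group comparisons;
"pairwise t-test" alone underdetermines the variant and Welch is the
safer default. Spearman correlations use tie-corrected ranks and
pairwise-complete observations with a minimum of 3 pairs per cell. All
stochastic procedures take explicit seeds; a single master seed is
sufficient to reproduce a full pipeline run bit-for-bit.

## Known limitations

* Annotation is accurate-mass only; identities are putative and
  many-to-many by construction.
* The bootstrap/permutation machinery refits thousands of models; at
  full published scale (1000 + 1000 iterations, thousands of features)
  a run is minutes-to-hours, not seconds.
* The enrichment resampling null conditions on the observed significant
  set size, not on the p-value threshold, matching the mummichog
  formulation; the two differ when the significance rule is external
  (e.g. VIP-based).
* Imputation assumes missingness is injection-order-smooth after drift
  correction; truly random missingness is handled but not modelled
  specially.
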