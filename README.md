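# metaboclass

Reusable, tested building blocks for a common study design in untargeted
serum metabolomics: classify subjects (for example by ethnicity or age
band) from LC–MS/GC–MS peak tables, find the metabolites that drive the
classification, and test which metabolic pathways they perturb — with the
quality control, validation and null models such a claim needs.

The package is aimed at metabolomics data analysts who receive deconvolved
feature tables (samples × features with m/z and retention time per
feature) from a multi-batch acquisition with interleaved pooled-QC and
blank injections, and want a scriptable, reproducible alternative to
point-and-click workflows.

## What it implements

**Preprocessing (QC-driven).** Features are kept only if detected in at
least 10 % of pooled-QC injections and if their QC relative standard
deviation is below 40 %; a blank-ratio filter (default 3-fold) removes
carry-over signal. Within-batch signal drift is divided out per feature by
a LOESS curve fitted to the pooled QCs over injection order (QC-RLSC),
batches are aligned on the grand QC median, missing cells are filled by a
natural cubic spline over injection order, and the matrix is
log10-transformed and Pareto-scaled, x′ = (x − x̄)/√s.

**Classification (PLS-DA).** A self-contained NIPALS PLS2 fits one-hot
class indicators Y on X; samples are classified by argmax over the
predicted indicator columns. Validation follows the bootstrap/permutation
recipe: for each of n_boot resamples the out-of-bag samples form the test
set and its correct classification rate (CCR) is recorded; n_perm null
models with permuted labels give the chance distribution and an empirical
p-value (1 + #{null ≥ observed})/(n_perm + 1). The component count is
chosen by inner cross-validation inside each resample. Class imbalance can
be handled with SMOTE, applied globally or (leak-free) inside each
training set only.

**Feature selection.** Variable importance in projection,
VIP_j = √( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a ), with
SSY_a = ‖c_a‖²(t_aᵀt_a); mean(VIP²) = 1 by construction. Selection by
VIP > 1 or by the top 10 % of the ranking; selected features are putatively
annotated by accurate-mass matching against positive-mode adducts
([M+H]⁺, [M+Na]⁺, [M+K]⁺, [M+NH₄]⁺) at a ppm tolerance, with declarative
plausibility rules that demote chemically implausible hits to
"unknown/unidentified".

**Pathway enrichment (mummichog-style).** Features are ranked by
Mann–Whitney U (two groups) or Kruskal–Wallis H (three or more);
significant features are mapped to candidate compounds through the same
adduct matching; each pathway gets a one-tailed Fisher's exact p, an
empirical resampling p (random feature sets of the same size pushed
through the same mapping), a Benjamini–Hochberg q and an enrichment ratio
observed/expected.

**Synthetic data.** `metaboclass.synthgen` generates cohorts (three
groups of 287/143/142 men aged 40–86 by default) and multi-batch peak
tables with smooth per-batch drift, pooled-QC and blank injections,
detection-limit missingness and a planted subset of class-discriminative
features, with full ground truth for recovery testing.

## Worked example

```python
from metaboclass.pipeline import run_pipeline

r = run_pipeline(preset_name="small", seed=7, n_boot=50, n_perm=50)
c, v = r["classification"], r["vip"]
print(f"mean OOB CCR: {c['mean_ccr']:.2f}%  (null p = {c['empirical_p']:.4f})")
print(f"sensitivity {c['sensitivity']:.1f}%  specificity {c['specificity']:.1f}%")
print(f"planted recovered in top-10% VIP: {v['n_recovered_in_top10']}/{v['n_planted_surviving']}")
```

prints

```
mean OOB CCR: 92.64%  (null p = 0.0196)
sensitivity 91.4%  specificity 95.9%
planted recovered in top-10% VIP: 15/15
```

i.e. on a synthetic 572-subject cohort with 300 features of which 15 carry
a 0.3 log10 group shift, the bootstrap-validated three-class model
classifies out-of-bag samples at ~93 % CCR, every permutation null falls
below the observed mean (p = 1/(n_perm+1)), and all planted features are
recovered in the top decile of the VIP ranking.

The same stages are available from the shell:

```sh
metaboclass simulate --preset small --seed 7 --out run.csv
metaboclass preprocess run.csv processed.csv --report prep.json
metaboclass classify processed.csv --target ethnicity --n-boot 1000 --n-perm 1000 --out ccr.json
metaboclass rank processed.csv --target ethnicity --out ranking.tsv
metaboclass enrich run.csv --target ethnicity --out enrichment.tsv
metaboclass summarize run.samples.csv --out demographics.json
```

## File formats

* **Intensity CSV** — rows = samples (first column `sample_id`), columns =
  feature ids, empty cells or `NA` = missing. Sidecars written next to it:
  `<stem>.samples.csv` (columns `sample_type` ∈ {sample, QC, blank},
  `batch`, `injection_order`, `ethnicity`, `age`, `age_band`, plus any
  covariates), `<stem>.features.csv` (`feature_id`, `mz`, `rt`,
  `platform`) and `<stem>.provenance.json` (applied transforms).
* **Compound table TSV** — `compound_id`, `name`, `monoisotopic_mass`
  (neutral, Da), `pathway_ids` (semicolon-separated).
* **Pathway model JSON** — `{"pathways": {id: {"name", "compounds"}},
  "reference_universe": [...]}`. A small built-in table of 12 metabolites
  over 4 pathways ships with the package for testing and demos.

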