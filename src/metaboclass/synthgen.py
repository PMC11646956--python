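"""Synthetic cohorts and peak tables with known ground truth.

The generator emulates the downstream shape of a multi-batch untargeted
LC-MS/GC-MS serum study: a cohort of men aged 40-86 in three ethnic groups,
feature tables with log-normal baseline intensities, smooth per-batch
signal drift, interleaved pooled-QC injections, blank injections, a planted
subset of class-discriminative features, and intensity-dependent missing
values.  Every draw descends from a single seed, so identical seeds yield
bit-identical tables.

The drift model is a per-batch cubic polynomial in injection order with
random coefficients scaled by ``drift_amplitude`` -- smooth and low-order,
which is exactly the regime a QC-based LOESS correction assumes.
Missingness follows a logistic probability that decreases with
log-intensity, mimicking detection-limit censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .peakio import Feature, FeatureTable, SampleRecord

__all__ = [
    "CohortSpec",
    "RunSpec",
    "EffectSpec",
    "SyntheticTruth",
    "generate_cohort",
    "generate_peak_table",
    "age_band",
    "PRESETS",
    "preset",
]

AGE_MIN, AGE_MAX = 40.0, 86.0

#: cohort defaults: three ethnic groups with the study's sample sizes and
#: age/BMI means +- SD (White European, South Asian, African Caribbean)
DEFAULT_GROUP_SIZES = {"WE": 287, "SA": 143, "AC": 142}
DEFAULT_AGE = {"WE": (63.66, 10.68), "SA": (56.97, 11.12), "AC": (54.01, 10.63)}
DEFAULT_BMI = {"WE": (27.47, 3.89), "SA": (27.75, 3.70), "AC": (27.80, 4.86)}


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class CohortSpec:
    """Cohort design: per-group sizes and age/BMI distributions."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    age_mean_sd: dict = field(default_factory=lambda: dict(DEFAULT_AGE))
    bmi_mean_sd: dict = field(default_factory=lambda: dict(DEFAULT_BMI))
    seed: int = 0

    def validate(self):
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ConfigurationError(f"group {g!r}: count must be > 0, got {n}")
        for name, d in (("age", self.age_mean_sd), ("bmi", self.bmi_mean_sd)):
            for g in self.group_sizes:
                if g in d and d[g][1] <= 0:
                    raise ConfigurationError(f"{name} SD for group {g!r} must be > 0")
        return self


@dataclass
class RunSpec:
    """Acquisition-run design: feature count, batches, QC cadence, drift and noise."""

    n_features: int = 1758
    n_batches: int = 4
    qc_interval: int = 10  # sample injections between pooled-QC injections
    drift_amplitude: float = 0.15  # relative amplitude of the within-batch drift
    noise_cv: float = 0.05  # technical CV applied to QC (and sample) replicates
    bio_sd_log10: float = 0.20  # biological between-subject SD on the log10 scale
    missing_rate: float = 0.05
    blank_level: float = 0.02  # blank signal as a fraction of the median sample signal
    mz_range: tuple = (70.0, 1000.0)
    rt_range: tuple = (0.5, 12.0)
    platform: str = "LC"
    n_blanks_per_batch: int = 2

    def validate(self):
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.qc_interval < 2:
            raise ConfigurationError("qc_interval must be >= 2")
        if self.n_features < 1 or self.n_batches < 1:
            raise ConfigurationError("n_features and n_batches must be >= 1")
        return self


@dataclass
class EffectSpec:
    """Planted class effects: which features discriminate which groups."""

    n_discriminative: int = 0
    effect_log10: float = 0.3  # per-class mean shift on the log10 scale
    affected_classes: tuple = ("WE", "SA", "AC")

    def validate(self, n_features):
        if self.n_discriminative > n_features:
            raise ConfigurationError(
                f"n_discriminative ({self.n_discriminative}) exceeds "
                f"n_features ({n_features})"
            )
        return self


@dataclass
class SyntheticTruth:
    """Ground truth of one generated table: enough to reconstruct expectations."""

    planted_features: list  # feature ids, each recorded exactly once
    planted_class: dict  # feature id -> class whose mean is shifted
    class_labels: dict  # sample id -> group
    drift_coefficients: dict  # batch -> cubic coefficients (highest degree first)
    baseline_log10: dict  # feature id -> baseline mean on log10 scale
    seed: int = 0


def age_band(age, scheme="band10"):
    """Derive an age-band label: ``band10`` gives 10-year bands, ``band2`` <60 vs >=60."""
    if scheme == "band2":
        return "<60" if age < 60 else ">=60"
    if age < 50:
        return "40-49"
    if age < 60:
        return "50-59"
    if age < 70:
        return "60-69"
    return ">=70"


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> list:
    """Draw a cohort of study subjects.

    Ages are truncated-normal on [40, 86]; per-group counts match the spec
    exactly; both two-band and 10-year age-band labels are derived (the
    10-year band is stored on the record, the two-band label in
    ``covariates['age2']``).  Reproducible for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = []
    for group in sorted(spec.group_sizes):
        n = spec.group_sizes[group]
        amean, asd = spec.age_mean_sd.get(group, (60.0, 10.0))
        bmean, bsd = spec.bmi_mean_sd.get(group, (27.0, 4.0))
        ages = _truncnorm(rng, amean, asd, AGE_MIN, AGE_MAX, n)
        bmis = np.maximum(rng.normal(bmean, bsd, n), 15.0)
        drinker = rng.random(n) < 0.6
        smoker = rng.random(n) < 0.12
        morbid = rng.random(n) < 0.45
        for i in range(n):
            records.append(
                SampleRecord(
                    sample_id=f"{group}_{i + 1:04d}",
                    sample_type="sample",
                    ethnicity=group,
                    age=float(ages[i]),
                    age_band=age_band(ages[i]),
                    covariates={
                        "age2": age_band(ages[i], "band2"),
                        "bmi": float(bmis[i]),
                        "alcohol": int(drinker[i]),
                        "smoking": int(smoker[i]),
                        "morbid": int(morbid[i]),
                    },
                )
            )
    return records


def _drift_factor(coeffs, x):
    """Multiplicative drift at normalised injection position x in [0, 1]."""
    return np.maximum(np.polyval(coeffs, x) + 1.0, 0.2)


def generate_peak_table(cohort, run: RunSpec, effects: EffectSpec, seed=0):
    """Generate one platform's peak table plus its ground truth.

    Sample intensities are log-normal around a per-feature baseline with
    biological spread ``bio_sd_log10``; pooled-QC rows are the cohort mean
    profile with only technical noise; blanks sit at ``blank_level`` of the
    median sample signal.  Planted features get a mean shift of
    ``effect_log10`` (log10 scale) in one affected class each (assigned
    round-robin over ``effects.affected_classes``).  A per-batch cubic drift
    multiplies every injection, and low-intensity cells go missing with
    higher probability such that the overall missing fraction is close to
    ``run.missing_rate``.
    """
    if not cohort:
        raise ConfigurationError("cohort must be nonempty")
    run.validate()
    effects.validate(run.n_features)
    root = np.random.default_rng(seed)
    rng_feat, rng_assign, rng_noise, rng_drift, rng_miss = root.spawn(5)

    p = run.n_features
    prefix = run.platform
    fids = [f"{prefix}_{j + 1:05d}" for j in range(p)]
    mz = np.sort(rng_feat.uniform(*run.mz_range, p))
    rt = rng_feat.uniform(*run.rt_range, p)
    feats = [Feature(fids[j], float(mz[j]), float(rt[j]), prefix) for j in range(p)]
    base_log10 = rng_feat.uniform(3.5, 6.0, p)

    # planted effects: feature j shifted in one class, round-robin
    planted_idx = rng_feat.choice(p, size=effects.n_discriminative, replace=False)
    planted_idx = np.sort(planted_idx)
    planted_class = {
        fids[j]: effects.affected_classes[k % len(effects.affected_classes)]
        for k, j in enumerate(planted_idx)
    }

    n_sub = len(cohort)
    order_in_cohort = rng_assign.permutation(n_sub)

    # build the injection sequence: batches of roughly equal size, each
    # starting/ending with a blank, QC after every qc_interval samples
    per_batch = int(np.ceil(n_sub / run.n_batches))
    rows = []  # (kind, payload) where payload is a cohort index or None
    batch_of, order_of = [], []
    cursor = 0
    for b in range(1, run.n_batches + 1):
        batch_subjects = order_in_cohort[cursor : cursor + per_batch]
        cursor += per_batch
        seq = [("blank", None), ("QC", None)]
        for i, ci in enumerate(batch_subjects):
            seq.append(("sample", ci))
            if (i + 1) % run.qc_interval == 0:
                seq.append(("QC", None))
        seq.append(("QC", None))
        seq.append(("blank", None))
        for k, item in enumerate(seq):
            rows.append(item)
            batch_of.append(b)
            order_of.append(k + 1)

    n_rows = len(rows)
    class_of = np.array(
        [cohort[ci].ethnicity if kind == "sample" else "" for kind, ci in rows]
    )

    # mean (log10) profile per row before drift/noise
    mu = np.tile(base_log10, (n_rows, 1))
    for fid, cls in planted_class.items():
        j = fids.index(fid)
        mu[class_of == cls, j] += effects.effect_log10

    log10_int = np.empty((n_rows, p))
    kinds = np.array([k for k, _ in rows])
    is_sample = kinds == "sample"
    is_qc = kinds == "QC"
    is_blank = kinds == "blank"

    # biological spread for study samples only
    log10_int[is_sample] = mu[is_sample] + rng_noise.normal(
        0.0, run.bio_sd_log10, (is_sample.sum(), p)
    )
    # pooled QC = cohort mean profile (planted shifts averaged in by class share)
    class_share = {
        g: np.mean(class_of[is_sample] == g) for g in set(class_of[is_sample])
    }
    qc_mu = base_log10.copy()
    for fid, cls in planted_class.items():
        qc_mu[fids.index(fid)] += effects.effect_log10 * class_share.get(cls, 0.0)
    log10_int[is_qc] = qc_mu
    median_sample = np.median(10 ** mu[is_sample], axis=0)
    log10_int[is_blank] = np.log10(np.maximum(run.blank_level * median_sample, 1e-6))

    inten = 10.0 ** log10_int
    # technical multiplicative noise on every injection
    if run.noise_cv > 0:
        sigma = np.sqrt(np.log1p(run.noise_cv**2))
        inten *= rng_noise.lognormal(-0.5 * sigma**2, sigma, inten.shape)

    # per-batch cubic drift, multiplicative, shared by all features
    drift_coeffs = {}
    batch_arr = np.asarray(batch_of)
    order_arr = np.asarray(order_of, dtype=float)
    for b in range(1, run.n_batches + 1):
        raw = rng_drift.uniform(-1.0, 1.0, 4)
        raw[-1] = 0.0  # constant term absorbed into the baseline
        x = np.linspace(0, 1, 50)
        scale = np.max(np.abs(np.polyval(raw, x))) or 1.0
        coeffs = raw / scale * run.drift_amplitude
        drift_coeffs[b] = coeffs.tolist()
        sel = batch_arr == b
        xnorm = (order_arr[sel] - 1) / max(order_arr[sel].max() - 1, 1)
        inten[sel] *= _drift_factor(coeffs, xnorm)[:, None]

    # detection-limit missingness: logistic in log-intensity, calibrated so
    # the mean probability over non-blank cells equals missing_rate
    if run.missing_rate > 0:
        nb = ~is_blank
        z = np.log10(np.maximum(inten[nb], 1e-12))
        w = 1.0 / (1.0 + np.exp((z - np.median(z)) / 0.5))
        prob = np.minimum(run.missing_rate * w / w.mean(), 1.0)
        drop = rng_miss.random(prob.shape) < prob
        block = inten[nb]
        block[drop] = np.nan
        inten[nb] = block

    samples = []
    counters = {"QC": 0, "blank": 0}
    for i, (kind, ci) in enumerate(rows):
        if kind == "sample":
            rec = cohort[ci]
            samples.append(
                SampleRecord(
                    sample_id=rec.sample_id,
                    sample_type="sample",
                    batch=int(batch_of[i]),
                    injection_order=int(order_of[i]),
                    ethnicity=rec.ethnicity,
                    age=rec.age,
                    age_band=rec.age_band,
                    covariates=dict(rec.covariates),
                )
            )
        else:
            counters[kind] += 1
            samples.append(
                SampleRecord(
                    sample_id=f"{kind}_{counters[kind]:03d}",
                    sample_type=kind,
                    batch=int(batch_of[i]),
                    injection_order=int(order_of[i]),
                )
            )

    table = FeatureTable.from_records(inten, feats, samples)
    table.log(
        "simulate",
        platform=run.platform,
        n_features=p,
        n_batches=run.n_batches,
        n_planted=effects.n_discriminative,
        seed=seed,
    )
    truth = SyntheticTruth(
        planted_features=[fids[j] for j in planted_idx],
        planted_class=planted_class,
        class_labels={cohort[ci].sample_id: cohort[ci].ethnicity for ci in range(n_sub)},
        drift_coefficients=drift_coeffs,
        baseline_log10=dict(zip(fids, base_log10.tolist())),
        seed=seed,
    )
    return table, truth


# -- presets ------------------------------------------------------------------

PRESETS = {
    # full-size study: two platforms' feature counts, 4 batches
    "paper": dict(
        cohort=dict(group_sizes=dict(DEFAULT_GROUP_SIZES)),
        run=dict(n_features=1758, n_batches=4, qc_interval=10),
        effects=dict(n_discriminative=88, effect_log10=0.3),
    ),
    # same cohort, reduced feature panel for desk-scale runs
    "small": dict(
        cohort=dict(group_sizes=dict(DEFAULT_GROUP_SIZES)),
        run=dict(n_features=300, n_batches=2, qc_interval=10),
        effects=dict(n_discriminative=15, effect_log10=0.3),
    ),
}


def preset(name, seed=0):
    """Instantiate the (CohortSpec, RunSpec, EffectSpec) triple of a named preset."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return (
        CohortSpec(seed=seed, **cfg["cohort"]),
        RunSpec(**cfg["run"]),
        EffectSpec(**cfg["effects"]),
    )
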