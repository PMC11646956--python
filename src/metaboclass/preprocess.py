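"""QC-driven filtering, signal-drift correction, imputation and scaling.

The preprocessing chain mirrors standard practice for pooled-QC untargeted
metabolomics:

1. presence filter  -- drop features detected in fewer than 10% of pooled
   QC injections (boundary inclusive: "at least 10%" keeps exactly 10%);
2. RSD filter       -- keep features whose QC relative standard deviation
   is strictly below 40% (sample SD);
3. blank-ratio filter -- keep features whose mean study-sample signal is at
   least ``blank_ratio_min``-fold the mean blank signal (default 3-fold);
4. drift correction -- per feature and batch, a LOESS curve is fitted to
   QC intensities over injection order and every injection is divided by
   the interpolated curve (QC-RLSC); batches are then rescaled onto the
   grand QC median;
5. cubic-spline imputation of missing cells over injection order;
6. log10 transform (zeros replaced by half the feature's minimum positive
   value first);
7. Pareto scaling: centre, divide by the square root of the SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from statsmodels.nonparametric.smoothers_lowess import lowess

from .peakio import FeatureTable, FeatureTableError

__all__ = [
    "FilterConfig",
    "DriftModel",
    "qc_presence_filter",
    "qc_rsd_filter",
    "blank_ratio_filter",
    "drift_correct",
    "impute_missing",
    "log10_transform",
    "pareto_scale",
    "run_preprocess",
    "qc_rsd",
]


@dataclass
class FilterConfig:
    """Thresholds of the three QC-based feature filters."""

    qc_presence_min: float = 0.10  # fraction of QCs a feature must appear in
    qc_rsd_max: float = 40.0  # %RSD across QCs, strict upper bound
    blank_ratio_min: float = 3.0  # sample/blank fold change, inclusive lower bound
    loess_span: float = 0.75  # LOESS span as a fraction of QCs per batch

    def __post_init__(self):
        if not (0 < self.qc_presence_min <= 1):
            raise ValueError("qc_presence_min must be in (0, 1]")
        if self.qc_rsd_max <= 0:
            raise ValueError("qc_rsd_max must be > 0")
        if self.blank_ratio_min < 1:
            raise ValueError("blank_ratio_min must be >= 1")


@dataclass
class DriftModel:
    """Fitted QC trends: (feature, batch) -> curve over injection order."""

    curves: dict = field(default_factory=dict)  # (feature_id, batch) -> (orders, fitted)
    reference_level: dict = field(default_factory=dict)  # feature_id -> grand QC median
    skipped: list = field(default_factory=list)  # features with nonpositive divisors
    span: float = 0.75


def qc_rsd(table: FeatureTable) -> pd.Series:
    """Per-feature %RSD (100*sd/mean, sample SD) across pooled-QC rows."""
    qc = table.intensities.loc[table.qc_mask]
    mean = qc.mean(axis=0, skipna=True)
    sd = qc.std(axis=0, ddof=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 100.0 * sd / mean


def qc_presence_filter(table: FeatureTable, config: FilterConfig | None = None):
    """Drop features not detected in at least ``qc_presence_min`` of QC rows."""
    config = config or FilterConfig()
    if not table.qc_mask.any():
        raise FeatureTableError(
            "qc_presence_filter requires at least one QC row; add pooled-QC "
            "injections to the sample metadata (sample_type='QC')"
        )
    qc = table.intensities.loc[table.qc_mask]
    presence = qc.notna().mean(axis=0)
    removed = presence.index[presence < config.qc_presence_min].tolist()
    out = table.drop_features(removed)
    out.log(
        "qc_presence_filter",
        threshold=config.qc_presence_min,
        removed=len(removed),
        kept=out.n_features,
    )
    return out, removed


def qc_rsd_filter(table: FeatureTable, config: FilterConfig | None = None):
    """Keep features with QC %RSD strictly below ``qc_rsd_max``.

    Features with fewer than two non-missing QC values, or a zero QC mean,
    are dropped with reason "insufficient QC support".
    """
    config = config or FilterConfig()
    qc = table.intensities.loc[table.qc_mask]
    n_obs = qc.notna().sum(axis=0)
    mean = qc.mean(axis=0, skipna=True)
    rsd = qc_rsd(table)

    insufficient = (n_obs < 2) | (mean == 0) | ~np.isfinite(rsd)
    too_variable = ~insufficient & (rsd >= config.qc_rsd_max)
    removed = rsd.index[insufficient | too_variable].tolist()
    out = table.drop_features(removed)
    out.log(
        "qc_rsd_filter",
        threshold=config.qc_rsd_max,
        removed=len(removed),
        removed_insufficient_support=int(insufficient.sum()),
        kept=out.n_features,
    )
    return out, removed


def blank_ratio_filter(table: FeatureTable, config: FilterConfig | None = None):
    """Keep features whose mean sample signal is >= ``blank_ratio_min`` x mean blank signal.

    A feature with no blank signal at all (blank mean 0 or all-missing) is
    kept.  With no blank rows the filter is skipped with a warning.
    """
    config = config or FilterConfig()
    if not table.blank_mask.any():
        warnings.warn("no blank rows: blank-ratio filter skipped", stacklevel=2)
        out = table.copy()
        out.log("blank_ratio_filter", skipped="no blank rows", kept=out.n_features)
        return out, []
    smean = table.intensities.loc[table.sample_mask].mean(axis=0, skipna=True)
    bmean = table.intensities.loc[table.blank_mask].mean(axis=0, skipna=True)
    bmean = bmean.fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = smean / bmean
    keep = (bmean == 0) | (ratio >= config.blank_ratio_min)
    removed = keep.index[~keep].tolist()
    out = table.drop_features(removed)
    out.log(
        "blank_ratio_filter",
        threshold=config.blank_ratio_min,
        removed=len(removed),
        kept=out.n_features,
    )
    return out, removed


def _loess_curve(orders, values, span):
    """LOESS (degree-1 lowess) fit of values vs orders, interpolated linearly."""
    fit = lowess(values, orders, frac=span, it=0, return_sorted=True)
    return fit[:, 0], fit[:, 1]


def drift_correct(table: FeatureTable, span: float = 0.75, min_qc_per_batch: int = 4):
    """QC-based LOESS signal correction (QC-RLSC).

    Per feature and batch a LOESS trend is fitted to the pooled-QC
    intensities over injection order; every injection in the batch is
    divided by the trend interpolated at its own injection order and the
    batch is rescaled onto the feature's grand QC median, which also aligns
    batches with one another.  Batches with fewer than ``min_qc_per_batch``
    usable QCs fall back to a median-ratio correction (with a warning);
    features whose interpolated divisor is nonpositive are flagged and left
    uncorrected.
    """
    out = table.copy()
    X = out.intensities
    qc_mask = out.qc_mask
    if not qc_mask.any():
        raise FeatureTableError("drift_correct requires pooled-QC rows")
    batches = out.samples["batch"].to_numpy()
    orders = out.samples["injection_order"].to_numpy(dtype=float)
    model = DriftModel(span=span)
    vals = X.to_numpy(dtype=float, copy=True)
    grand_qc_median = np.nanmedian(vals[qc_mask], axis=0)
    model.reference_level = dict(zip(X.columns, grand_qc_median.tolist()))
    fallback_batches = set()

    corrected = vals.copy()
    skip = np.zeros(vals.shape[1], dtype=bool)
    for b in np.unique(batches):
        in_b = batches == b
        qc_b = in_b & qc_mask
        ord_b = orders[in_b]
        for j, fid in enumerate(X.columns):
            if skip[j]:
                continue
            qv = vals[qc_b, j]
            qo = orders[qc_b]
            ok = np.isfinite(qv)
            if ok.sum() < min_qc_per_batch:
                # median-ratio fallback for this feature in this batch
                med = np.nanmedian(qv[ok]) if ok.any() else np.nan
                if not np.isfinite(med) or med <= 0:
                    skip[j] = True
                    continue
                fallback_batches.add(int(b))
                corrected[in_b, j] = vals[in_b, j] / med * grand_qc_median[j]
                continue
            xs, ys = _loess_curve(qo[ok], qv[ok], span)
            divisor = np.interp(ord_b, xs, ys)
            if np.any(divisor <= 0):
                skip[j] = True
                continue
            model.curves[(fid, int(b))] = (xs.tolist(), ys.tolist())
            corrected[in_b, j] = vals[in_b, j] / divisor

    # between-batch normalisation: bring every batch's QC median to the
    # grand QC median on the original intensity scale
    for b in np.unique(batches):
        in_b = batches == b
        qc_b = in_b & qc_mask
        for j in range(vals.shape[1]):
            if skip[j]:
                continue
            med_b = np.nanmedian(corrected[qc_b, j])
            if np.isfinite(med_b) and med_b > 0:
                corrected[in_b, j] *= grand_qc_median[j] / med_b

    corrected[:, skip] = vals[:, skip]
    model.skipped = [X.columns[j] for j in np.where(skip)[0]]
    if fallback_batches:
        warnings.warn(
            f"batches {sorted(fallback_batches)} had < {min_qc_per_batch} QCs "
            "for some features; median-ratio fallback used",
            stacklevel=2,
        )
    out.intensities = pd.DataFrame(corrected, index=X.index, columns=X.columns)
    out.log(
        "drift_correct",
        span=span,
        skipped_features=len(model.skipped),
        fallback_batches=sorted(fallback_batches),
    )
    return out, model


def impute_missing(table: FeatureTable):
    """Replace missing cells by a natural cubic spline over injection order.

    The spline is fitted per feature to the observed values ordered by a
    global injection index (batch-major).  Missing cells inside the
    observed range take the spline value; cells outside it take the nearest
    observed value; imputed values are clipped at zero.  Features with
    fewer than 4 observations fall back to the feature median.
    """
    out = table.copy()
    X = out.intensities
    vals = X.to_numpy(dtype=float, copy=True)
    # batch-major global ordering so the spline runs along acquisition time
    global_order = np.lexsort(
        (out.samples["injection_order"].to_numpy(), out.samples["batch"].to_numpy())
    )
    pos = np.empty(len(global_order))
    pos[global_order] = np.arange(len(global_order), dtype=float)

    n_fallback = 0
    for j in range(vals.shape[1]):
        col = vals[:, j]
        miss = ~np.isfinite(col)
        if not miss.any():
            continue
        obs = ~miss
        if obs.sum() < 4:
            fill = np.nanmedian(col) if obs.any() else 0.0
            col[miss] = fill
            n_fallback += 1
            continue
        xo = pos[obs]
        srt = np.argsort(xo)
        xo, yo = xo[srt], col[obs][srt]
        spline = CubicSpline(xo, yo, bc_type="natural")
        xm = pos[miss]
        filled = np.where(
            xm < xo[0], yo[0], np.where(xm > xo[-1], yo[-1], spline(xm))
        )
        col[miss] = np.maximum(filled, 0.0)
    out.intensities = pd.DataFrame(vals, index=X.index, columns=X.columns)
    out.log("impute_missing", method="cubic_spline", median_fallbacks=n_fallback)
    return out


def log10_transform(table: FeatureTable):
    """Elementwise log10; zeros first replaced by half the feature's minimum positive value."""
    out = table.copy()
    vals = out.intensities.to_numpy(dtype=float, copy=True)
    n_zero = 0
    for j in range(vals.shape[1]):
        col = vals[:, j]
        zero = col == 0
        if zero.any():
            positive = col[np.isfinite(col) & (col > 0)]
            surrogate = positive.min() / 2.0 if positive.size else 1.0
            col[zero] = surrogate
            n_zero += int(zero.sum())
    if np.nanmin(vals, initial=np.inf) < 0:
        raise FeatureTableError("log10_transform requires nonnegative intensities")
    out.intensities = pd.DataFrame(
        np.log10(vals), index=out.intensities.index, columns=out.intensities.columns
    )
    out.log("log10_transform", zero_cells_substituted=n_zero)
    return out


def pareto_scale(table: FeatureTable):
    """Pareto scaling: x' = (x - mean) / sqrt(sd), per feature (sample SD).

    Intermediate between unit-variance and no scaling: large fold changes
    are damped but not flattened.  Zero-variance features are set to 0.
    """
    out = table.copy()
    X = out.intensities
    mean = X.mean(axis=0, skipna=True)
    sd = X.std(axis=0, ddof=1, skipna=True)
    constant = (sd == 0) | ~np.isfinite(sd)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance features set to 0 by Pareto scaling",
            stacklevel=2,
        )
    denom = np.sqrt(sd.where(~constant, 1.0))
    scaled = (X - mean) / denom
    scaled.loc[:, constant] = 0.0
    out.intensities = scaled
    out.log("pareto_scale", zero_variance_features=int(constant.sum()))
    return out


def run_preprocess(table: FeatureTable, config: FilterConfig | None = None):
    """Full preprocessing chain; returns the table plus a per-stage report.

    Order: presence filter, RSD filter, blank-ratio filter, drift
    correction, spline imputation, log10, Pareto scaling.
    """
    config = config or FilterConfig()
    report = {"input_features": table.n_features}
    t, removed = qc_presence_filter(table, config)
    report["qc_presence_removed"] = len(removed)
    t, removed = qc_rsd_filter(t, config)
    report["qc_rsd_removed"] = len(removed)
    t, removed = blank_ratio_filter(t, config)
    report["blank_ratio_removed"] = len(removed)
    t, drift = drift_correct(t, span=config.loess_span)
    report["drift_skipped"] = len(drift.skipped)
    t = impute_missing(t)
    t = log10_transform(t)
    t = pareto_scale(t)
    report["output_features"] = t.n_features
    t.log("run_preprocess", **report)
    return t, report
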