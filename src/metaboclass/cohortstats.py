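"""Cohort demographic summaries, metadata correlations and group comparisons.

Summaries follow the conventional demographics-table layout: per-group n,
mean +- SD for continuous covariates, and "a : b (ratio)" blocks for
binary covariates such as drinker/non-drinker or morbid/healthy.
Metadata association is screened with a Spearman rank-correlation matrix
(pairwise-complete, tie-corrected); single-metabolite group comparisons
use Welch pairwise t-tests with Benjamini-Hochberg adjustment plus
boxplot five-number summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_fdr

__all__ = [
    "CohortSummary",
    "group_ratio",
    "cohort_summary",
    "spearman_matrix",
    "pairwise_group_test",
]


@dataclass
class CohortSummary:
    """Per-group demographic summary blocks."""

    groups: dict = field(default_factory=dict)  # group -> {"n": ..., "age": ..., ...}
    notes: list = field(default_factory=list)

    def to_dict(self):
        return {"groups": self.groups, "notes": self.notes}


def group_ratio(a, b, decimals=2):
    """Ratio a/b rounded to ``decimals``; b = 0 yields inf with a warning."""
    if b == 0:
        warnings.warn("ratio denominator is 0; reporting inf", stacklevel=2)
        return math.inf
    return round(a / b, decimals)


def _mean_sd(values):
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return None
    if len(values) == 1:
        return {"mean": float(values[0]), "sd": 0.0, "n": 1, "degenerate": True}
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)),
        "n": int(len(values)),
    }


def _ratio_block(flags, decimals=2):
    flags = pd.Series(flags)
    known = flags.dropna()
    yes = int((known.astype(float) == 1).sum())
    no = int(len(known) - yes)
    return {
        "numerator": yes,
        "denominator": no,
        "ratio": group_ratio(yes, no, decimals) if no else math.inf,
        "missing": int(flags.isna().sum()),
    }


def cohort_summary(samples: pd.DataFrame, group_col="ethnicity",
                   continuous=("age", "bmi"), binary=("alcohol", "smoking", "morbid"),
                   decimals=2) -> CohortSummary:
    """Demographics-table summary of a sample-metadata frame.

    Study samples only (QCs/blanks excluded when a ``sample_type`` column
    is present).  Missing covariates are excluded per variable, with the
    exclusion counts logged in ``notes``.
    """
    df = samples
    if "sample_type" in df.columns:
        df = df[df["sample_type"] == "sample"]
    if group_col not in df.columns or df[group_col].isna().all():
        raise ValueError(f"group column {group_col!r} absent or empty")
    out = CohortSummary()
    for group, grp in df.groupby(group_col, sort=True):
        block = {"n": int(len(grp))}
        for var in continuous:
            if var in grp.columns:
                ms = _mean_sd(grp[var])
                if ms is None:
                    out.notes.append(f"{group}: no data for {var}; block omitted")
                else:
                    if ms.pop("degenerate", False):
                        out.notes.append(f"{group}: single member, SD of {var} reported as 0")
                    if ms["n"] < len(grp):
                        out.notes.append(
                            f"{group}: {len(grp) - ms['n']} of {len(grp)} missing {var}"
                        )
                    block[var] = ms
        for var in binary:
            if var in grp.columns:
                if grp[var].notna().sum() == 0:
                    out.notes.append(f"{group}: no data for {var}; block omitted")
                    continue
                rb = _ratio_block(grp[var], decimals)
                if rb["missing"]:
                    out.notes.append(
                        f"{group}: {rb['missing']} of {len(grp)} missing {var}"
                    )
                block[var] = rb
        out.groups[str(group)] = block
    return out


def spearman_matrix(covariates: pd.DataFrame, min_pairs=3) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlations with tie-corrected ranks.

    Cells with fewer than ``min_pairs`` complete pairs are NaN; the
    diagonal is 1.
    """
    cols = covariates.columns
    n = len(cols)
    out = np.full((n, n), np.nan)
    vals = covariates.to_numpy(dtype=float)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            mask = np.isfinite(vals[:, i]) & np.isfinite(vals[:, j])
            if mask.sum() < min_pairs:
                continue
            rho = stats.spearmanr(vals[mask, i], vals[mask, j]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=cols, columns=cols)


def _five_number(values):
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(len(values) - len(inside)),
    }


def pairwise_group_test(values, labels):
    """Welch t-tests for all group pairs plus boxplot statistics per group.

    Returns (pairs, boxstats): ``pairs`` is a DataFrame with one row per
    unordered group pair (t statistic, p, BH-adjusted p); ``boxstats``
    maps each group to its median/quartiles/1.5-IQR whiskers.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    per_group = {}
    for g in groups:
        v = values[(labels == g) & np.isfinite(values)]
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        per_group[g] = v
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            t, p = stats.ttest_ind(per_group[g1], per_group[g2], equal_var=False)
            rows.append({"group_a": g1, "group_b": g2, "t": float(t), "p": float(p)})
    pairs = pd.DataFrame(rows)
    pairs["p_adj"] = bh_fdr(pairs["p"].to_numpy())
    boxstats = {g: _five_number(v) for g, v in per_group.items()}
    return pairs, boxstats
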