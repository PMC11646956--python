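"""Mummichog-style pathway enrichment from untargeted m/z features.

Without confirmed identifications, pathway analysis of untargeted data
proceeds by (1) ranking all features with a nonparametric group test
(Mann-Whitney U for two groups, Kruskal-Wallis for three or more),
(2) mapping the significant features to candidate compounds through
accurate-mass adduct matching, (3) testing each pathway's overlap with the
significant compound set by a one-tailed Fisher's exact test, (4) guarding
against the many-to-many m/z->compound mapping with an empirical
resampling null (random feature sets of the same size pushed through the
same mapping), and (5) Benjamini-Hochberg FDR adjustment across pathways.

This is a compound-level simplification of the mummichog idea: empirical
compound grouping of isotopes/adducts and network topology scoring are
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .featrank import POSITIVE_ADDUCTS, annotate_mz
from .peakio import FeatureTable, PathwayModel

__all__ = [
    "RankedFeature",
    "EnrichmentResult",
    "rank_features",
    "significant_set",
    "mz_to_compounds",
    "pathway_fet",
    "resampling_adjust",
    "bh_fdr",
    "run_enrichment",
]


@dataclass(frozen=True)
class RankedFeature:
    feature_id: str
    mz: float
    statistic: float  # Mann-Whitney U or Kruskal-Wallis H
    p_value: float
    test: str  # "MW" or "KW"


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    hits_observed: int
    hits_expected: float
    fet_p: float
    resampling_p: float = float("nan")
    fdr_q: float = float("nan")

    @property
    def enrichment_ratio(self):
        return self.hits_observed / self.hits_expected if self.hits_expected > 0 else 0.0


def rank_features(table: FeatureTable, labels) -> list:
    """Rank every feature by a nonparametric group test.

    Two groups: Mann-Whitney U, two-sided (exact when both groups are
    small and tie-free, normal approximation with tie correction
    otherwise).  Three or more groups: Kruskal-Wallis H with chi-square p
    and tie correction.  Missing cells are dropped per feature.
    """
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("rank_features requires >= 2 groups")
    for g in groups:
        if np.sum(labels == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    X = table.intensities.to_numpy(dtype=float)
    mz = table.features["mz"].to_numpy(dtype=float)
    out = []
    for j, fid in enumerate(table.intensities.columns):
        col = X[:, j]
        vals = [col[(labels == g) & np.isfinite(col)] for g in groups]
        if any(len(v) < 2 for v in vals):
            stat, p, test = np.nan, 1.0, "NA"
        elif len(groups) == 2:
            try:
                res = stats.mannwhitneyu(
                    vals[0], vals[1], alternative="two-sided", method="auto"
                )
                stat, p, test = float(res.statistic), float(res.pvalue), "MW"
            except ValueError:  # all values identical in both groups
                stat, p, test = np.nan, 1.0, "MW"
        else:
            try:
                res = stats.kruskal(*vals)
                stat, p, test = float(res.statistic), float(res.pvalue), "KW"
            except ValueError:
                stat, p, test = np.nan, 1.0, "KW"
        if not np.isfinite(p):
            p = 1.0
        out.append(RankedFeature(str(fid), float(mz[j]), stat, min(max(p, 0.0), 1.0), test))
    return out


def significant_set(ranked, alpha=0.05, feature_ids=None):
    """Feature ids considered significant.

    Default mode: p <= alpha from the nonparametric ranking.  Alternate
    mode: pass an externally chosen list (e.g. the VIP > 1 set) through
    ``feature_ids``, which overrides the p-value rule.
    """
    if not ranked:
        raise ValueError("empty ranking")
    if feature_ids is not None:
        known = {r.feature_id for r in ranked}
        return [f for f in feature_ids if f in known]
    return [r.feature_id for r in ranked if r.p_value <= alpha]


def mz_to_compounds(feature_ids, ranked, compounds, adducts=None, tol_ppm=5.0):
    """Map features to candidate compounds via accurate-mass adduct matching.

    Returns feature_id -> list of compound ids; a feature may hit several
    compounds and all candidates are retained (mummichog-style ambiguity).
    """
    by_id = {r.feature_id: r for r in ranked}
    feats = pd.DataFrame(
        {"mz": [by_id[f].mz for f in feature_ids if f in by_id]},
        index=[f for f in feature_ids if f in by_id],
    )
    cands = annotate_mz(feats, compounds, adducts or POSITIVE_ADDUCTS, tol_ppm)
    mapping = {}
    for c in cands:
        mapping.setdefault(c.feature_id, []).append(c.compound_id)
    # deduplicate per feature, preserving best-ppm-first order
    return {f: list(dict.fromkeys(ids)) for f, ids in mapping.items()}


def compound_set(mapping):
    """Deduplicated compound set hit by a feature->compounds mapping."""
    out = set()
    for ids in mapping.values():
        out.update(ids)
    return out


def pathway_fet(sig_compounds, pathway_model: PathwayModel, reference_compounds):
    """Per-pathway hit counts and one-tailed Fisher's exact enrichment p.

    The 2x2 table crosses pathway membership with significance within the
    reference universe; ``hits_expected`` is the chance expectation
    pathway_size * |sig| / |reference|.
    """
    reference = set(reference_compounds)
    sig = set(sig_compounds) & reference
    results = []
    for pid, (name, members) in pathway_model.pathways.items():
        members = members & reference
        if not members:
            continue
        hits = len(sig & members)
        table = [
            [hits, len(sig) - hits],
            [len(members) - hits, len(reference) - len(members) - (len(sig) - hits)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        expected = len(members) * len(sig) / len(reference)
        results.append(
            EnrichmentResult(pid, name, hits, expected, float(p))
        )
    return results


def resampling_adjust(
    results, pathway_model, ranked, compounds, sig_size,
    n_resamples=1000, adducts=None, tol_ppm=5.0, seed=0,
):
    """Empirical per-pathway p from random feature sets of the observed size.

    Each resample draws ``sig_size`` features from the full ranked list,
    repeats the m/z -> compound mapping, and counts pathway hits;
    empirical p = (1 + #{null hits >= observed}) / (n_resamples + 1).
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    all_ids = [r.feature_id for r in ranked]
    if sig_size > len(all_ids):
        raise ValueError("sig_size exceeds the number of ranked features")
    rng = np.random.default_rng(seed)
    exceed = {r.pathway_id: 0 for r in results}
    observed = {r.pathway_id: r.hits_observed for r in results}
    members = {
        r.pathway_id: pathway_model.pathways[r.pathway_id][1] for r in results
    }
    for _ in range(n_resamples):
        draw = rng.choice(all_ids, size=sig_size, replace=False)
        hit_compounds = compound_set(
            mz_to_compounds(draw, ranked, compounds, adducts, tol_ppm)
        )
        for pid in exceed:
            if len(hit_compounds & members[pid]) >= observed[pid]:
                exceed[pid] += 1
    for r in results:
        r.resampling_p = (1 + exceed[r.pathway_id]) / (n_resamples + 1)
    return results


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(
    table, labels, compounds, pathway_model, alpha=0.05,
    feature_ids=None, adducts=None, tol_ppm=5.0, n_resamples=1000, seed=0,
):
    """Full enrichment chain; returns results sorted by ascending FET p.

    Pathways are ordered by -log10(p) descending, matching the usual
    bubble-plot presentation.
    """
    ranked = rank_features(table, labels)
    sig = significant_set(ranked, alpha=alpha, feature_ids=feature_ids)
    sig_map = mz_to_compounds(sig, ranked, compounds, adducts, tol_ppm)
    sig_compounds = compound_set(sig_map)
    results = pathway_fet(sig_compounds, pathway_model, pathway_model.reference_universe)
    if results and sig:
        results = resampling_adjust(
            results, pathway_model, ranked, compounds, len(sig),
            n_resamples=n_resamples, adducts=adducts, tol_ppm=tol_ppm, seed=seed,
        )
    qs = bh_fdr([r.fet_p for r in results])
    for r, q in zip(results, qs):
        r.fdr_q = float(q)
    results.sort(key=lambda r: (r.fet_p, r.pathway_id))
    return results, ranked, sig
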