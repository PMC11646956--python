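"""VIP-score feature ranking and accurate-mass putative annotation.

The variable importance in projection (VIP) score aggregates a feature's
squared PLS weights across components, weighted by the Y-variance each
component explains:

    VIP_j = sqrt( p * sum_a SSY_a * w_aj^2 / sum_a SSY_a ),

with SSY_a = ||c_a||^2 * (t_a . t_a) and unit-norm weight vectors, so the
mean of squared VIPs over all p model features is exactly 1.  Selection
uses either the conventional VIP > 1 rule (strict) or the top fraction of
the ranking.

Annotation matches observed positive-mode m/z values against neutral
monoisotopic masses of a compound table over a configurable adduct list at
a ppm tolerance; this yields putative (accurate-mass only) identities, so
candidates carry an MSI confidence level and can be demoted to
"unknown/unidentified" by declarative plausibility rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chemometrics import PLSModel

__all__ = [
    "VIPRanking",
    "AnnotationCandidate",
    "POSITIVE_ADDUCTS",
    "vip_scores",
    "select_features",
    "annotate_mz",
    "plausibility_gate",
]

#: positive-mode electrospray adducts: label -> exact mass shift (Da)
POSITIVE_ADDUCTS = {
    "[M+H]+": 1.007276,
    "[M+Na]+": 22.989218,
    "[M+K]+": 38.963158,
    "[M+NH4]+": 18.033823,
}


@dataclass
class VIPRanking:
    """VIP scores of one fitted model, indexed by feature id."""

    scores: pd.Series  # feature_id -> VIP, descending not guaranteed
    n_components: int

    def ordered(self):
        """Descending VIP; ties broken by feature id (deterministic)."""
        df = self.scores.rename("vip").rename_axis("feature_id").reset_index()
        df = df.sort_values(["vip", "feature_id"], ascending=[False, True])
        return df.set_index("feature_id")["vip"]


@dataclass(frozen=True)
class AnnotationCandidate:
    feature_id: str
    compound_id: str
    compound_name: str
    adduct: str
    mass_error_ppm: float
    msi_level: str = "3"  # accurate-mass only -> putative
    plausibility: str = "plausible"


def vip_scores(model: PLSModel, feature_ids=None) -> VIPRanking:
    """VIP score per feature of a fitted PLS-DA model."""
    if model is None or model.weights is None:
        raise ValueError("vip_scores requires a fitted model")
    W = model.weights  # p x A, unit-norm columns
    T = model.scores  # n x A
    C = model.y_loadings  # k x A
    p, A = W.shape
    ssy = np.array([(C[:, a] @ C[:, a]) * (T[:, a] @ T[:, a]) for a in range(A)])
    wnorm2 = W**2 / np.maximum(np.sum(W**2, axis=0), 1e-300)
    vip = np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    return VIPRanking(
        pd.Series(vip, index=pd.Index(feature_ids, name="feature_id")), A
    )


def select_features(ranking: VIPRanking, mode="vip_gt1", fraction=0.10):
    """Feature ids selected by VIP, in descending-VIP order.

    ``vip_gt1`` keeps scores strictly above 1; ``top_fraction`` keeps the
    ceil(fraction * p) largest.  Ties are broken by feature id.
    """
    ordered = ranking.ordered()
    if len(ordered) == 0:
        raise ValueError("empty ranking")
    if mode == "vip_gt1":
        return ordered.index[ordered > 1.0].tolist()
    if mode == "top_fraction":
        k = int(np.ceil(fraction * len(ordered)))
        return ordered.index[:k].tolist()
    raise ValueError(f"unknown selection mode {mode!r}")


def annotate_mz(features, compounds, adducts=None, tol_ppm=5.0):
    """Accurate-mass annotation of features against a compound table.

    ``features`` is an iterable of objects (or a DataFrame) with
    ``feature_id`` and ``mz``.  For every (feature, compound, adduct) whose
    relative mass error |mz_obs - (M + shift)| / (M + shift) * 1e6 is
    within ``tol_ppm``, one candidate is emitted; candidates are ordered
    per feature by absolute ppm error.
    """
    if adducts is None:
        adducts = POSITIVE_ADDUCTS
    if not compounds:
        raise ValueError("empty compound table")
    if isinstance(features, pd.DataFrame):
        items = [(str(i), row["mz"]) for i, row in features.iterrows()]
    else:
        items = [(f.feature_id, f.mz) for f in features]
    out = []
    for fid, mz in items:
        if not np.isfinite(mz):
            continue
        cands = []
        for comp in compounds:
            for adduct, shift in adducts.items():
                expected = comp.monoisotopic_mass + shift
                ppm = (mz - expected) / expected * 1e6
                if abs(ppm) <= tol_ppm:
                    cands.append(
                        AnnotationCandidate(
                            feature_id=fid,
                            compound_id=comp.compound_id,
                            compound_name=comp.name,
                            adduct=adduct,
                            mass_error_ppm=float(ppm),
                        )
                    )
        cands.sort(key=lambda c: (abs(c.mass_error_ppm), c.compound_id, c.adduct))
        out.extend(cands)
    return out


@dataclass
class PlausibilityRule:
    """Declarative gate: candidates failing ``check`` become unknown/unidentified."""

    name: str
    check: callable  # (candidate, feature_meta) -> bool, True = plausible


def min_rt_rule(name, compound_ids, min_rt):
    """Rule: listed compounds are implausible below ``min_rt`` minutes.

    Models the reversed-phase gradient argument that e.g. a lipid eluting in
    the first two minutes cannot be a genuine lipid identification.
    """
    ids = frozenset(compound_ids)

    def check(cand, meta):
        if cand.compound_id not in ids:
            return True
        rt = meta.get(cand.feature_id, {}).get("rt", np.nan)
        return not (np.isfinite(rt) and rt < min_rt)

    return PlausibilityRule(name, check)


def plausibility_gate(candidates, rules, feature_meta=None):
    """Relabel candidates failing any rule as unknown/unidentified (never dropped)."""
    feature_meta = feature_meta or {}
    out = []
    for cand in candidates:
        ok = all(rule.check(cand, feature_meta) for rule in rules)
        out.append(
            cand if ok else replace(cand, plausibility="unknown/unidentified",
                                    msi_level="unknown")
        )
    return out
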