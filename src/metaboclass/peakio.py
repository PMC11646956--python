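"""Feature-table containers and plain-text I/O.

The central object of the pipeline is the :class:`FeatureTable`: a
samples x features intensity matrix (missing values as NaN) together with
per-feature metadata (m/z, retention time, platform), per-sample metadata
(sample type, batch, injection order, class labels, covariates) and a
provenance log that records every transform applied.

All on-disk formats are plain text: comma-separated for intensity and
sample tables, tab-separated for compound tables, JSON for pathway models
and provenance sidecars.  Missing cells are written as empty strings and
parsed from empty/"NA" tokens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Feature",
    "SampleRecord",
    "FeatureTable",
    "CompoundRecord",
    "PathwayModel",
    "FeatureTableError",
    "read_feature_table",
    "write_feature_table",
    "read_compound_table",
    "read_pathway_model",
]

SAMPLE_TYPES = ("sample", "QC", "blank")

#: columns of the sample-metadata table that are not covariates
_CORE_SAMPLE_COLS = (
    "sample_type",
    "batch",
    "injection_order",
    "ethnicity",
    "age",
    "age_band",
)


class FeatureTableError(ValueError):
    """Structural problem in a feature table or its metadata."""


@dataclass(frozen=True)
class Feature:
    """One measured feature: an (m/z, retention time) pair on a platform."""

    feature_id: str
    mz: float
    rt: float
    platform: str = "LC"

    def __post_init__(self):
        if not self.mz > 0:
            raise FeatureTableError(f"feature {self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise FeatureTableError(f"feature {self.feature_id}: rt must be >= 0")


@dataclass
class SampleRecord:
    """One injection: a study sample, a pooled QC, or a blank."""

    sample_id: str
    sample_type: str = "sample"
    batch: int = 1
    injection_order: int = 0
    ethnicity: str | None = None
    age: float | None = None
    age_band: str | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sample_type not in SAMPLE_TYPES:
            raise FeatureTableError(
                f"sample {self.sample_id}: sample_type must be one of {SAMPLE_TYPES}"
            )


@dataclass
class FeatureTable:
    """Samples x features intensity matrix plus metadata and provenance.

    Attributes
    ----------
    intensities : pandas.DataFrame
        Rows indexed by sample id, columns by feature id; NaN marks a
        missing (undetected) cell.  Values are on the raw intensity scale
        unless the provenance log records a transform.
    features : pandas.DataFrame
        Indexed by feature id with columns ``mz``, ``rt``, ``platform``.
    samples : pandas.DataFrame
        Indexed by sample id with the core columns in ``_CORE_SAMPLE_COLS``
        plus any covariate columns.
    provenance_log : list of dict
        Append-only record of applied transforms.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    provenance_log: list = field(default_factory=list)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(cls, intensities, feature_list, sample_list, provenance=None):
        """Build a table from :class:`Feature` / :class:`SampleRecord` lists."""
        fdf = pd.DataFrame(
            {
                "mz": [f.mz for f in feature_list],
                "rt": [f.rt for f in feature_list],
                "platform": [f.platform for f in feature_list],
            },
            index=pd.Index([f.feature_id for f in feature_list], name="feature_id"),
        )
        rows = []
        for s in sample_list:
            row = {
                "sample_type": s.sample_type,
                "batch": s.batch,
                "injection_order": s.injection_order,
                "ethnicity": s.ethnicity,
                "age": s.age,
                "age_band": s.age_band,
            }
            row.update(s.covariates)
            rows.append(row)
        sdf = pd.DataFrame(
            rows,
            index=pd.Index([s.sample_id for s in sample_list], name="sample_id"),
            columns=list(_CORE_SAMPLE_COLS) if not rows else None,
        )
        idf = pd.DataFrame(
            np.asarray(intensities, dtype=float), index=sdf.index, columns=fdf.index
        )
        table = cls(idf, fdf, sdf, list(provenance or []))
        table.validate()
        return table

    # -- validation -----------------------------------------------------------

    def validate(self):
        """Check every structural invariant; raise FeatureTableError on the first violation."""
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FeatureTableError(f"duplicate sample id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FeatureTableError(f"duplicate feature id: {dup!r}")
        if not idx.equals(self.samples.index):
            raise FeatureTableError(
                "sample ids of intensity matrix and sample metadata disagree "
                f"({len(idx)} vs {len(self.samples)} rows)"
            )
        if not cols.equals(self.features.index):
            raise FeatureTableError(
                "feature ids of intensity matrix and feature metadata disagree "
                f"({len(cols)} vs {len(self.features)} columns)"
            )
        vals = self.intensities.to_numpy()
        if not self._is_transformed() and np.nanmin(vals, initial=np.inf) < 0:
            r, c = np.argwhere(np.asarray(self.intensities < 0))[0]
            raise FeatureTableError(
                f"negative intensity at sample {idx[r]!r}, feature {cols[c]!r}"
            )
        bad_type = ~self.samples["sample_type"].isin(SAMPLE_TYPES)
        if bad_type.any():
            sid = self.samples.index[bad_type][0]
            raise FeatureTableError(f"sample {sid!r}: invalid sample_type")
        for batch, grp in self.samples.groupby("batch"):
            if grp["injection_order"].duplicated().any():
                order = grp["injection_order"][grp["injection_order"].duplicated()].iloc[0]
                raise FeatureTableError(
                    f"duplicate injection_order {order} within batch {batch}"
                )
        return self

    def _is_transformed(self):
        # log/Pareto stages legitimately produce negative values
        return any(
            e.get("stage") in ("log10_transform", "pareto_scale")
            for e in self.provenance_log
        )

    # -- accessors ------------------------------------------------------------

    @property
    def n_samples(self):
        return self.intensities.shape[0]

    @property
    def n_features(self):
        return self.intensities.shape[1]

    def mask(self, sample_type):
        return (self.samples["sample_type"] == sample_type).to_numpy()

    @property
    def qc_mask(self):
        return self.mask("QC")

    @property
    def blank_mask(self):
        return self.mask("blank")

    @property
    def sample_mask(self):
        return self.mask("sample")

    def log(self, stage, **info):
        """Append one provenance entry (monotone append-only)."""
        entry = {"stage": stage}
        entry.update(info)
        self.provenance_log.append(entry)
        return self

    def copy(self):
        return FeatureTable(
            self.intensities.copy(),
            self.features.copy(),
            self.samples.copy(),
            list(self.provenance_log),
        )

    def drop_features(self, feature_ids):
        keep = [c for c in self.intensities.columns if c not in set(feature_ids)]
        return FeatureTable(
            self.intensities[keep],
            self.features.loc[keep],
            self.samples.copy(),
            list(self.provenance_log),
        )


# -- feature table I/O --------------------------------------------------------

_NA_TOKENS = ["", "NA", "NaN", "nan"]


def _sidecar(path, suffix):
    p = Path(path)
    return p.with_name(p.stem + suffix)


def read_feature_table(path, metadata_path=None, features_path=None) -> FeatureTable:
    """Read an intensity CSV plus its sample-metadata CSV.

    ``path`` holds the samples x features matrix (first column = sample id,
    header row = feature ids).  ``metadata_path`` defaults to the
    ``<stem>.samples.csv`` sidecar, ``features_path`` to
    ``<stem>.features.csv``; a missing features sidecar yields NaN m/z and
    rt.  A ``<stem>.provenance.json`` sidecar is loaded when present.
    """
    path = Path(path)
    metadata_path = Path(metadata_path) if metadata_path else _sidecar(path, ".samples.csv")
    features_path = Path(features_path) if features_path else _sidecar(path, ".features.csv")

    inten = pd.read_csv(
        path, index_col=0, na_values=_NA_TOKENS, keep_default_na=False
    )
    inten.index = inten.index.astype(str)
    inten.index.name = "sample_id"
    inten.columns = inten.columns.astype(str)
    inten.columns.name = "feature_id"
    inten = inten.astype(float)

    samples = pd.read_csv(
        metadata_path, index_col=0, na_values=_NA_TOKENS, keep_default_na=False
    )
    samples.index = samples.index.astype(str)
    samples.index.name = "sample_id"
    for col in _CORE_SAMPLE_COLS:
        if col not in samples.columns:
            samples[col] = np.nan
    samples["batch"] = samples["batch"].fillna(1).astype(int)
    samples["injection_order"] = samples["injection_order"].fillna(0).astype(int)
    samples["sample_type"] = samples["sample_type"].fillna("sample")

    if features_path.exists():
        features = pd.read_csv(features_path, index_col=0)
        features.index = features.index.astype(str)
    else:
        features = pd.DataFrame(
            {"mz": np.nan, "rt": np.nan, "platform": "LC"}, index=inten.columns
        )
    features.index.name = "feature_id"

    prov_path = _sidecar(path, ".provenance.json")
    provenance = []
    if prov_path.exists():
        provenance = json.loads(prov_path.read_text())

    table = FeatureTable(inten, features, samples, provenance)
    table.validate()
    return table


def write_feature_table(table: FeatureTable, path):
    """Write intensity CSV plus ``.samples.csv``/``.features.csv``/``.provenance.json`` sidecars.

    Column order is deterministic (the table's own order); floats are
    written with Python shortest-repr so a read round-trips exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.intensities.to_csv(path, na_rep="")
    table.samples.to_csv(_sidecar(path, ".samples.csv"), na_rep="")
    table.features.to_csv(_sidecar(path, ".features.csv"))
    _sidecar(path, ".provenance.json").write_text(
        json.dumps(table.provenance_log, indent=1, default=str)
    )
    return path


# -- compound tables and pathway models ---------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """A reference metabolite with its neutral monoisotopic mass."""

    compound_id: str
    name: str
    monoisotopic_mass: float
    pathway_ids: frozenset = frozenset()

    def __post_init__(self):
        if not self.monoisotopic_mass > 0:
            raise FeatureTableError(
                f"compound {self.compound_id}: monoisotopic mass must be > 0"
            )


@dataclass
class PathwayModel:
    """Named compound sets over a reference universe of compound ids."""

    pathways: dict  # pathway_id -> (name, frozenset of compound ids)
    reference_universe: frozenset

    def __post_init__(self):
        for pid, (_, members) in self.pathways.items():
            missing = members - self.reference_universe
            if missing:
                raise FeatureTableError(
                    f"pathway {pid!r}: member compounds {sorted(missing)} "
                    "absent from reference universe"
                )

    def __len__(self):
        return len(self.pathways)


def read_compound_table(path) -> list:
    """Read a tab-separated compound table.

    Columns: ``compound_id``, ``name``, ``monoisotopic_mass``,
    ``pathway_ids`` (semicolon-separated, may be empty).
    """
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
    records = []
    for _, row in df.iterrows():
        raw = row.get("pathway_ids", "")
        pids = frozenset(p for p in str(raw).split(";") if p and p != "nan")
        records.append(
            CompoundRecord(
                compound_id=row["compound_id"],
                name=row["name"],
                monoisotopic_mass=float(row["monoisotopic_mass"]),
                pathway_ids=pids,
            )
        )
    return records


def read_pathway_model(path) -> PathwayModel:
    """Read a pathway model from JSON.

    Layout: ``{"pathways": {id: {"name": ..., "compounds": [...]}},
    "reference_universe": [...]}``.
    """
    doc = json.loads(Path(path).read_text())
    pathways = {
        pid: (entry.get("name", pid), frozenset(entry["compounds"]))
        for pid, entry in doc["pathways"].items()
    }
    return PathwayModel(pathways, frozenset(doc["reference_universe"]))
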