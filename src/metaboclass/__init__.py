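"""metaboclass: QC-driven preprocessing, bootstrap-validated PLS-DA and
pathway enrichment for untargeted LC-MS/GC-MS peak tables."""

from importlib import resources

from .peakio import (
    CompoundRecord,
    Feature,
    FeatureTable,
    PathwayModel,
    SampleRecord,
    read_compound_table,
    read_feature_table,
    read_pathway_model,
    write_feature_table,
)
from .synthgen import CohortSpec, EffectSpec, RunSpec, generate_cohort, generate_peak_table, preset
from .preprocess import FilterConfig, run_preprocess
from .chemometrics import (
    BootstrapConfig,
    PLSModel,
    ValidationSummary,
    bootstrap_validate,
    fit_pls,
    permutation_null,
    predict_classes,
    smote_oversample,
)
from .featrank import annotate_mz, select_features, vip_scores
from .enrich import run_enrichment
from .cohortstats import cohort_summary, group_ratio, pairwise_group_test, spearman_matrix

__version__ = "0.1.0"


def bundled_compounds():
    """The bundled toy compound table (12 metabolites, accurate masses)."""
    with resources.as_file(resources.files("metaboclass.data") / "compounds.tsv") as p:
        return read_compound_table(p)


def bundled_pathways():
    """The bundled toy pathway model (4 pathways over the 12 compounds)."""
    with resources.as_file(resources.files("metaboclass.data") / "pathways.json") as p:
        return read_pathway_model(p)
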