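"""Shared fixtures: small synthetic tables and an engineered filter fixture."""

import numpy as np
import pytest

from metaboclass.peakio import Feature, FeatureTable, SampleRecord
from metaboclass.synthgen import CohortSpec, EffectSpec, RunSpec, generate_cohort, generate_peak_table


def make_table(intensities, qc_rows=(), blank_rows=(), mz=None, rt=None, batch=None):
    """Assemble a FeatureTable from a raw matrix and row-type indices."""
    intensities = np.asarray(intensities, dtype=float)
    n, p = intensities.shape
    mz = mz if mz is not None else np.linspace(100, 500, p)
    rt = rt if rt is not None else np.linspace(1, 10, p)
    feats = [Feature(f"F{j + 1:03d}", float(mz[j]), float(rt[j])) for j in range(p)]
    samples = []
    for i in range(n):
        if i in qc_rows:
            stype, sid = "QC", f"QC_{i:03d}"
        elif i in blank_rows:
            stype, sid = "blank", f"blank_{i:03d}"
        else:
            stype, sid = "sample", f"S_{i:03d}"
        samples.append(
            SampleRecord(sid, stype, batch=int(batch[i]) if batch is not None else 1,
                         injection_order=i + 1,
                         ethnicity="WE" if stype == "sample" else None)
        )
    return FeatureTable.from_records(intensities, feats, samples)


@pytest.fixture(scope="session")
def small_synth():
    """A compact multi-batch synthetic run with planted effects and its truth."""
    spec = CohortSpec(
        group_sizes={"WE": 40, "SA": 30, "AC": 30},
        seed=11,
    )
    cohort = generate_cohort(spec)
    run = RunSpec(n_features=60, n_batches=2, qc_interval=8, drift_amplitude=0.1,
                  noise_cv=0.05, missing_rate=0.05)
    effects = EffectSpec(n_discriminative=6, effect_log10=0.4)
    table, truth = generate_peak_table(cohort, run, effects, seed=11)
    return table, truth


@pytest.fixture
def filter_fixture():
    """10 engineered features: 2 fail QC presence, 2 fail RSD, 2 fail blank ratio.

    20 QC rows, 2 blanks, 8 study samples, one batch.
    Columns: F001/F002 detected in 1 of 20 QCs (5% < 10%); F003/F004
    alternate 50/150 across QCs (RSD ~51% >= 40%); F005/F006 have mean
    sample signal 1000 vs mean blank 400 (ratio 2.5 < 3); F007-F010 pass
    everything.
    """
    n_qc, n_blank, n_samp = 20, 2, 8
    n = n_qc + n_blank + n_samp
    X = np.full((n, 10), np.nan)
    qc_rows = list(range(n_qc))
    blank_rows = [n_qc, n_qc + 1]
    samp_rows = list(range(n_qc + n_blank, n))

    X[:, :] = 1000.0
    # presence failures: only first QC sees the feature
    X[qc_rows, 0] = np.nan
    X[qc_rows, 1] = np.nan
    X[qc_rows[0], 0] = 800.0
    X[qc_rows[0], 1] = 900.0
    # RSD failures: alternate 50/150 over the QCs
    for j in (2, 3):
        X[qc_rows, j] = [50.0 if i % 2 == 0 else 150.0 for i in range(n_qc)]
    # blank failures: strong blank signal
    X[blank_rows, :] = 0.0
    X[blank_rows, 4] = 400.0
    X[blank_rows, 5] = 400.0
    X[samp_rows, :] = 1000.0
    return make_table(X, qc_rows=qc_rows, blank_rows=blank_rows)
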