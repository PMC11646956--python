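"""QC filters, drift correction, imputation, log10 and Pareto scaling."""

import numpy as np
import pytest

from metaboclass.peakio import FeatureTableError
from metaboclass.preprocess import (
    FilterConfig,
    blank_ratio_filter,
    drift_correct,
    impute_missing,
    log10_transform,
    pareto_scale,
    qc_presence_filter,
    qc_rsd,
    qc_rsd_filter,
    run_preprocess,
)

from conftest import make_table


# -- presence filter ----------------------------------------------------------

def _qc_table(qc_matrix, sample_rows=2):
    n_qc, p = np.asarray(qc_matrix).shape
    X = np.vstack([qc_matrix, np.full((sample_rows, p), 1000.0)])
    return make_table(X, qc_rows=range(n_qc))


@pytest.mark.parametrize(
    "n_detected, kept",
    [(1, False),  # 5% of 20 QCs -> removed
     (2, True),   # exactly 10% -> kept ("at least" is inclusive)
     (20, True)], # always detected -> kept
)
def test_qc_presence_boundaries(n_detected, kept):
    qc = np.full((20, 1), np.nan)
    qc[:n_detected, 0] = 500.0
    table = _qc_table(qc)
    out, removed = qc_presence_filter(table, FilterConfig())
    assert (out.n_features == 1) is kept
    assert (removed == ["F001"]) is not kept


def test_presence_filter_requires_qcs():
    t = make_table(np.ones((3, 2)))
    with pytest.raises(FeatureTableError, match="QC"):
        qc_presence_filter(t, FilterConfig())


# -- RSD filter ---------------------------------------------------------------

def test_rsd_computation_matches_hand_value():
    # [50, 150]: mean 100, sample sd 70.71 -> RSD 70.71%
    table = _qc_table(np.array([[50.0], [150.0]]))
    assert qc_rsd(table).iloc[0] == pytest.approx(70.7106781, abs=1e-6)
    out, removed = qc_rsd_filter(table, FilterConfig())
    assert removed == ["F001"]


def test_constant_qcs_kept():
    table = _qc_table(np.full((3, 1), 100.0))
    out, removed = qc_rsd_filter(table, FilterConfig())
    assert removed == [] and out.n_features == 1


def test_rsd_exactly_40_percent_removed():
    # choose two QC values with RSD exactly 40%: mean m, sd 0.4m
    # [a, b]: sd = |a-b|/sqrt(2); pick a=100-x, b=100+x with x = 40/sqrt(2)*... solve:
    # mean 100, want sd 40 -> |a-b| = 40*sqrt(2)
    d = 40.0 * np.sqrt(2.0)
    table = _qc_table(np.array([[100 - d / 2], [100 + d / 2]]))
    assert qc_rsd(table).iloc[0] == pytest.approx(40.0, abs=1e-9)
    _, removed = qc_rsd_filter(table, FilterConfig())
    assert removed == ["F001"]  # strict "< 40" keeps, so 40 itself is removed


def test_zero_qc_mean_dropped_not_crashed():
    table = _qc_table(np.zeros((3, 1)))
    _, removed = qc_rsd_filter(table, FilterConfig())
    assert removed == ["F001"]


# -- blank ratio filter -------------------------------------------------------

def _blank_table(sample_val, blank_val):
    X = np.array([[sample_val]] * 4 + [[blank_val]] * 2 + [[sample_val]] * 2)
    # rows: 4 samples, 2 blanks, 2 QCs
    return make_table(X, qc_rows=(6, 7), blank_rows=(4, 5))


@pytest.mark.parametrize(
    "sample_mean, blank_mean, kept",
    [(1000.0, 400.0, False),  # ratio 2.5 -> removed
     (900.0, 300.0, True)],   # ratio 3.0 -> kept (inclusive)
)
def test_blank_ratio_boundaries(sample_mean, blank_mean, kept):
    table = _blank_table(sample_mean, blank_mean)
    out, removed = blank_ratio_filter(table, FilterConfig(blank_ratio_min=3.0))
    assert (out.n_features == 1) is kept


def test_all_missing_blank_keeps_feature():
    table = _blank_table(1000.0, 0.0)
    table.intensities.iloc[4:6, 0] = np.nan
    out, removed = blank_ratio_filter(table, FilterConfig())
    assert removed == []


def test_no_blank_rows_skips_with_warning():
    t = make_table(np.ones((4, 2)), qc_rows=(0, 1))
    with pytest.warns(UserWarning, match="blank"):
        out, removed = blank_ratio_filter(t, FilterConfig())
    assert out.n_features == 2 and removed == []


# -- drift correction ---------------------------------------------------------

def test_linear_drift_corrected_exactly():
    # intensity = 100 + injection_order for every row; QCs every 3rd row
    n = 30
    orders = np.arange(1, n + 1)
    X = (100.0 + orders)[:, None] * np.ones((1, 3))
    table = make_table(X, qc_rows=range(0, n, 3))
    out, model = drift_correct(table, span=1.0)
    rsd_after = qc_rsd(out)
    assert (rsd_after < 1e-6).all()
    assert not model.skipped


def test_no_drift_input_unchanged_up_to_batch_scaling():
    X = np.full((20, 2), 500.0)
    table = make_table(X, qc_rows=range(0, 20, 4))
    out, _ = drift_correct(table)
    assert np.allclose(out.intensities.to_numpy(), 500.0, rtol=1e-9)


def test_drift_correction_reduces_qc_rsd(small_synth):
    table, _ = small_synth
    before = qc_rsd(table).median()
    out, _ = drift_correct(table)
    after = qc_rsd(out).median()
    assert after < before


def test_drift_correction_preserves_shape(small_synth):
    table, _ = small_synth
    out, _ = drift_correct(table)
    assert out.intensities.shape == table.intensities.shape


# -- imputation ---------------------------------------------------------------

def test_collinear_spline_reduces_to_line():
    X = np.array([[1.0], [2.0], [np.nan], [4.0], [5.0]])
    table = make_table(X)
    out = impute_missing(table)
    assert out.intensities.iloc[2, 0] == pytest.approx(3.0, abs=1e-9)


def test_no_missing_is_identity(small_synth):
    table, _ = small_synth
    full = impute_missing(table)
    filled = impute_missing(full)
    assert np.allclose(full.intensities.to_numpy(), filled.intensities.to_numpy())


def test_boundary_missing_takes_nearest_observed():
    X = np.array([[np.nan], [2.0], [3.0], [4.0], [5.0], [np.nan]])
    table = make_table(X)
    out = impute_missing(table)
    assert out.intensities.iloc[0, 0] == pytest.approx(2.0)
    assert out.intensities.iloc[5, 0] == pytest.approx(5.0)


# -- log10 and Pareto ---------------------------------------------------------

def test_log10_known_values():
    X = np.array([[1.0, 1000.0]] * 3)
    out = log10_transform(make_table(X))
    assert np.allclose(out.intensities.to_numpy(), [[0.0, 3.0]] * 3)


def test_log10_zero_uses_half_minimum():
    X = np.array([[0.0], [10.0], [40.0]])
    out = log10_transform(make_table(X))
    assert out.intensities.iloc[0, 0] == pytest.approx(np.log10(5.0))
    assert out.provenance_log[-1]["zero_cells_substituted"] == 1


def test_pareto_hand_example():
    X = np.array([[1.0], [2.0], [3.0]])
    out = pareto_scale(make_table(X))
    assert np.allclose(out.intensities.to_numpy().ravel(), [-1.0, 0.0, 1.0])


def test_pareto_constant_column_zeroed():
    X = np.column_stack([np.full(4, 7.0), np.arange(4.0) + 1])
    with pytest.warns(UserWarning, match="zero-variance"):
        out = pareto_scale(make_table(X))
    assert np.allclose(out.intensities.iloc[:, 0], 0.0)


def test_pareto_defining_property(small_synth):
    # mean 0, and variance equals the pre-scaling SD for every feature
    table, _ = small_synth
    filled = impute_missing(table)
    logged = log10_transform(filled)
    sd_before = logged.intensities.std(ddof=1)
    out = pareto_scale(logged)
    assert np.abs(out.intensities.mean()).max() < 1e-10
    nonconst = sd_before > 0
    assert np.allclose(out.intensities.loc[:, nonconst].var(ddof=1),
                       sd_before[nonconst], rtol=1e-8)


# -- full chain ---------------------------------------------------------------

def test_engineered_fixture_removes_2_2_2(filter_fixture):
    out, report = run_preprocess(filter_fixture)
    assert report["qc_presence_removed"] == 2
    assert report["qc_rsd_removed"] == 2
    assert report["blank_ratio_removed"] == 2
    assert report["output_features"] == 4
    stages = [e["stage"] for e in out.provenance_log]
    expected_order = ["qc_presence_filter", "qc_rsd_filter", "blank_ratio_filter",
                      "drift_correct", "impute_missing", "log10_transform",
                      "pareto_scale"]
    positions = [stages.index(s) for s in expected_order]
    assert positions == sorted(positions)


def test_all_passing_features_unchanged_in_count(small_synth):
    table, _ = small_synth
    out, report = run_preprocess(table)
    assert report["output_features"] + report["qc_presence_removed"] + \
        report["qc_rsd_removed"] + report["blank_ratio_removed"] == table.n_features


def test_filters_idempotent_on_survivors(filter_fixture):
    t1, _ = qc_presence_filter(filter_fixture)
    t1, _ = qc_rsd_filter(t1)
    t1, _ = blank_ratio_filter(t1)
    t2, r1 = qc_presence_filter(t1)
    t2, r2 = qc_rsd_filter(t2)
    t2, r3 = blank_ratio_filter(t2)
    assert r1 == r2 == r3 == []
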