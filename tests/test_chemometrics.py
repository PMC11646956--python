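"""NIPALS PLS-DA, classification metrics, SMOTE, bootstrap and permutation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaboclass.chemometrics import (
    BootstrapConfig,
    attach_null,
    bootstrap_validate,
    ccr,
    classwise_rates,
    empirical_p,
    fit_pls,
    macro_metrics,
    one_hot,
    pca_scores,
    permutation_null,
    predict_classes,
    predict_scores,
    smote_oversample,
)


def separable_data(n_per=10, p=6, gap=8.0, seed=0, k=2):
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for c in range(k):
        centre = np.zeros(p)
        centre[c % p] = gap * c
        blocks.append(rng.normal(size=(n_per, p)) + centre)
        labels += [chr(ord("A") + c)] * n_per
    return np.vstack(blocks), np.array(labels)


# -- fitting and prediction ---------------------------------------------------

def test_separable_training_ccr_is_100():
    X, y = separable_data(gap=10.0, k=2)
    model = fit_pls(X, y, 2)
    assert ccr(y, predict_classes(model, X)) == 100.0


def test_single_class_rejected():
    X = np.random.default_rng(0).normal(size=(8, 3))
    with pytest.raises(ValueError, match="2 classes"):
        fit_pls(X, np.array(["A"] * 8), 1)


def test_too_many_components_rejected():
    X, y = separable_data(n_per=4, p=3)
    with pytest.raises(ValueError, match="n_components"):
        fit_pls(X, y, 10)


def test_scores_orthogonal_weights_unit_norm():
    X, y = separable_data(n_per=8, p=10, gap=2.0, k=3, seed=3)
    m = fit_pls(X, y, 4)
    T = m.scores
    G = T.T @ T
    off = G - np.diag(np.diag(G))
    norms = np.sqrt(np.diag(G))
    assert np.max(np.abs(off)) < 1e-8 * np.outer(norms, norms).max()
    assert np.allclose(np.linalg.norm(m.weights, axis=0), 1.0)


def test_nipals_matches_sklearn_reference():
    """Predictions agree with an independent SVD/NIPALS reference to 1e-6."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    rng = np.random.default_rng(17)
    for _ in range(20):
        X = rng.normal(size=(12, 6))
        y = np.array(["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        model = fit_pls(X, y, 3)
        Y, _ = one_hot(y)
        ref = sklearn.PLSRegression(
            n_components=3, scale=False, tol=1e-14, max_iter=20000
        ).fit(X, Y)
        X_new = rng.normal(size=(5, 6))
        assert np.max(np.abs(predict_scores(model, X_new) - ref.predict(X_new))) < 1e-6


def test_permuted_labels_reach_chance_training_ccr():
    # with n >> p and no signal, training CCR approaches 1/k
    rng = np.random.default_rng(5)
    n, k = 300, 3
    X = rng.normal(size=(n, 10))
    y = np.repeat(["A", "B", "C"], n // k)
    y = rng.permutation(y)
    model = fit_pls(X, y, 3)
    rate = ccr(y, predict_classes(model, X)) / 100.0
    se = np.sqrt((1 / k) * (1 - 1 / k) / n)
    # training fit overstates chance slightly; allow 3 SE above 1/k
    assert rate < 1 / k + 5 * se


def test_tie_breaks_to_first_class():
    X, y = separable_data()
    model = fit_pls(X, y, 2)
    model.coef = np.zeros_like(model.coef)  # force exact ties
    model.y_mean = np.zeros_like(model.y_mean)
    labels = predict_classes(model, X[:3])
    assert list(labels) == ["A", "A", "A"]


def test_feature_count_mismatch_rejected():
    X, y = separable_data()
    model = fit_pls(X, y, 2)
    with pytest.raises(ValueError, match="feature count"):
        predict_classes(model, np.zeros((2, 99)))


# -- metrics ------------------------------------------------------------------

def test_all_correct_metrics():
    y = np.array(["A", "B", "C"] * 4)
    assert ccr(y, y) == 100.0
    sens, spec, acc = macro_metrics(y, y)
    assert sens == spec == acc == 100.0


def test_half_correct_symmetric_classes():
    y = np.repeat(["A", "B", "C"], 4)
    pred = y.copy()
    # rotate half of each class to the next label
    for c, nxt in (("A", "B"), ("B", "C"), ("C", "A")):
        idx = np.where(y == c)[0][:2]
        pred[idx] = nxt
    assert ccr(y, pred) == 50.0
    assert all(v == 50.0 for v in classwise_rates(y, pred).values())


def test_binary_confusion_matches_enumeration():
    # 4 of class A (1 wrong), 4 of class B (all right): CCR 87.5
    y = np.array(["A"] * 4 + ["B"] * 4)
    pred = np.array(["A", "A", "A", "B"] + ["B"] * 4)
    assert ccr(y, pred) == 87.5
    sens, spec, acc = macro_metrics(y, pred)
    # one-vs-rest tables by hand: A: tp3 fn1 tn4 fp0; B: tp4 fn0 tn3 fp1
    assert sens == pytest.approx((75.0 + 100.0) / 2)
    assert spec == pytest.approx((100.0 + 75.0) / 2)
    assert acc == 87.5


# -- SMOTE --------------------------------------------------------------------

def test_smote_balanced_input_is_identity():
    X, y = separable_data(n_per=6)
    X2, y2 = smote_oversample(X, y, 3, seed=0)
    assert np.array_equal(X2, X) and np.array_equal(y2, y)


def test_smote_synthetic_points_on_segment():
    X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[10.0, 0.0]] * 8)
    y = np.array(["m"] * 2 + ["M"] * 8)
    X2, y2 = smote_oversample(X, y, k_neighbors=1, seed=1)
    synth = X2[len(X):]
    assert np.allclose(synth[:, 0], synth[:, 1])
    assert ((synth >= 0.0) & (synth <= 1.0)).all()


def test_smote_restores_study_class_balance():
    rng = np.random.default_rng(2)
    sizes = {"WE": 287, "SA": 143, "AC": 142}
    X = rng.normal(size=(sum(sizes.values()), 5))
    y = np.concatenate([[g] * n for g, n in sizes.items()])
    X2, y2 = smote_oversample(X, y, 5, seed=2)
    counts = {g: int(np.sum(y2 == g)) for g in sizes}
    assert counts == {"WE": 287, "SA": 287, "AC": 287}


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_smote_stays_in_minority_convex_hull_1d(seed):
    rng = np.random.default_rng(seed)
    Xm = np.sort(rng.normal(size=6))[:, None]
    X = np.vstack([Xm, rng.normal(10, 1, size=(12, 1))])
    y = np.array(["m"] * 6 + ["M"] * 12)
    X2, y2 = smote_oversample(X, y, 3, seed=seed)
    synth = X2[len(X):, 0]
    assert (synth >= Xm.min() - 1e-12).all() and (synth <= Xm.max() + 1e-12).all()


# -- bootstrap / permutation --------------------------------------------------

def test_identical_rows_per_class_give_perfect_oob():
    X = np.vstack([np.tile([0.0, 0.0, 5.0], (6, 1)), np.tile([5.0, 5.0, 0.0], (6, 1))])
    y = np.array(["A"] * 6 + ["B"] * 6)
    cfg = BootstrapConfig(n_boot=20, n_perm=1, seed=0, max_components=2, inner_cv_folds=0)
    summary = bootstrap_validate(X, y, cfg)
    assert np.all(summary.observed_ccr == 100.0)


def test_bootstrap_deterministic_under_seed(small_synth):
    X = np.random.default_rng(0).normal(size=(40, 8))
    y = np.repeat(["A", "B"], 20)
    cfg = BootstrapConfig(n_boot=15, n_perm=10, seed=7, max_components=3, inner_cv_folds=0)
    s1 = bootstrap_validate(X, y, cfg)
    s2 = bootstrap_validate(X, y, cfg)
    assert np.array_equal(s1.observed_ccr, s2.observed_ccr)
    n1 = permutation_null(X, y, cfg)
    n2 = permutation_null(X, y, cfg)
    assert np.array_equal(n1, n2)


def test_empirical_p_formula():
    nulls = np.array([10.0, 20.0, 30.0, 95.0])
    assert empirical_p(90.0, nulls) == pytest.approx(2 / 5)
    assert empirical_p(99.0, nulls) == pytest.approx(1 / 5)


def test_attach_null_on_separated_histograms():
    X, y = separable_data(n_per=15, gap=12.0)
    cfg = BootstrapConfig(n_boot=25, n_perm=25, seed=3, max_components=2, inner_cv_folds=0)
    summary = bootstrap_validate(X, y, cfg)
    nulls = permutation_null(X, y, cfg)
    attach_null(summary, nulls)
    assert summary.empirical_p == pytest.approx(1 / 26)


# -- PCA ----------------------------------------------------------------------

def test_rank_one_matrix_pc1_explains_everything():
    u = np.arange(5.0)[:, None]
    v = np.array([[1.0, 2.0, 3.0]])
    scores, var = pca_scores(u @ v, 2)
    assert var[0] == pytest.approx(1.0)


def test_orthogonal_design_variance_split():
    # two orthogonal directions with SDs 2 and 1 -> variance split 4:1
    rng = np.random.default_rng(0)
    n = 20000
    X = np.zeros((n, 2))
    X[:, 0] = rng.normal(0, 2, n)
    X[:, 1] = rng.normal(0, 1, n)
    _, var = pca_scores(X, 2)
    assert var[0] == pytest.approx(0.8, abs=0.01)


def test_qcs_cluster_tighter_than_samples_in_pc_space(small_synth):
    table, _ = small_synth
    from metaboclass.preprocess import run_preprocess

    proc, _ = run_preprocess(table)
    scores, _ = pca_scores(proc.intensities.to_numpy(), 2)
    qc = scores[proc.qc_mask]
    samp = scores[proc.sample_mask]

    def mean_pairwise(a):
        d = np.linalg.norm(a[:, None] - a[None, :], axis=2)
        return d[np.triu_indices(len(a), 1)].mean()

    assert mean_pairwise(qc) < mean_pairwise(samp)
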