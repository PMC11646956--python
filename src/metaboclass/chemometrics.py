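"""PLS-DA classification with bootstrap and permutation validation.

Partial least squares discriminant analysis (PLS-DA) regresses a one-hot
class indicator matrix Y on the feature matrix X by NIPALS PLS2 and
classifies by argmax over the predicted indicator columns.  Model quality
is reported the way validated chemometrics studies report it: the correct
classification rate (CCR) of out-of-bag test sets over bootstrap
resamples, against a null distribution obtained by refitting after random
permutation of the class labels.  Class imbalance can be addressed with
SMOTE oversampling, applied either globally or (leak-free) inside each
bootstrap training set only.

The NIPALS implementation here is self-contained; scikit-learn is not a
runtime dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "BootstrapConfig",
    "ValidationSummary",
    "fit_pls",
    "predict_classes",
    "ccr",
    "classwise_rates",
    "macro_metrics",
    "smote_oversample",
    "bootstrap_validate",
    "permutation_null",
    "empirical_p",
    "pca_scores",
]


@dataclass
class PLSModel:
    """Fitted PLS2 discriminant model (NIPALS, X deflated each component)."""

    n_components: int
    weights: np.ndarray  # W, features x A, unit-norm columns
    loadings: np.ndarray  # P, features x A
    y_loadings: np.ndarray  # C, classes x A
    scores: np.ndarray  # T, train samples x A, mutually orthogonal
    coef: np.ndarray  # B, features x classes
    classes: list  # label order of the one-hot encoding
    x_mean: np.ndarray
    y_mean: np.ndarray


def one_hot(y, classes=None):
    y = np.asarray(y)
    if classes is None:
        classes = sorted(set(y.tolist()))
    Y = np.zeros((len(y), len(classes)))
    for k, c in enumerate(classes):
        Y[y == c, k] = 1.0
    return Y, list(classes)


def fit_pls(X, y, n_components, tol=1e-12, max_iter=1000) -> PLSModel:
    """Fit a PLS2 discriminant model by NIPALS.

    X is centred on its column means (no additional scaling; the caller
    scales, e.g. by Pareto scaling, upstream).  Y is the centred one-hot
    indicator matrix.  Each component: iterate weight/score updates to
    convergence, then deflate X (and Y) by the score's rank-one
    approximation.  Sign convention: the largest-magnitude element of each
    weight vector is positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("fit_pls requires at least 2 classes")
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    Y, classes = one_hot(y, classes)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean

    A = n_components
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    C = np.zeros((len(classes), A))
    T = np.zeros((n, A))
    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(A):
        u = Yd[:, np.argmax(np.var(Yd, axis=0))].copy()
        if np.linalg.norm(u) < tol:
            A = a
            break
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw < tol:
                break
            w /= nw
            t = Xd @ w
            c = Yd.T @ t / (t @ t)
            u = Yd @ c / (c @ c)
            if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        # deterministic sign: largest-|w| element positive
        sign = np.sign(w[np.argmax(np.abs(w))]) or 1.0
        w, t, c = w * sign, t * sign, c * sign
        tt = t @ t
        if tt < tol:
            A = a
            break
        pvec = Xd.T @ t / tt
        Xd = Xd - np.outer(t, pvec)
        Yd = Yd - np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, pvec, c, t
    if A == 0:
        raise ValueError("no PLS component could be extracted (X has no variance)")
    W, P, C, T = W[:, :A], P[:, :A], C[:, :A], T[:, :A]
    # B = W (P'W)^{-1} C'
    coef = W @ np.linalg.solve(P.T @ W, C.T)
    return PLSModel(A, W, P, C, T, coef, classes, x_mean, y_mean)


def predict_scores(model: PLSModel, X_new):
    """Predicted one-hot responses for new observations."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"feature count mismatch: model has {model.coef.shape[0]}, "
            f"input has {X_new.shape[1]}"
        )
    return (X_new - model.x_mean) @ model.coef + model.y_mean


def predict_classes(model: PLSModel, X_new):
    """Argmax decision rule; exact ties go to the lexicographically first class."""
    Yhat = predict_scores(model, X_new)
    # classes are stored sorted, and np.argmax takes the first maximum,
    # which is the lexicographically first label on ties
    idx = np.argmax(Yhat, axis=1)
    return np.array([model.classes[k] for k in idx])


# -- classification metrics ---------------------------------------------------


def ccr(true_labels, predicted):
    """Correct classification rate, percent."""
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted)
    if len(true_labels) != len(predicted):
        raise ValueError("label vectors must have equal length")
    return 100.0 * np.mean(true_labels == predicted)


def classwise_rates(true_labels, predicted):
    """Per-class CCR (recall), percent, as a dict label -> rate."""
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted)
    out = {}
    for c in sorted(set(true_labels.tolist())):
        m = true_labels == c
        out[c] = 100.0 * np.mean(predicted[m] == c)
    return out


def macro_metrics(true_labels, predicted):
    """Macro-averaged one-vs-rest (sensitivity, specificity, accuracy), percent."""
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted)
    classes = sorted(set(true_labels.tolist()) | set(predicted.tolist()))
    sens, spec = [], []
    for c in classes:
        tp = np.sum((true_labels == c) & (predicted == c))
        fn = np.sum((true_labels == c) & (predicted != c))
        tn = np.sum((true_labels != c) & (predicted != c))
        fp = np.sum((true_labels != c) & (predicted == c))
        if tp + fn:
            sens.append(100.0 * tp / (tp + fn))
        if tn + fp:
            spec.append(100.0 * tn / (tn + fp))
    accuracy = 100.0 * np.mean(true_labels == predicted)
    return float(np.mean(sens)), float(np.mean(spec)), float(accuracy)


# -- SMOTE --------------------------------------------------------------------


def smote_oversample(X, y, k_neighbors=5, seed=0):
    """Synthetic minority oversampling (SMOTE).

    Every minority class is upsampled to the majority class size.  Each
    synthetic point is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1) and
    x_nn drawn from the k nearest minority-class neighbours of x_i
    (Euclidean), so synthetic points never leave the minority class's
    convex hull.  If a class has fewer than k+1 members, k is reduced.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    counts = {c: np.sum(y == c) for c in sorted(set(y.tolist()))}
    target = max(counts.values())
    X_out, y_out = [X], [y]
    for c, n_c in counts.items():
        deficit = target - n_c
        if deficit == 0:
            continue
        Xc = X[y == c]
        k = min(k_neighbors, n_c - 1)
        if k < 1:
            raise ValueError(f"class {c!r} has a single member; SMOTE impossible")
        # pairwise distances within the class (classes are small here)
        d = np.linalg.norm(Xc[:, None, :] - Xc[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1)[:, :k]
        base = rng.integers(0, n_c, deficit)
        pick = nn[base, rng.integers(0, k, deficit)]
        u = rng.random(deficit)[:, None]
        synth = Xc[base] + u * (Xc[pick] - Xc[base])
        X_out.append(synth)
        y_out.append(np.full(deficit, c, dtype=y.dtype))
    return np.vstack(X_out), np.concatenate(y_out)


# -- bootstrap / permutation validation ---------------------------------------


@dataclass
class BootstrapConfig:
    """Resampling settings for bootstrap validation and permutation nulls."""

    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 0
    max_components: int = 15
    inner_cv_folds: int = 7  # 0 disables inner CV and fixes A = max_components
    smote: str = "off"  # off | global | fold
    k_neighbors: int = 5

    def __post_init__(self):
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("n_boot and n_perm must be >= 1")
        if self.smote not in ("off", "global", "fold"):
            raise ValueError("smote must be off, global or fold")


@dataclass
class ValidationSummary:
    """Observed and null CCR distributions plus summary rates (percent)."""

    observed_ccr: np.ndarray
    mean_ccr: float
    classwise_ccr: dict
    sensitivity: float
    specificity: float
    accuracy: float
    null_ccr: np.ndarray = field(default_factory=lambda: np.array([]))
    empirical_p: float = float("nan")

    def to_dict(self):
        return {
            "mean_ccr": self.mean_ccr,
            "classwise_ccr": self.classwise_ccr,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "n_boot": int(len(self.observed_ccr)),
            "n_perm": int(len(self.null_ccr)),
            "empirical_p": self.empirical_p,
        }


def _predict_per_A(W, P, C, x_mean, y_mean, classes, X_test, A_list):
    """Class predictions of the truncated model for every A in A_list."""
    Xc = np.atleast_2d(X_test) - x_mean
    out = {}
    for A in A_list:
        Wa, Pa, Ca = W[:, :A], P[:, :A], C[:, :A]
        B = Wa @ np.linalg.solve(Pa.T @ Wa, Ca.T)
        Yhat = Xc @ B + y_mean
        out[A] = np.array([classes[k] for k in np.argmax(Yhat, axis=1)])
    return out


def select_components(X, y, max_components, n_folds, rng):
    """Pick the component count minimising inner-CV misclassification."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    max_A = min(max_components, n - max(2, n // n_folds) - 1, X.shape[1])
    max_A = max(max_A, 1)
    if n_folds < 2 or max_A == 1:
        return max_A
    idx = rng.permutation(n)
    folds = np.array_split(idx, n_folds)
    errors = np.zeros(max_A)
    counted = np.zeros(max_A)
    for f in folds:
        train = np.setdiff1d(idx, f, assume_unique=False)
        if len(set(y[train].tolist())) < 2 or len(f) == 0:
            continue
        A_cap = min(max_A, len(train) - 1, X.shape[1])
        model = fit_pls(X[train], y[train], A_cap)
        preds = _predict_per_A(
            model.weights, model.loadings, model.y_loadings,
            model.x_mean, model.y_mean, model.classes,
            X[f], range(1, model.n_components + 1),
        )
        for A, yhat in preds.items():
            errors[A - 1] += np.sum(yhat != y[f])
            counted[A - 1] += len(f)
    valid = counted > 0
    if not valid.any():
        return 1
    rates = np.where(valid, errors / np.maximum(counted, 1), np.inf)
    return int(np.argmin(rates) + 1)  # ties -> fewest components


def _one_bootstrap_cycle(X, y, config, rng):
    """Draw train/OOB, optional fold-SMOTE, select A, fit, score the OOB set.

    Degenerate draws (empty OOB or single-class training) are redrawn.
    """
    n = len(y)
    for _ in range(100):
        train = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), train)
        if len(oob) == 0 or len(set(y[train].tolist())) < 2:
            continue
        Xtr, ytr = X[train], y[train]
        if config.smote == "fold":
            Xtr, ytr = smote_oversample(
                Xtr, ytr, config.k_neighbors, seed=int(rng.integers(2**31))
            )
        if config.inner_cv_folds >= 2:
            A = select_components(Xtr, ytr, config.max_components, config.inner_cv_folds, rng)
        else:
            A = min(config.max_components, len(ytr) - 1, X.shape[1])
        model = fit_pls(Xtr, ytr, A)
        yhat = predict_classes(model, X[oob])
        return y[oob], yhat
    raise RuntimeError("could not draw a usable bootstrap sample in 100 attempts")


def bootstrap_validate(X, y, config: BootstrapConfig) -> ValidationSummary:
    """Bootstrap-validated PLS-DA: OOB test-set CCR over ``n_boot`` resamples.

    Each iteration draws n samples with replacement as the training set and
    uses the out-of-bag samples as its test set; the component count is
    chosen by inner cross-validation on the training set.  Classwise rates
    and macro metrics are pooled over all OOB predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if config.smote == "global":
        X, y = smote_oversample(X, y, config.k_neighbors, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    ccrs = np.empty(config.n_boot)
    pooled_true, pooled_pred = [], []
    for b in range(config.n_boot):
        yt, yp = _one_bootstrap_cycle(X, y, config, rng)
        ccrs[b] = ccr(yt, yp)
        pooled_true.append(yt)
        pooled_pred.append(yp)
    yt = np.concatenate(pooled_true)
    yp = np.concatenate(pooled_pred)
    sens, spec, acc = macro_metrics(yt, yp)
    return ValidationSummary(
        observed_ccr=ccrs,
        mean_ccr=float(np.mean(ccrs)),
        classwise_ccr=classwise_rates(yt, yp),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
    )


def permutation_null(X, y, config: BootstrapConfig) -> np.ndarray:
    """Null CCR distribution: permute the labels, then one bootstrap cycle each.

    ``n_perm`` null models are generated; each permutes y, draws one
    bootstrap training set and scores its out-of-bag samples, giving the
    test-set CCR a label-free dataset would achieve.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if config.smote == "global":
        X, y = smote_oversample(X, y, config.k_neighbors, seed=config.seed)
    rng = np.random.default_rng((config.seed, 0x9E3779B9))
    nulls = np.empty(config.n_perm)
    for i in range(config.n_perm):
        yperm = rng.permutation(y)
        yt, yp = _one_bootstrap_cycle(X, yperm, config, rng)
        nulls[i] = ccr(yt, yp)
    return nulls


def empirical_p(observed_mean, null_ccrs):
    """Permutation p-value: (1 + #{null >= observed}) / (n_perm + 1)."""
    null_ccrs = np.asarray(null_ccrs)
    return float((1 + np.sum(null_ccrs >= observed_mean)) / (len(null_ccrs) + 1))


def attach_null(summary: ValidationSummary, null_ccrs) -> ValidationSummary:
    """Store the null distribution and its empirical p on a summary."""
    summary.null_ccr = np.asarray(null_ccrs)
    summary.empirical_p = empirical_p(summary.mean_ccr, null_ccrs)
    return summary


# -- PCA ----------------------------------------------------------------------


def pca_scores(X, n_pc=2):
    """SVD principal-component scores and explained-variance fractions."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2 / np.sum(S**2) if np.sum(S**2) > 0 else np.zeros_like(S)
    n_pc = min(n_pc, len(S))
    return U[:, :n_pc] * S[:n_pc], var[:n_pc]
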