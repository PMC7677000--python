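"""PCA, two-class PLS-DA with VIP scores, and permutation validation.

The screening contrasts each producing strain against the growth medium
(and against the non-protective control strain) with a partial
least-squares discriminant analysis.  Components are extracted by the
NIPALS algorithm for a univariate response (class membership coded 0/1);
per-feature variable-importance-in-projection (VIP) scores summarize how
much each feature contributes to the class separation, normalized so the
mean squared VIP over features is exactly 1.  A label-permutation test
guards against overfitting: the model passes when every permuted model has
a lower cross-validated Q2 than the original and the regression of
permuted Q2 on the label correlation intercepts the vertical axis below
zero.

Feature matrices are log10-transformed, column-centered and (by default)
unit-variance scaled before decomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputError
from .feature_io import FeatureTable

logger = logging.getLogger(__name__)

#: Convergence tolerance for the NIPALS inner loop (vector 2-norm change).
NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


def _design_matrix(table, log_transform: bool = True):
    """samples x features float matrix (+ feature ids, sample ids)."""
    if isinstance(table, FeatureTable):
        X = table.intensities.to_numpy(dtype=float).T
        if np.isnan(X).any():
            raise InputError("multivariate analysis requires an imputed table")
        feature_ids = list(table.features.index)
        sample_ids = list(table.samples.index)
    else:
        X = np.asarray(table, dtype=float)
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
    if log_transform:
        if np.any(X <= 0):
            raise InputError("log transform requires positive intensities")
        X = np.log10(X)
    return X, feature_ids, sample_ids


@dataclass
class PcaResult:
    scores: pd.DataFrame           # samples x components
    loadings: pd.DataFrame         # features x components
    explained_variance_fraction: np.ndarray


def pca(table, n_components: int = 2, scale: bool = True,
        log_transform: bool = True) -> PcaResult:
    """Principal-component analysis by SVD of the centered (and optionally
    unit-variance scaled) log10 matrix.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so results are reproducible across runs.
    """
    X, feature_ids, sample_ids = _design_matrix(table, log_transform)
    n, p = X.shape
    if n < 2:
        raise InputError("PCA needs at least 2 samples")
    if not 1 <= n_components <= min(n, p):
        raise InputError(f"n_components must be in [1, {min(n, p)}]")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for a in range(len(s)):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    total = float((s**2).sum())
    frac = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    comp = [f"PC{a + 1}" for a in range(n_components)]
    scores = pd.DataFrame(U[:, :n_components] * s[:n_components],
                          index=sample_ids, columns=comp)
    loadings = pd.DataFrame(Vt[:n_components].T, index=feature_ids, columns=comp)
    return PcaResult(scores, loadings, frac)


@dataclass
class PlsdaModel:
    """Two-class PLS-DA fitted by NIPALS (univariate response).

    ``weights``/``x_loadings`` are features x A; ``x_scores`` samples x A;
    ``y_loadings`` and ``y_explained_ss`` per component.  ``x_mean``,
    ``x_scale`` and ``y_mean`` hold the centering/scaling applied before
    decomposition; ``feature_ids`` lists the features kept after dropping
    zero-variance columns.
    """

    classes: tuple[str, str]
    n_components: int
    weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    y_explained_ss: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    feature_ids: list[str]
    log_transform: bool = True
    keep_mask: np.ndarray | None = None  # original-column mask after variance drop

    @property
    def coef(self) -> np.ndarray:
        """Regression vector B with ŷ = y_mean + X_scaled @ B."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        X = np.asarray(X_raw, dtype=float)
        if self.log_transform:
            X = np.log10(X)
        if self.keep_mask is not None and X.shape[1] == len(self.keep_mask):
            X = X[:, self.keep_mask]
        Xs = (X - self.x_mean) / self.x_scale
        return self.y_mean + Xs @ self.coef


def _encode_labels(labels) -> tuple[np.ndarray, tuple[str, str]]:
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise InputError(f"PLS-DA requires exactly two classes, got {classes}")
    y = np.array([1.0 if lab == classes[1] else 0.0 for lab in labels])
    for c, cnt in zip(classes, [len(labels) - int(y.sum()), int(y.sum())]):
        if cnt < 2:
            raise InputError(f"class {c!r} has fewer than 2 samples")
    return y, (classes[0], classes[1])


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Sequential NIPALS extraction with deflation for a univariate y."""
    n, p = Xc.shape
    X, y = Xc.copy(), yc.copy()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < NIPALS_TOL:
            raise ComputationError(
                f"no covariance left to extract component {a + 1}"
            )
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt < NIPALS_TOL:
            raise ComputationError(f"degenerate score vector at component {a + 1}")
        p_load = X.T @ t / tt
        q_a = float(y @ t) / tt
        X = X - np.outer(t, p_load)
        y = y - q_a * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_load, q_a
    ss = q**2 * np.einsum("ia,ia->a", T, T)  # Y sum of squares explained per component
    return W, T, P, q, ss


def plsda_fit(table, labels, n_components: int = 2,
              log_transform: bool = True) -> PlsdaModel:
    """Fit a two-class PLS-DA on a feature table (or samples x features array).

    X is log10-transformed, centered and unit-variance scaled; y is the 0/1
    class indicator, centered.  Zero-variance features are dropped with a
    warning before scaling.
    """
    X, feature_ids, _ = _design_matrix(table, log_transform)
    y, classes = _encode_labels(labels)
    if len(y) != X.shape[0]:
        raise InputError("labels length does not match number of samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("plsda_fit: dropping %d zero-variance features",
                       int((~keep).sum()))
        X = X[:, keep]
        feature_ids = [f for f, k in zip(feature_ids, keep) if k]
    if X.shape[1] == 0:
        raise InputError("no features with variance remain")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    Xc = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean
    W, T, P, q, ss = _nipals_pls1(Xc, yc, n_components)
    return PlsdaModel(
        classes=classes, n_components=n_components, weights=W, x_scores=T,
        x_loadings=P, y_loadings=q, y_explained_ss=ss, x_mean=x_mean,
        x_scale=x_scale, y_mean=y_mean, feature_ids=feature_ids,
        log_transform=log_transform, keep_mask=keep,
    )


def vip_scores(model: PlsdaModel) -> pd.Series:
    """Variable importance in projection.

    ``VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )`` with
    p the number of features; by construction ``mean(VIP^2) = 1``.
    """
    ss = model.y_explained_ss
    total = float(ss.sum())
    if total <= 0:
        raise ComputationError("degenerate PLS model: no Y variance explained")
    W = model.weights
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    p = W.shape[0]
    vip2 = p * ((W**2 / wnorm2) @ ss) / total
    return pd.Series(np.sqrt(vip2), index=model.feature_ids, name="vip")


@dataclass
class PermutationResult:
    n_perm: int
    r2_orig: float
    q2_orig: float
    r2_perm: np.ndarray
    q2_perm: np.ndarray
    y_correlations: np.ndarray
    q2_intercept: float
    passed: bool


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment per sample, stratified by class, deterministic in rng."""
    fold = np.empty(len(y), dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = np.arange(len(idx)) % k
    return fold


def _r2_q2(X: np.ndarray, y: np.ndarray, n_components: int, fold: np.ndarray,
           log_transform: bool) -> tuple[float, float]:
    labels = np.where(y == 1, "b", "a")
    model = plsda_fit(X, labels, n_components, log_transform=log_transform)
    resid = y - model.predict(X)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - float((resid**2).sum()) / tss
    press = 0.0
    for f in np.unique(fold):
        test = fold == f
        sub = plsda_fit(X[~test], labels[~test],
                        n_components, log_transform=log_transform)
        press += float(((y[test] - sub.predict(X[test])) ** 2).sum())
    return r2, 1 - press / tss


def permutation_test(table, labels, n_components: int = 2, n_perm: int = 100,
                     seed: int = 0, k_folds: int = 7,
                     log_transform: bool = True) -> PermutationResult:
    """Label-permutation overfitting diagnostic for a two-class PLS-DA.

    For each permutation the model is refit and the K-fold cross-validated
    Q2 (1 - PRESS/TSS, folds stratified by class and fixed by ``seed``) is
    recorded together with |corr(permuted y, y)|.  The model passes when
    every permuted Q2 is below the original and the straight-line fit of Q2
    against the correlation (original point included at correlation 1)
    intercepts the axis below zero.
    """
    if n_perm < 20:
        raise InputError("n_perm must be >= 20")
    X, _, _ = _design_matrix(table, log_transform)
    y, _ = _encode_labels(labels)
    n_min = int(min((y == 0).sum(), (y == 1).sum()))
    k = min(k_folds, n_min)
    if k < k_folds:
        logger.warning("permutation_test: reducing folds %d -> %d", k_folds, k)
    if k < 2:
        raise InputError("class sizes too small for cross-validation")
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, k, rng)
    # X already log-transformed by _design_matrix
    r2_orig, q2_orig = _r2_q2(X, y, n_components, fold, log_transform=False)
    r2_perm = np.empty(n_perm)
    q2_perm = np.empty(n_perm)
    corrs = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        while yp.std() == 0:  # cannot happen with two classes >= 2 each
            yp = rng.permutation(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrs[i] = abs(float(stats.pearsonr(yp, y)[0]))
        fold_p = _stratified_folds(yp, k, rng)
        r2_perm[i], q2_perm[i] = _r2_q2(X, yp, n_components, fold_p,
                                        log_transform=False)
    xs = np.concatenate([corrs, [1.0]])
    ys = np.concatenate([q2_perm, [q2_orig]])
    slope, intercept = np.polyfit(xs, ys, 1)
    passed = bool(np.all(q2_perm < q2_orig) and intercept < 0)
    return PermutationResult(
        n_perm=n_perm, r2_orig=r2_orig, q2_orig=q2_orig, r2_perm=r2_perm,
        q2_perm=q2_perm, y_correlations=corrs, q2_intercept=float(intercept),
        passed=passed,
    )
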