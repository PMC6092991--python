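"""Common Spatial Patterns: two-class and one-vs-rest multiclass filters
plus log-normalized-variance features.

A CSP filter ``w`` maximizes the variance ratio between two signal
classes; it is an eigenvector of the generalized problem

    Sigma_a w = lambda (Sigma_a + Sigma_b) w,       lambda in [0, 1],

solved here by whitening the composite covariance.  For K classes the
one-vs-rest (OVR) scheme pits each class covariance against the
unweighted mean of the remaining ones and keeps the first (largest
eigenvalue) and last (smallest) eigenvector of each subproblem, giving
L = 2K filters (8 for four motor-imagery classes).  From a filtered
trial ``Z = W X`` the feature vector is the log of the normalized row
variances:

    v_p = log( var(Z_p) / sum_i var(Z_i) ),     p = 1..L,

so sum_p exp(v_p) = 1 for every valid input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ClassCovariances",
    "CSPModel",
    "class_covariances",
    "csp_two_class",
    "csp_multiclass_ovr",
    "apply_csp",
    "log_variance_features",
    "OneVsRestCSP",
]

logger = logging.getLogger(__name__)

RIDGE_FRACTION = 1e-8


@dataclass
class ClassCovariances:
    """Per-class mean spatial covariance of trace-normalized trials."""

    covariances: dict[int, np.ndarray]
    n: int
    trial_counts: dict[int, int] = field(default_factory=dict)

    @property
    def classes(self) -> list[int]:
        return sorted(self.covariances)


@dataclass
class CSPModel:
    """Spatial projection W (L x n); rows are the spatial filters."""

    W: np.ndarray
    class_order: list[int]
    source_kind: str = "sensor"
    roi_name: str | None = None
    eigenvalues: np.ndarray | None = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if not np.all(np.isfinite(self.W)):
            raise ValueError("CSP projection has non-finite rows")
        if np.any(~np.any(self.W != 0, axis=1)):
            raise ValueError("CSP projection has an all-zero row")

    @property
    def L(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]


def trial_covariances(X: np.ndarray, normalize_trace: bool = True) -> np.ndarray:
    """Stack of per-trial spatial covariances (channel means removed).

    With ``normalize_trace`` each trial covariance is divided by its
    trace, the standard CSP normalization that removes trial-to-trial
    global amplitude differences.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected trials x channels x samples")
    if X.shape[2] < 2:
        raise ValueError("trials need at least 2 samples")
    Xc = X - X.mean(axis=2, keepdims=True)
    C = np.einsum("tcs,tds->tcd", Xc, Xc)
    if normalize_trace:
        tr = np.trace(C, axis1=1, axis2=2)
        if np.any(tr <= 0):
            raise ValueError("trial with zero total variance")
        C = C / tr[:, None, None]
    else:
        C = C / max(X.shape[2] - 1, 1)
    return C


def class_covariances(data, labels=None) -> ClassCovariances:
    """Mean trace-normalized covariance per class, with a tiny ridge.

    ``data`` may be a (trials, n, samples) array plus ``labels``, or any
    epochs container exposing ``.data`` and ``.labels``.
    """
    if labels is None:
        labels = data.labels
        data = data.data
    labels = np.asarray(labels)
    C = trial_covariances(data)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    covs, counts = {}, {}
    for k in classes:
        mask = labels == k
        if not mask.any():
            raise ValueError(f"class {k} has zero trials")
        mean_cov = C[mask].mean(axis=0)
        ridge = RIDGE_FRACTION * float(np.mean(np.diag(mean_cov)))
        covs[int(k)] = mean_cov + ridge * np.eye(mean_cov.shape[0])
        counts[int(k)] = int(mask.sum())
    return ClassCovariances(covariances=covs, n=C.shape[1], trial_counts=counts)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(W), axis=1)
    signs = np.sign(W[np.arange(W.shape[0]), idx])
    signs[signs == 0] = 1.0
    return W * signs[:, None]


def _csp_eig(cov_a: np.ndarray, cov_b: np.ndarray):
    """All generalized eigenpairs of (cov_a, cov_a + cov_b), descending.

    Solved by whitening the composite covariance, which is numerically
    stabler than direct inversion.  Returns (eigenvalues, filters) with
    filters as rows scaled so w (cov_a + cov_b) w^T = 1.
    """
    comp = cov_a + cov_b
    w, V = np.linalg.eigh(comp)
    tol = w.max() * 1e-12 if w.max() > 0 else 0.0
    if np.any(w <= tol):
        raise np.linalg.LinAlgError(
            "composite covariance singular after ridge; cannot whiten")
    P = V @ np.diag(w ** -0.5) @ V.T  # symmetric whitener
    lam, U = np.linalg.eigh(P @ cov_a @ P)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, 1.0)
    W = (P @ U[:, order]).T
    return lam, _fix_signs(W)


def csp_two_class(cov_a: np.ndarray, cov_b: np.ndarray,
                  n_filters: int = 8) -> CSPModel:
    """Two-class CSP keeping n_filters/2 top and n_filters/2 bottom filters."""
    cov_a = np.asarray(cov_a, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    if cov_a.shape != cov_b.shape or cov_a.ndim != 2:
        raise ValueError("covariances must share a square shape")
    n = cov_a.shape[0]
    if n_filters % 2 or n_filters < 2:
        raise ValueError("n_filters must be even and >= 2")
    if n_filters > n:
        raise ValueError(f"n_filters={n_filters} exceeds dimension {n}")
    lam, W = _csp_eig(cov_a, cov_b)
    half = n_filters // 2
    keep = list(range(half)) + list(range(n - half, n))
    return CSPModel(W=W[keep], class_order=[0, 1],
                    eigenvalues=lam[keep])


def csp_multiclass_ovr(covs: ClassCovariances,
                       filters_per_class: int = 2) -> CSPModel:
    """One-vs-rest multiclass CSP.

    For every class the 'rest' covariance is the unweighted mean of the
    other classes' mean covariances; the first and last eigenvector of
    each subproblem are kept and stacked in ascending class order.  When
    the input dimension cannot support 2K independent filters (tiny
    synthetic ROIs), the stack is reduced to at most ``n`` rows by
    greedily keeping the most discriminative (|lambda - 1/2| largest)
    non-collinear filters, with a logged warning.
    """
    classes = covs.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if filters_per_class % 2:
        raise ValueError("filters_per_class must be even")
    n = covs.n
    rows, lams, scores = [], [], []
    for k in classes:
        rest = np.mean([covs.covariances[j] for j in classes if j != k], axis=0)
        lam, W = _csp_eig(covs.covariances[k], rest)
        take = list(range(filters_per_class // 2)) + \
            list(range(n - filters_per_class // 2, n))
        for i in take:
            rows.append(W[i])
            lams.append(lam[i])
            scores.append(abs(lam[i] - 0.5))
    W = np.asarray(rows)
    lam = np.asarray(lams)
    L_full = W.shape[0]
    cap = max(2, (n * (n + 1)) // 2)
    if L_full > cap:
        logger.warning(
            "input dimension %d < %d OVR filters; reducing to the %d most "
            "discriminative non-collinear filters", n, L_full, cap)
        order = np.argsort(scores)[::-1]
        Wn = W / np.linalg.norm(W, axis=1, keepdims=True)
        keep: list[int] = []
        for i in order:
            if any(abs(Wn[i] @ Wn[j]) > 0.999 for j in keep):
                continue
            keep.append(i)
            if len(keep) == cap:
                break
        while len(keep) < min(n, 2):
            # a single filter yields a constant feature; force a second,
            # least-collinear one in
            cos = np.max(np.abs(Wn @ Wn[keep].T), axis=1)
            cos[keep] = np.inf
            keep.append(int(np.argmin(cos)))
        keep.sort()  # preserve class-order stacking among survivors
        W, lam = W[keep], lam[keep]
    return CSPModel(W=W, class_order=list(classes), eigenvalues=lam)


def apply_csp(model: CSPModel, X: np.ndarray) -> np.ndarray:
    """Spatially filter one trial (or a stack of trials): Z = W X."""
    X = np.asarray(X, dtype=float)
    if X.shape[-2] != model.n:
        raise ValueError(
            f"input has {X.shape[-2]} channels, projection expects {model.n}")
    return model.W @ X


def log_variance_features(Z: np.ndarray) -> np.ndarray:
    """Eq.-style feature: v_p = log(var(Z_p) / sum_i var(Z_i))."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("expected L x samples with samples >= 2")
    v = Z.var(axis=1, ddof=1)
    if np.any(v <= 0):
        raise ValueError("zero-variance filter output; log feature undefined")
    return np.log(v / v.sum())


def _features_from_trial_covs(W: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Log-variance features straight from per-trial covariances.

    var(w X) = w C_trial w^T when C_trial has channel means removed, so
    this equals log_variance_features(apply_csp(...)) up to the common
    normalization that cancels in the ratio.
    """
    var = np.einsum("ln,tnm,lm->tl", W, C, W)
    var = np.maximum(var, np.finfo(float).tiny)
    return np.log(var / var.sum(axis=1, keepdims=True))


class OneVsRestCSP(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: epochs (trials, n, samples) -> features.

    Parameters
    ----------
    filters_per_class : int
        Even number of filters kept per OVR subproblem (first + last
        eigenvectors); total L = filters_per_class * n_classes, reduced
        if the input dimension is smaller.

    Attributes
    ----------
    model_ : CSPModel
        Fitted projection.
    classes_ : ndarray
        Class labels seen during fit, ascending.
    """

    def __init__(self, filters_per_class: int = 2):
        self.filters_per_class = filters_per_class

    def fit(self, X, y):
        covs = class_covariances(np.asarray(X), np.asarray(y))
        self.model_ = csp_multiclass_ovr(covs, self.filters_per_class)
        self.classes_ = np.asarray(covs.classes)
        self.n_features_in_ = covs.n
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        C = trial_covariances(X, normalize_trace=False)
        return _features_from_trial_covs(self.model_.W, C)

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X, y).transform(X)
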