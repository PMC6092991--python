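"""Linear discriminant analysis with a pooled within-class covariance.

Classic Gaussian LDA: each class is modelled with its own mean and a
shared covariance, giving the linear discriminant score

    s_k(x) = x^T S^{-1} mu_k - 0.5 mu_k^T S^{-1} mu_k + log pi_k.

Optional shrinkage pulls the pooled covariance toward its own diagonal,
S(s) = (1 - s) S + s diag(S), which keeps the fit well-posed on tiny or
collinear feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["LDAModel", "ShrinkageLDA", "lda_fit", "lda_predict"]


@dataclass
class LDAModel:
    """Fitted LDA parameters."""

    class_means: dict[int, np.ndarray]
    pooled_covariance: np.ndarray
    priors: dict[int, float]
    shrinkage: float = 0.0
    coef_: np.ndarray = field(default=None, repr=False)
    intercept_: np.ndarray = field(default=None, repr=False)

    @property
    def classes(self) -> list[int]:
        return sorted(self.class_means)


def lda_fit(features: np.ndarray, labels, shrinkage: float = 0.0) -> LDAModel:
    """Fit class means, pooled within-class covariance and empirical priors."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (trials x L)")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must lie in [0, 1]")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    n, L = X.shape
    means, priors = {}, {}
    S = np.zeros((L, L))
    for k in classes:
        Xk = X[y == k]
        if Xk.shape[0] < 2:
            raise ValueError(f"class {k} needs at least 2 trials")
        mu = Xk.mean(axis=0)
        means[int(k)] = mu
        priors[int(k)] = Xk.shape[0] / n
        d = Xk - mu
        S += d.T @ d
    S /= (n - classes.size)
    if shrinkage > 0:
        S = (1 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    try:
        cho = scipy.linalg.cho_factor(S)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; use shrinkage > 0") from exc
    mu_mat = np.stack([means[int(k)] for k in classes])  # K x L
    Sinv_mu = scipy.linalg.cho_solve(cho, mu_mat.T).T
    coef = Sinv_mu
    intercept = (-0.5 * np.einsum("kl,kl->k", mu_mat, Sinv_mu)
                 + np.log([priors[int(k)] for k in classes]))
    return LDAModel(class_means=means, pooled_covariance=S, priors=priors,
                    shrinkage=shrinkage, coef_=coef, intercept_=intercept)


def lda_predict(model: LDAModel, features: np.ndarray):
    """Return (labels, scores): argmax class and the per-class scores.

    Ties (scores equal to machine precision) resolve to the smallest
    class label via the stable argmax.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.coef_.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.coef_.shape[1]})")
    scores = X @ model.coef_.T + model.intercept_
    classes = np.asarray(model.classes)
    labels = classes[np.argmax(scores, axis=1)]
    return labels, scores


class ShrinkageLDA(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper around :func:`lda_fit` / :func:`lda_predict`.

    Attributes
    ----------
    model_ : LDAModel
    classes_ : ndarray
    """

    def __init__(self, shrinkage: float = 0.0):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        self.model_ = lda_fit(X, y, shrinkage=self.shrinkage)
        self.classes_ = np.asarray(self.model_.classes)
        return self

    def decision_function(self, X):
        _, scores = lda_predict(self.model_, X)
        return scores

    def predict(self, X):
        labels, _ = lda_predict(self.model_, X)
        return labels
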