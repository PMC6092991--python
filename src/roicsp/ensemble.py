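"""Per-ROI CSP + LDA classifiers, cross-validated ROI ranking, top-Q
selection and majority-vote fusion.

Every region of interest gets its own one-vs-rest CSP projection and LDA
model.  ROIs are ranked by repeated stratified 10-fold cross-validation
(CSP and LDA refit inside every training fold, so no information from a
held-out fold ever reaches the filters), the Q most accurate ROIs are
selected, and at inference each selected ROI votes; the modal class
wins, with ties broken by the summed LDA scores over the tied classes
and, failing that, the smallest class label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .containers import SensorEpochs, SourceEpochs
from .csp import (CSPModel, ClassCovariances, RIDGE_FRACTION,
                  _features_from_trial_covs, csp_multiclass_ovr,
                  trial_covariances)
from .lda import LDAModel, lda_fit, lda_predict
from .rois import ROI, ROICatalog

__all__ = [
    "ROIClassifier", "ROIRanking", "EnsembleModel",
    "fit_roi_classifier", "roi_cv_accuracy", "rank_rois", "select_rois",
    "train_ensemble", "predict_ensemble", "majority_vote",
    "sensor_baseline", "alt_classifier_comparison", "ROIEnsembleClassifier",
]

logger = logging.getLogger(__name__)


@dataclass
class ROIClassifier:
    """One region's CSP projection plus LDA model (and its vertices)."""

    roi_name: str
    csp: CSPModel
    lda: LDAModel
    vertices: np.ndarray | None = None

    def __post_init__(self):
        if self.csp.L != self.lda.coef_.shape[1]:
            raise ValueError("CSP filter count does not match LDA dimension")


@dataclass
class ROIRanking:
    """Mean and per-repeat-per-fold CV accuracy for every ranked ROI."""

    names: list[str]
    mean_accuracy: dict[str, float]
    fold_accuracies: dict[str, np.ndarray]  # (repeats, folds)
    folds: int
    repeats: int
    seed: int


@dataclass
class EnsembleModel:
    """Q selected ROIs with their classifiers and the vote policy."""

    selected_rois: list[str]
    classifiers: dict[str, ROIClassifier]
    Q: int
    tie_break: str = "score_sum_then_index"
    ranking: ROIRanking | None = None
    class_order: list[int] = field(default_factory=list)

    def __post_init__(self):
        if len(self.selected_rois) != len(self.classifiers):
            raise ValueError("one classifier per selected ROI required")


# ---------------------------------------------------------------------------
# per-ROI covariance caching (fast path; identical algebra to the public ops)

def _roi_cov_stack(data: np.ndarray, vertices: np.ndarray | None):
    X = data if vertices is None else data[:, vertices, :]
    Xc = X - X.mean(axis=2, keepdims=True)
    Craw = np.einsum("tcs,tds->tcd", Xc, Xc)
    tr = np.trace(Craw, axis1=1, axis2=2)
    tr = np.where(tr > 0, tr, 1.0)
    return Craw, Craw / tr[:, None, None]


def _class_covs_from_stack(Cnorm: np.ndarray, labels: np.ndarray,
                           idx: np.ndarray) -> ClassCovariances:
    covs, counts = {}, {}
    sub = labels[idx]
    n = Cnorm.shape[1]
    for k in np.unique(sub):
        mask = idx[sub == k]
        mean_cov = Cnorm[mask].mean(axis=0)
        ridge = RIDGE_FRACTION * float(np.mean(np.diag(mean_cov)))
        covs[int(k)] = mean_cov + ridge * np.eye(n)
        counts[int(k)] = int(mask.size)
    return ClassCovariances(covariances=covs, n=n, trial_counts=counts)


def _fit_fold(Cnorm, Craw, labels, train_idx, filters_per_class, shrinkage):
    """Fit CSP + LDA on the training trials only."""
    covs = _class_covs_from_stack(Cnorm, labels, train_idx)
    csp = csp_multiclass_ovr(covs, filters_per_class)
    feats = _features_from_trial_covs(csp.W, Craw[train_idx])
    lda = lda_fit(feats, labels[train_idx], shrinkage=shrinkage)
    return csp, lda


def _cv_fold_accuracies(Cnorm, Craw, labels, folds, repeats, seed,
                        filters_per_class, shrinkage):
    acc = np.empty((repeats, folds))
    fold_seeds = _repeat_seeds(seed, repeats)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(fold_seeds[r]))
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            csp, lda = _fit_fold(Cnorm, Craw, labels, tr,
                                 filters_per_class, shrinkage)
            feats = _features_from_trial_covs(csp.W, Craw[te])
            pred, _ = lda_predict(lda, feats)
            acc[r, f] = float(np.mean(pred == labels[te]))
    return acc


def _repeat_seeds(seed: int, repeats: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(repeats) % (2 ** 31)


def _check_cv_feasible(labels: np.ndarray, folds: int) -> None:
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"every class needs at least {folds} trials for {folds}-fold CV "
            f"(smallest class has {counts.min()})")


# ---------------------------------------------------------------------------
# public operations

def fit_roi_classifier(src: SourceEpochs, roi: ROI | None,
                       filters_per_class: int = 2,
                       shrinkage: float = 0.0) -> ROIClassifier:
    """Fit the CSP + LDA model of one ROI on all supplied trials."""
    vertices = None if roi is None else roi.vertices
    Craw, Cnorm = _roi_cov_stack(src.data, vertices)
    idx = np.arange(src.n_trials)
    csp, lda = _fit_fold(Cnorm, Craw, src.labels, idx,
                         filters_per_class, shrinkage)
    csp.source_kind = "roi" if roi is not None else "sensor"
    csp.roi_name = roi.name if roi is not None else None
    return ROIClassifier(roi_name=csp.roi_name or "<all>", csp=csp, lda=lda,
                         vertices=vertices)


def roi_cv_accuracy(src: SourceEpochs, roi: ROI, folds: int = 10,
                    repeats: int = 10, seed: int = 0,
                    filters_per_class: int = 2,
                    shrinkage: float = 0.0) -> float:
    """Mean repeated stratified-CV accuracy of one ROI's CSP+LDA model."""
    _check_cv_feasible(src.labels, folds)
    Craw, Cnorm = _roi_cov_stack(src.data, roi.vertices)
    acc = _cv_fold_accuracies(Cnorm, Craw, src.labels, folds, repeats, seed,
                              filters_per_class, shrinkage)
    return float(acc.mean())


def rank_rois(src: SourceEpochs, catalog: ROICatalog, folds: int = 10,
              repeats: int = 10, seed: int = 0, filters_per_class: int = 2,
              shrinkage: float = 0.0) -> ROIRanking:
    """Repeated-CV accuracy for every catalogue ROI (identical folds)."""
    _check_cv_feasible(src.labels, folds)
    means, per_fold = {}, {}
    for roi in catalog:
        Craw, Cnorm = _roi_cov_stack(src.data, roi.vertices)
        acc = _cv_fold_accuracies(Cnorm, Craw, src.labels, folds, repeats,
                                  seed, filters_per_class, shrinkage)
        per_fold[roi.name] = acc
        means[roi.name] = float(acc.mean())
    return ROIRanking(names=catalog.names, mean_accuracy=means,
                      fold_accuracies=per_fold, folds=folds, repeats=repeats,
                      seed=seed)


def select_rois(ranking: ROIRanking, Q: int = 8) -> list[str]:
    """Top-Q ROI names by mean accuracy; ties keep catalogue order."""
    if not ranking.names:
        raise ValueError("empty ranking")
    if len(ranking.names) < Q:
        logger.warning("only %d ROIs available for Q=%d; returning all",
                       len(ranking.names), Q)
        Q = len(ranking.names)
    order = sorted(range(len(ranking.names)),
                   key=lambda i: -ranking.mean_accuracy[ranking.names[i]])
    return [ranking.names[i] for i in order[:Q]]


def train_ensemble(src: SourceEpochs, catalog: ROICatalog, Q: int = 8,
                   folds: int = 10, repeats: int = 10, seed: int = 0,
                   filters_per_class: int = 2,
                   shrinkage: float = 0.0) -> EnsembleModel:
    """Rank all ROIs, select the top Q, refit each on all trials."""
    catalog.validate_against(src.n_dipoles)
    ranking = rank_rois(src, catalog, folds, repeats, seed,
                        filters_per_class, shrinkage)
    selected = select_rois(ranking, Q)
    classifiers = {
        name: fit_roi_classifier(src, catalog[name], filters_per_class,
                                 shrinkage)
        for name in selected
    }
    class_order = sorted(int(k) for k in np.unique(src.labels))
    return EnsembleModel(selected_rois=selected, classifiers=classifiers,
                         Q=len(selected), ranking=ranking,
                         class_order=class_order)


def majority_vote(votes, scores=None, class_order=None) -> int:
    """Modal class of the per-ROI votes.

    Ties are broken by the largest sum of LDA scores over the tied
    classes across all voters, then by the smallest class label.
    ``scores`` is an (n_voters, n_classes) array whose columns follow
    ``class_order`` (default: the sorted distinct vote labels); when
    omitted, ties fall straight to the smallest class label.
    """
    votes = list(votes)
    if not votes:
        raise ValueError("no votes to fuse")
    classes, counts = np.unique(votes, return_counts=True)
    tied = sorted(int(c) for c in classes[counts == counts.max()])
    if len(tied) == 1 or scores is None:
        return tied[0]
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if class_order is None:
        class_order = sorted(int(c) for c in classes)
    col_of = {int(c): i for i, c in enumerate(class_order)}
    sums = {c: float(scores[:, col_of[c]].sum()) for c in tied if c in col_of}
    if not sums:
        return tied[0]
    top = max(sums.values())
    return min(c for c, s in sums.items() if s >= top - 1e-12)


def _roi_votes(model: EnsembleModel, src: SourceEpochs):
    """Per-ROI predicted labels and score stacks for every trial."""
    votes = np.empty((len(model.selected_rois), src.n_trials), dtype=int)
    n_classes = len(model.class_order)
    score_stack = np.empty((len(model.selected_rois), src.n_trials, n_classes))
    for i, name in enumerate(model.selected_rois):
        clf = model.classifiers[name]
        Craw, _ = _roi_cov_stack(src.data, clf.vertices)
        feats = _features_from_trial_covs(clf.csp.W, Craw)
        labels, scores = lda_predict(clf.lda, feats)
        votes[i] = labels
        score_stack[i] = scores
    return votes, score_stack


def predict_ensemble(model: EnsembleModel, src: SourceEpochs) -> np.ndarray:
    """Majority-vote prediction for every trial."""
    votes, scores = _roi_votes(model, src)
    out = np.empty(src.n_trials, dtype=int)
    for t in range(src.n_trials):
        out[t] = majority_vote(votes[:, t], scores[:, t, :],
                               class_order=model.class_order)
    return out


def sensor_baseline(epochs: SensorEpochs, folds: int = 10, repeats: int = 10,
                    seed: int = 0, filters_per_class: int = 2,
                    shrinkage: float = 0.0) -> float:
    """Conventional arm: one OVR CSP (+LDA) on the preprocessed channels.

    Same repeated stratified-CV protocol as the ROI ranking, so source
    and sensor accuracies are directly comparable.
    """
    _check_cv_feasible(epochs.labels, folds)
    Craw, Cnorm = _roi_cov_stack(epochs.data, None)
    acc = _cv_fold_accuracies(Cnorm, Craw, epochs.labels, folds, repeats,
                              seed, filters_per_class, shrinkage)
    return float(acc.mean())


_CLASSIFIER_KINDS = ("lda", "knn", "naive_bayes", "decision_tree")


def _make_classifier(kind: str, seed: int = 0):
    if kind == "lda":
        from .lda import ShrinkageLDA
        return ShrinkageLDA()
    if kind == "knn":
        from sklearn.neighbors import KNeighborsClassifier
        return KNeighborsClassifier(n_neighbors=5)
    if kind == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB
        return GaussianNB()
    if kind == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(
        f"unknown classifier kind {kind!r}; choose from {_CLASSIFIER_KINDS}")


def alt_classifier_comparison(features: np.ndarray, labels,
                              classifier_kind: str | None = None,
                              folds: int = 10, repeats: int = 10,
                              seed: int = 0):
    """Repeated-CV accuracy of a pluggable classifier on fixed features.

    With ``classifier_kind=None`` all four candidates (LDA, kNN, naive
    Bayes, decision tree) are evaluated and a kind -> accuracy dict is
    returned; with a single kind, its accuracy alone.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_cv_feasible(y, folds)
    kinds = _CLASSIFIER_KINDS if classifier_kind is None else (classifier_kind,)
    fold_seeds = _repeat_seeds(seed, repeats)
    table = {}
    for kind in kinds:
        accs = []
        for r in range(repeats):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=int(fold_seeds[r]))
            for tr, te in skf.split(X, y):
                clf = _make_classifier(kind, seed)
                clf.fit(X[tr], y[tr])
                accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        table[kind] = float(np.mean(accs))
    return table if classifier_kind is None else table[kinds[0]]


class ROIEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator over source epochs (trials, dipoles, samples).

    Parameters mirror :func:`train_ensemble`; fitted attributes are
    ``ensemble_`` (the :class:`EnsembleModel`), ``ranking_`` and
    ``selected_rois_``.
    """

    def __init__(self, catalog: ROICatalog | None = None, Q: int = 8,
                 folds: int = 10, repeats: int = 10, seed: int = 0,
                 filters_per_class: int = 2, shrinkage: float = 0.0):
        self.catalog = catalog
        self.Q = Q
        self.folds = folds
        self.repeats = repeats
        self.seed = seed
        self.filters_per_class = filters_per_class
        self.shrinkage = shrinkage

    def _as_source(self, X, y=None) -> SourceEpochs:
        if isinstance(X, SourceEpochs):
            return X
        X = np.asarray(X, dtype=float)
        return SourceEpochs(data=X, fs=1.0,
                            labels=np.asarray(y if y is not None
                                              else np.zeros(X.shape[0], int)))

    def fit(self, X, y=None):
        if self.catalog is None:
            raise ValueError("a ROICatalog is required")
        src = self._as_source(X, y)
        self.ensemble_ = train_ensemble(
            src, self.catalog, Q=self.Q, folds=self.folds,
            repeats=self.repeats, seed=self.seed,
            filters_per_class=self.filters_per_class,
            shrinkage=self.shrinkage)
        self.ranking_ = self.ensemble_.ranking
        self.selected_rois_ = list(self.ensemble_.selected_rois)
        self.classes_ = np.asarray(self.ensemble_.class_order)
        return self

    def predict(self, X):
        src = self._as_source(X)
        return predict_ensemble(self.ensemble_, src)
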