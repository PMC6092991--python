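import numpy as np
import pytest

from roicsp import SourceEpochs
from roicsp.ensemble import (ROIEnsembleClassifier, _fit_fold, _roi_cov_stack,
                             alt_classifier_comparison, fit_roi_classifier,
                             majority_vote, predict_ensemble, rank_rois,
                             roi_cv_accuracy, select_rois, sensor_baseline,
                             train_ensemble, ROIRanking)
from roicsp.rois import ROI, ROICatalog


def _planted_roi_session(trials_per_class=50, n=6, samples=120, seed=0):
    """Trials whose class-conditional spatial covariances differ strongly
    inside one 6-channel ROI (each class amplifies its own eigen-direction)."""
    rng = np.random.default_rng(seed)
    basis = np.linalg.qr(rng.standard_normal((n, n)))[0]
    data, labels = [], []
    for k in range(1, 5):
        scales = np.ones(n)
        scales[k - 1] = 6.0
        cov = basis @ np.diag(scales) @ basis.T
        L = np.linalg.cholesky(cov)
        for _ in range(trials_per_class):
            data.append(L @ rng.standard_normal((n, samples)))
            labels.append(k)
    order = rng.permutation(len(labels))
    return SourceEpochs(data=np.stack(data)[order], fs=100.0,
                        labels=np.asarray(labels)[order])


ROI_ALL = ROI(name="ALL", hemisphere="L", vertices=np.arange(6))


class TestMajorityVote:
    def test_unanimous(self):
        assert majority_vote([2, 2, 2]) == 2

    def test_plurality(self):
        assert majority_vote([1, 1, 2, 3, 3, 3, 4, 4]) == 3

    def test_tie_broken_by_summed_scores(self):
        votes = [1, 1, 2, 2]
        scores = np.array([[1.0, 0.5], [1.0, 0.5], [0.5, 1.25], [0.5, 1.25]])
        # summed scores over voters: class 1 -> 3.0, class 2 -> 3.5
        assert majority_vote(votes, scores, class_order=[1, 2]) == 2

    def test_residual_tie_smallest_class(self):
        votes = [3, 3, 1, 1]
        scores = np.tile([[0.5, 0.5]], (4, 1))
        assert majority_vote(votes, scores, class_order=[1, 3]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestSelectROIs:
    def _ranking(self, accs):
        names = [f"R{i:02d}" for i in range(len(accs))]
        return ROIRanking(names=names,
                          mean_accuracy=dict(zip(names, accs)),
                          fold_accuracies={}, folds=10, repeats=10, seed=0)

    def test_top_q_by_accuracy(self):
        rng = np.random.default_rng(0)
        accs = rng.permutation(np.linspace(0.2, 0.9, 24))
        ranking = self._ranking(accs)
        picked = select_rois(ranking, Q=8)
        expect = [ranking.names[i] for i in np.argsort(-accs, kind="stable")[:8]]
        assert picked == expect

    def test_tie_keeps_catalog_order(self):
        ranking = self._ranking([0.5, 0.9, 0.7, 0.7, 0.1])
        assert select_rois(ranking, Q=3) == ["R01", "R02", "R03"]

    def test_fewer_rois_than_q_returns_all(self):
        ranking = self._ranking([0.3, 0.6, 0.4, 0.5, 0.2])
        assert len(select_rois(ranking, Q=8)) == 5


class TestROICVAccuracy:
    def test_separable_planted_structure(self):
        src = _planted_roi_session()
        acc = roi_cv_accuracy(src, ROI_ALL, folds=10, repeats=2, seed=0,
                              filters_per_class=2)
        assert acc >= 0.9

    def test_shuffled_labels_at_chance(self):
        src = _planted_roi_session(seed=1)
        rng = np.random.default_rng(1)
        shuffled = src.copy_with(labels=rng.permutation(src.labels))
        acc = roi_cv_accuracy(shuffled, ROI_ALL, folds=10, repeats=2, seed=0)
        se = np.sqrt(0.25 * 0.75 / src.n_trials)
        assert abs(acc - 0.25) < 3 * se + 1e-9

    def test_deterministic_per_seed(self):
        src = _planted_roi_session(trials_per_class=20, seed=2)
        a = roi_cv_accuracy(src, ROI_ALL, folds=5, repeats=2, seed=42)
        b = roi_cv_accuracy(src, ROI_ALL, folds=5, repeats=2, seed=42)
        assert a == b

    def test_too_few_trials_per_class_rejected(self):
        src = _planted_roi_session(trials_per_class=5, seed=3)
        with pytest.raises(ValueError, match="fold"):
            roi_cv_accuracy(src, ROI_ALL, folds=10)


class TestLeakageGuard:
    def test_held_out_labels_cannot_touch_fitted_parameters(self):
        src = _planted_roi_session(trials_per_class=20, seed=4)
        Craw, Cnorm = _roi_cov_stack(src.data, None)
        idx = np.arange(src.n_trials)
        train, test = idx[:60], idx[60:]
        csp1, lda1 = _fit_fold(Cnorm, Craw, src.labels, train, 2, 0.0)
        perturbed = src.labels.copy()
        perturbed[test] = np.random.default_rng(0).permutation(perturbed[test])
        csp2, lda2 = _fit_fold(Cnorm, Craw, perturbed, train, 2, 0.0)
        assert csp1.W.tobytes() == csp2.W.tobytes()
        assert lda1.coef_.tobytes() == lda2.coef_.tobytes()
        assert lda1.intercept_.tobytes() == lda2.intercept_.tobytes()


class TestEnsemble:
    def test_planted_rois_recovered_and_accurate(self, bench):
        src, cat, truth = bench["src"], bench["catalog"], bench["truth"]
        rng = np.random.default_rng(0)
        idx = rng.permutation(src.n_trials)
        tr, te = idx[:216], idx[216:]
        train = src.copy_with(data=src.data[tr], labels=src.labels[tr])
        test = src.copy_with(data=src.data[te], labels=src.labels[te])
        model = train_ensemble(train, cat, Q=8, folds=10, repeats=2, seed=0,
                               shrinkage=0.05)
        planted = set(truth.active_roi)
        assert planted <= set(model.selected_rois)
        pred = predict_ensemble(model, test)
        assert np.mean(pred == test.labels) >= 0.85

    def test_ensemble_not_much_worse_than_best_voter(self, bench):
        from roicsp.ensemble import _roi_votes
        src, cat = bench["src"], bench["catalog"]
        rng = np.random.default_rng(1)
        idx = rng.permutation(src.n_trials)
        tr, te = idx[:216], idx[216:]
        train = src.copy_with(data=src.data[tr], labels=src.labels[tr])
        test = src.copy_with(data=src.data[te], labels=src.labels[te])
        model = train_ensemble(train, cat, Q=8, folds=10, repeats=2, seed=0,
                               shrinkage=0.05)
        votes, _ = _roi_votes(model, test)
        best = max(np.mean(votes[i] == test.labels)
                   for i in range(votes.shape[0]))
        ens = np.mean(predict_ensemble(model, test) == test.labels)
        assert ens >= best - 0.05

    def test_single_roi_ensemble_reduces_to_roi_classifier(self, bench):
        from roicsp.ensemble import EnsembleModel
        from roicsp.lda import lda_predict
        from roicsp.csp import _features_from_trial_covs
        src, cat = bench["src"], bench["catalog"]
        roi = cat["M1H_L"]
        clf = fit_roi_classifier(src, roi, shrinkage=0.05)
        single = EnsembleModel(selected_rois=[roi.name],
                               classifiers={roi.name: clf}, Q=1,
                               class_order=[1, 2, 3, 4])
        pred_ens = predict_ensemble(single, src)
        Craw, _ = _roi_cov_stack(src.data, roi.vertices)
        feats = _features_from_trial_covs(clf.csp.W, Craw)
        pred_direct, _ = lda_predict(clf.lda, feats)
        np.testing.assert_array_equal(pred_ens, pred_direct)

    def test_prediction_is_stateless_under_permutation(self, bench):
        src, cat = bench["src"], bench["catalog"]
        small = src.copy_with(data=src.data[:40], labels=src.labels[:40])
        model = train_ensemble(small, cat, Q=4, folds=5, repeats=1, seed=0,
                               shrinkage=0.05)
        perm = np.random.default_rng(2).permutation(40)
        pred = predict_ensemble(model, small)
        pred_perm = predict_ensemble(
            model, small.copy_with(data=small.data[perm],
                                   labels=small.labels[perm]))
        np.testing.assert_array_equal(pred[perm], pred_perm)

    def test_q_equals_catalog_size(self, bench):
        src, cat = bench["src"], bench["catalog"]
        small = src.copy_with(data=src.data[:60], labels=src.labels[:60])
        model = train_ensemble(small, cat, Q=24, folds=5, repeats=1, seed=0,
                               shrinkage=0.05)
        assert set(model.selected_rois) == set(cat.names)

    def test_deterministic_for_fixed_seed(self, bench):
        src, cat = bench["src"], bench["catalog"]
        small = src.copy_with(data=src.data[:60], labels=src.labels[:60])
        m1 = train_ensemble(small, cat, Q=4, folds=5, repeats=1, seed=9,
                            shrinkage=0.05)
        m2 = train_ensemble(small, cat, Q=4, folds=5, repeats=1, seed=9,
                            shrinkage=0.05)
        assert m1.selected_rois == m2.selected_rois
        for name in m1.selected_rois:
            assert (m1.classifiers[name].csp.W.tobytes()
                    == m2.classifiers[name].csp.W.tobytes())


class TestSensorBaseline:
    def test_above_chance_on_separable_session(self, bench):
        acc = sensor_baseline(bench["epochs"], folds=5, repeats=1, seed=0,
                              shrinkage=0.05)
        assert acc > 0.5

    def test_chance_on_shuffled_labels(self, bench):
        ep = bench["epochs"]
        rng = np.random.default_rng(3)
        shuffled = ep.copy_with(labels=rng.permutation(ep.labels))
        acc = sensor_baseline(shuffled, folds=5, repeats=2, seed=0,
                              shrinkage=0.05)
        se = np.sqrt(0.25 * 0.75 / ep.n_trials)
        assert abs(acc - 0.25) < 3 * se + 1e-9

    def test_deterministic(self, bench):
        a = sensor_baseline(bench["epochs"], folds=5, repeats=1, seed=5,
                            shrinkage=0.05)
        b = sensor_baseline(bench["epochs"], folds=5, repeats=1, seed=5,
                            shrinkage=0.05)
        assert a == b


class TestAltClassifiers:
    def _features(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(3 * k, 0.3, (30, 4))
                            for k in range(4)])
        return X, np.repeat([1, 2, 3, 4], 30)

    def test_all_kinds_on_separable_features(self):
        X, y = self._features()
        table = alt_classifier_comparison(X, y, folds=5, repeats=1, seed=0)
        assert set(table) == {"lda", "knn", "naive_bayes", "decision_tree"}
        for kind, acc in table.items():
            assert 0.95 <= acc <= 1.0, kind

    def test_single_kind_returns_scalar(self):
        X, y = self._features()
        acc = alt_classifier_comparison(X, y, "knn", folds=5, repeats=1,
                                        seed=0)
        assert isinstance(acc, float)

    def test_unknown_kind_rejected(self):
        X, y = self._features()
        with pytest.raises(ValueError, match="unknown"):
            alt_classifier_comparison(X, y, "svm", folds=5, repeats=1, seed=0)

    def test_nearest_neighbor_memorizes_training_set(self):
        from sklearn.neighbors import KNeighborsClassifier
        X, y = self._features()
        clf = KNeighborsClassifier(n_neighbors=1).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0


def test_sklearn_estimator_interface(bench):
    src, cat = bench["src"], bench["catalog"]
    est = ROIEnsembleClassifier(catalog=cat, Q=4, folds=5, repeats=1, seed=0,
                                shrinkage=0.05)
    est.fit(src.data[:80], src.labels[:80])
    assert len(est.selected_rois_) == 4
    pred = est.predict(src.data[80:120])
    assert pred.shape == (40,)
    assert set(pred) <= {1, 2, 3, 4}
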