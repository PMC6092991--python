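"""End-to-end experiment orchestration.

Ties the stages together: (optional) preprocessing, inverse mapping,
outer cross-validation with a full ensemble fit inside every training
fold (ROI ranking included, so the selection never sees held-out
trials), the sensor-space comparison arm on identical folds, and the
paired difference table.

A single global seed expands into per-stage seeds through a fixed
``numpy.random.SeedSequence`` spawning scheme, so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import ContinuousEEG, SensorEpochs, SourceEpochs
from .csp import _features_from_trial_covs
from .ensemble import (_fit_fold, _repeat_seeds, _roi_cov_stack,
                       predict_ensemble, train_ensemble)
from .headmodel import LeadField, estimate_noise_covariance
from .inverse import InverseConfig, apply_inverse, build_inverse_operator
from .lda import lda_predict
from .metrics import EvaluationReport, compare_methods, confusion
from .rois import ROICatalog

__all__ = ["RunConfig", "stage_seeds", "run_source_experiment",
           "run_sensor_experiment", "run_comparison", "invert_epochs"]


@dataclass
class RunConfig:
    """Every stage's tunable parameters in one validated bundle."""

    band_low: float = 7.0
    band_high: float = 15.0
    fs_out: float = 100.0
    offset_s: float = 0.5
    duration_s: float = 3.0
    lambda2: float = 1.0 / 9.0
    depth_exponent: float = 0.5
    loading_fraction: float = 0.05
    Q: int = 8
    outer_folds: int = 10
    outer_repeats: int = 1
    rank_folds: int = 10
    rank_repeats: int = 10
    filters_per_class: int = 2
    shrinkage: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if min(self.Q, self.outer_folds, self.rank_folds) < 2:
            raise ValueError("Q and fold counts must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


_STAGES = ("simulate", "preprocess", "inverse", "outer_cv", "ranking")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2**31) from one global seed."""
    children = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s % (2 ** 31)) for name, s in zip(_STAGES, children)}


def invert_epochs(epochs: SensorEpochs, baseline: ContinuousEEG | SensorEpochs,
                  lf: LeadField, cfg: RunConfig | None = None) -> SourceEpochs:
    """Noise covariance from the resting baseline -> wMNE -> source epochs."""
    cfg = cfg or RunConfig()
    cov = estimate_noise_covariance(baseline, cfg.loading_fraction)
    inv = build_inverse_operator(
        lf, cov, InverseConfig(lambda2=cfg.lambda2,
                               depth_exponent=cfg.depth_exponent))
    return apply_inverse(inv, epochs)


def _outer_splits(labels: np.ndarray, folds: int, repeats: int, seed: int):
    """Identical fold sequence for both arms of a paired comparison."""
    seeds = _repeat_seeds(seed, repeats)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(seeds[r]))
        yield from skf.split(np.zeros(len(labels)), labels)


def run_source_experiment(src: SourceEpochs, catalog: ROICatalog,
                          cfg: RunConfig | None = None):
    """Outer CV with a per-fold ensemble fit (ranking, selection, refit).

    Returns ``(report, selection_counts)``: the pooled
    :class:`EvaluationReport` over all held-out folds and a ROI ->
    selection-count Series (the selection histogram).
    """
    cfg = cfg or RunConfig()
    seeds = stage_seeds(cfg.seed)
    y_true, y_pred = [], []
    counts = {name: 0 for name in catalog.names}
    for i, (tr, te) in enumerate(_outer_splits(src.labels, cfg.outer_folds,
                                               cfg.outer_repeats,
                                               seeds["outer_cv"])):
        train = src.copy_with(data=src.data[tr], labels=src.labels[tr])
        model = train_ensemble(train, catalog, Q=cfg.Q, folds=cfg.rank_folds,
                               repeats=cfg.rank_repeats,
                               seed=seeds["ranking"] + i,
                               filters_per_class=cfg.filters_per_class,
                               shrinkage=cfg.shrinkage)
        test = src.copy_with(data=src.data[te], labels=src.labels[te])
        pred = predict_ensemble(model, test)
        y_true.extend(src.labels[te].tolist())
        y_pred.extend(pred.tolist())
        for name in model.selected_rois:
            counts[name] += 1
    report = EvaluationReport(confusion(y_true, y_pred))
    return report, pd.Series(counts, name="selection_count")


def run_sensor_experiment(epochs: SensorEpochs,
                          cfg: RunConfig | None = None) -> EvaluationReport:
    """Sensor-space arm: one OVR CSP + LDA per fold, identical folds."""
    cfg = cfg or RunConfig()
    seeds = stage_seeds(cfg.seed)
    Craw, Cnorm = _roi_cov_stack(epochs.data, None)
    y_true, y_pred = [], []
    for tr, te in _outer_splits(epochs.labels, cfg.outer_folds,
                                cfg.outer_repeats, seeds["outer_cv"]):
        csp, lda = _fit_fold(Cnorm, Craw, epochs.labels, tr,
                             cfg.filters_per_class, cfg.shrinkage)
        feats = _features_from_trial_covs(csp.W, Craw[te])
        pred, _ = lda_predict(lda, feats)
        y_true.extend(epochs.labels[te].tolist())
        y_pred.extend(pred.tolist())
    return EvaluationReport(confusion(y_true, y_pred))


def _report_row(report: EvaluationReport, label: str) -> pd.DataFrame:
    row = {"accuracy_pct": 100.0 * report.accuracy, "kappa": report.kappa}
    for c in report.confusion_matrix.class_order:
        row[f"sensitivity_{c}_pct"] = 100.0 * report.sensitivity[c]
        row[f"specificity_{c}_pct"] = 100.0 * report.specificity[c]
    return pd.DataFrame([row], index=[label])


def run_comparison(report_source: EvaluationReport,
                   report_sensor: EvaluationReport,
                   decimals: int | None = 1) -> pd.DataFrame:
    """Source-minus-sensor difference table for one paired evaluation."""
    a = _report_row(report_sensor, "run")
    b = _report_row(report_source, "run")
    return compare_methods(a, b, decimals=decimals)
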