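"""Canned desk-scale experiments on the synthetic benchmark.

These wrap the full pipeline at the study conditions used for validation:
4 classes x 72 trials in the 24-ROI template toy world, 80% band-power
suppression in the class-specific region, high sensor SNR.  Problem
sizes (fold counts, ranking repeats) are chosen so each experiment runs
in seconds to minutes on one core.
"""

from __future__ import annotations

import numpy as np

from .ensemble import rank_rois, select_rois, sensor_baseline
from .metrics import EvaluationReport
from .pipeline import RunConfig, invert_epochs, run_source_experiment
from .synth import make_benchmark_session

__all__ = ["benchmark_cv_report", "planted_roi_recovery",
           "shuffled_label_accuracy", "benchmark_sensor_accuracy"]

_BENCH_CFG = dict(outer_folds=10, outer_repeats=1, rank_folds=10,
                  rank_repeats=3, shrinkage=0.05)


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def benchmark_cv_report(seed: int = 0):
    """10-fold CV of the source ensemble on one benchmark session.

    The ensemble (ROI ranking, top-8 selection, per-ROI CSP+LDA refit)
    is fit inside every training fold.  Returns ``(report, histogram)``.
    """
    sim_seed, cv_seed = _seeds(seed, 2)
    lf, catalog, epochs, baseline, _ = make_benchmark_session(int(sim_seed))
    src = invert_epochs(epochs, baseline, lf)
    cfg = RunConfig(seed=int(cv_seed), **_BENCH_CFG)
    return run_source_experiment(src, catalog, cfg)


def benchmark_sensor_accuracy(seed: int = 0) -> float:
    """Sensor-space OVR-CSP + LDA baseline on the same session/protocol."""
    sim_seed, cv_seed = _seeds(seed, 2)
    _, _, epochs, _, _ = make_benchmark_session(int(sim_seed))
    return sensor_baseline(epochs, folds=10, repeats=1, seed=int(cv_seed),
                           shrinkage=0.05)


def planted_roi_recovery(seed: int = 0, n_replicates: int = 20,
                         Q: int = 8) -> float:
    """Fraction of replicate sessions whose 4 planted regions all appear
    in the top-Q ROI ranking."""
    hits = 0
    for rep_seed in _seeds(seed, n_replicates):
        lf, catalog, epochs, baseline, truth = make_benchmark_session(
            int(rep_seed))
        src = invert_epochs(epochs, baseline, lf)
        ranking = rank_rois(src, catalog, folds=10, repeats=3,
                            seed=int(rep_seed), shrinkage=0.05)
        selected = select_rois(ranking, Q=Q)
        hits += set(truth.active_roi) <= set(selected)
    return hits / n_replicates


def shuffled_label_accuracy(seed: int = 0) -> EvaluationReport:
    """Chance-level control: the same CV on label-shuffled data."""
    sim_seed, cv_seed, perm_seed = _seeds(seed, 3)
    lf, catalog, epochs, baseline, _ = make_benchmark_session(int(sim_seed))
    src = invert_epochs(epochs, baseline, lf)
    rng = np.random.default_rng(int(perm_seed))
    shuffled = src.copy_with(labels=rng.permutation(src.labels))
    cfg = RunConfig(seed=int(cv_seed), **_BENCH_CFG)
    report, _ = run_source_experiment(shuffled, catalog, cfg)
    return report
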