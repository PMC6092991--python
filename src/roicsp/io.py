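"""HDF5 (and NPZ fallback) persistence for the pipeline's artifacts.

Layouts
-------
continuous : datasets ``data`` (channels x samples), ``fs``,
    ``channel_names``, ``event_samples``, ``event_labels``
epochs : ``data`` (trials x channels x samples), ``labels``, ``fs``,
    ``t0``, ``channel_names``
source epochs : ``data`` (trials x dipoles x samples), ``labels``,
    ``fs``, ``t0``
leadfield : ``G``, ``channel_names``, optional ``positions`` /
    ``orientations``; a whitespace-delimited text matrix with a sidecar
    ``<file>.channels`` list is also accepted by :func:`load_leadfield`
ensemble : per-ROI groups with the CSP projection and LDA parameters
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .containers import ContinuousEEG, SensorEpochs, SourceEpochs
from .csp import CSPModel
from .ensemble import EnsembleModel, ROIClassifier
from .headmodel import LeadField
from .lda import LDAModel

__all__ = [
    "save_epochs", "load_epochs", "save_source_epochs", "load_source_epochs",
    "save_continuous", "load_continuous", "save_leadfield", "load_leadfield",
    "save_ensemble", "load_ensemble", "read_raw_eeg",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_names(g, key, names):
    g.create_dataset(key, data=np.asarray(names, dtype=object), dtype=_STR)


def _read_names(g, key):
    return [s.decode() if isinstance(s, bytes) else str(s) for s in g[key][()]]


# ---------------------------------------------------------------- epochs

def save_epochs(epochs: SensorEpochs, path) -> None:
    path = os.fspath(path)
    if path.endswith(".npz"):
        np.savez_compressed(path, data=epochs.data, labels=epochs.labels,
                            fs=epochs.fs, t0=epochs.t0,
                            channel_names=np.asarray(epochs.channel_names))
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.attrs["fs"] = epochs.fs
        f.attrs["t0"] = epochs.t0
        _write_names(f, "channel_names", epochs.channel_names)


def load_epochs(path) -> SensorEpochs:
    path = os.fspath(path)
    if path.endswith(".npz"):
        z = np.load(path, allow_pickle=False)
        return SensorEpochs(data=z["data"], labels=z["labels"],
                            fs=float(z["fs"]), t0=float(z["t0"]),
                            channel_names=[str(s) for s in z["channel_names"]])
    with h5py.File(path, "r") as f:
        return SensorEpochs(data=f["data"][()], labels=f["labels"][()],
                            fs=float(f.attrs["fs"]), t0=float(f.attrs["t0"]),
                            channel_names=_read_names(f, "channel_names"))


def save_source_epochs(src: SourceEpochs, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=src.data)
        f.create_dataset("labels", data=src.labels)
        f.attrs["fs"] = src.fs
        f.attrs["t0"] = src.t0


def load_source_epochs(path) -> SourceEpochs:
    with h5py.File(path, "r") as f:
        return SourceEpochs(data=f["data"][()], labels=f["labels"][()],
                            fs=float(f.attrs["fs"]), t0=float(f.attrs["t0"]))


# ------------------------------------------------------------ continuous

def save_continuous(x: ContinuousEEG, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=x.data)
        f.attrs["fs"] = x.fs
        _write_names(f, "channel_names", x.channel_names)
        ev = np.asarray(x.events, dtype=int).reshape(-1, 2)
        f.create_dataset("event_samples", data=ev[:, 0])
        f.create_dataset("event_labels", data=ev[:, 1])


def load_continuous(path) -> ContinuousEEG:
    with h5py.File(path, "r") as f:
        events = list(zip(f["event_samples"][()].tolist(),
                          f["event_labels"][()].tolist()))
        return ContinuousEEG(data=f["data"][()], fs=float(f.attrs["fs"]),
                             channel_names=_read_names(f, "channel_names"),
                             events=events)


# ------------------------------------------------------------- leadfield

def save_leadfield(lf: LeadField, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("G", data=lf.G)
        _write_names(f, "channel_names", lf.channel_names)
        if lf.source_positions is not None:
            f.create_dataset("positions", data=lf.source_positions)
        if lf.source_orientations is not None:
            f.create_dataset("orientations", data=lf.source_orientations)


def load_leadfield(path, expected_channels: list[str] | None = None) -> LeadField:
    """Load and validate a gain matrix; optionally align channel order.

    When ``expected_channels`` is given, the stored rows are reordered
    by name to that order; missing or surplus names raise, listing the
    offenders.
    """
    path = os.fspath(path)
    if path.endswith((".txt", ".tsv", ".dat")):
        G = np.loadtxt(path)
        sidecar = path + ".channels"
        names = None
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                names = [ln.strip() for ln in fh if ln.strip()]
        lf = LeadField(G=G, channel_names=names or [])
    else:
        with h5py.File(path, "r") as f:
            lf = LeadField(
                G=f["G"][()],
                channel_names=_read_names(f, "channel_names"),
                source_positions=f["positions"][()] if "positions" in f else None,
                source_orientations=(f["orientations"][()]
                                     if "orientations" in f else None))
    if expected_channels is not None:
        missing = [c for c in expected_channels if c not in lf.channel_names]
        surplus = [c for c in lf.channel_names if c not in expected_channels]
        if missing or surplus:
            raise ValueError(
                f"channel mismatch: missing {missing}, unexpected {surplus}")
        order = [lf.channel_names.index(c) for c in expected_channels]
        lf = LeadField(G=lf.G[order], channel_names=list(expected_channels),
                       source_positions=lf.source_positions,
                       source_orientations=lf.source_orientations)
    return lf


# --------------------------------------------------------------- ensemble

def save_ensemble(model: EnsembleModel, path, seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        _write_names(f, "selected_rois", model.selected_rois)
        f.attrs["Q"] = model.Q
        f.attrs["tie_break"] = model.tie_break
        f.attrs["class_order"] = np.asarray(model.class_order, dtype=int)
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if model.ranking is not None:
            rk = f.create_group("ranking")
            _write_names(rk, "names", model.ranking.names)
            rk.create_dataset("mean_accuracy", data=np.asarray(
                [model.ranking.mean_accuracy[n] for n in model.ranking.names]))
            rk.attrs["folds"] = model.ranking.folds
            rk.attrs["repeats"] = model.ranking.repeats
            rk.attrs["seed"] = model.ranking.seed
        grp = f.create_group("classifiers")
        for name, clf in model.classifiers.items():
            g = grp.create_group(name)
            g.create_dataset("W", data=clf.csp.W)
            g.attrs["class_order"] = np.asarray(clf.csp.class_order, dtype=int)
            if clf.vertices is not None:
                g.create_dataset("vertices", data=clf.vertices)
            g.create_dataset("lda_coef", data=clf.lda.coef_)
            g.create_dataset("lda_intercept", data=clf.lda.intercept_)
            g.create_dataset("pooled_covariance",
                             data=clf.lda.pooled_covariance)
            classes = clf.lda.classes
            g.attrs["lda_classes"] = np.asarray(classes, dtype=int)
            g.create_dataset("class_means", data=np.stack(
                [clf.lda.class_means[c] for c in classes]))
            g.create_dataset("priors", data=np.asarray(
                [clf.lda.priors[c] for c in classes]))
            g.attrs["shrinkage"] = clf.lda.shrinkage


def load_ensemble(path) -> EnsembleModel:
    with h5py.File(path, "r") as f:
        selected = _read_names(f, "selected_rois")
        classifiers = {}
        for name in selected:
            g = f["classifiers"][name]
            classes = [int(c) for c in g.attrs["lda_classes"]]
            means = g["class_means"][()]
            lda = LDAModel(
                class_means={c: means[i] for i, c in enumerate(classes)},
                pooled_covariance=g["pooled_covariance"][()],
                priors={c: float(p) for c, p in zip(classes, g["priors"][()])},
                shrinkage=float(g.attrs["shrinkage"]),
                coef_=g["lda_coef"][()], intercept_=g["lda_intercept"][()])
            csp = CSPModel(W=g["W"][()],
                           class_order=[int(c) for c in g.attrs["class_order"]],
                           source_kind="roi", roi_name=name)
            vertices = g["vertices"][()] if "vertices" in g else None
            classifiers[name] = ROIClassifier(roi_name=name, csp=csp, lda=lda,
                                              vertices=vertices)
        return EnsembleModel(
            selected_rois=selected, classifiers=classifiers,
            Q=int(f.attrs["Q"]), tie_break=str(f.attrs["tie_break"]),
            class_order=[int(c) for c in f.attrs["class_order"]])


# ------------------------------------------------- optional GDF/EDF input

def read_raw_eeg(path, event_map: dict[int, int],
                 picks: list[str] | None = None) -> ContinuousEEG:
    """Read a GDF/EDF recording into a :class:`ContinuousEEG`.

    Requires the optional ``mne`` dependency.  ``event_map`` translates
    annotation/event codes to class labels 1..4; unmapped events are
    dropped.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading GDF/EDF requires the 'mne' extra") from exc
    path = os.fspath(path)
    reader = (mne.io.read_raw_gdf if path.lower().endswith(".gdf")
              else mne.io.read_raw_edf)
    raw = reader(path, preload=True, verbose="error")
    if picks:
        raw.pick(picks)
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    inv = {v: k for k, v in event_id.items()}
    out_events = []
    for sample, _, code in events:
        key = inv.get(code)
        try:
            key_int = int(key)
        except (TypeError, ValueError):
            continue
        if key_int in event_map:
            out_events.append((int(sample), int(event_map[key_int])))
    return ContinuousEEG(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                         channel_names=list(raw.ch_names), events=out_events)
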