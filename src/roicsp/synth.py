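"""Synthetic multiclass motor-imagery sessions with known ground truth.

Every cortical dipole carries a band-limited 8-13 Hz oscillation (white
noise band-pass filtered, random phase per trial) on top of a 1/f-shaped
background.  In a trial of class k, the dipoles of the class's active
ROI have their oscillatory amplitude scaled by (1 + erd_depth): a
negative depth emulates event-related desynchronization (ERD), the
power drop that real motor imagery produces over the contralateral
sensorimotor cortex.  Sources are projected to the sensors through the
lead field (M = G D) and white sensor noise is added at a configurable
power SNR.  A separate resting baseline with no class modulation is
emitted for noise-covariance estimation.

What this emulates: class-dependent band-power modulation in known
regions, volume conduction mixing, additive sensor noise.  What it does
not: time-resolved ERD envelopes, non-stationarity, artifacts, realistic
electrode montages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import ContinuousEEG, SensorEpochs
from .headmodel import LeadField, surrogate_leadfield
from .rois import AREA_NAMES, ROI, ROICatalog

__all__ = ["SimulationConfig", "GroundTruth", "simulate_session",
           "make_toy_world", "make_benchmark_session",
           "DEFAULT_ACTIVE_ROIS", "BENCHMARK_WORLD_SEED"]

# the surrogate 'template anatomy' used by the decoding benchmark; fixed
# just as a template head model is shared across subjects in practice
BENCHMARK_WORLD_SEED = 1

# one distinct sensorimotor region per motor-imagery class, drawn from
# the nodes that decoding studies most consistently find informative
# (supplementary motor area, primary hand motor and somatosensory
# cortex, cingulate motor area)
DEFAULT_ACTIVE_ROIS = {1: "SMA_L", 2: "M1H_L", 3: "S1H_L", 4: "CMA_R"}


@dataclass(frozen=True)
class SimulationConfig:
    """Session-level simulation parameters.

    ``erd_depth`` is the fractional oscillatory amplitude change in the
    active ROI (-0.5 halves the amplitude there); ``sensor_snr`` is the
    per-channel signal-to-noise power ratio.
    """

    n_classes: int = 4
    trials_per_class: int = 72
    fs: float = 100.0
    epoch_duration: float = 3.0
    active_roi_per_class: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVE_ROIS))
    erd_depth: float = -0.5
    oscillation_band: tuple[float, float] = (8.0, 13.0)
    background_amplitude: float = 0.3
    sensor_snr: float = 5.0
    baseline_duration: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if self.sensor_snr <= 0:
            raise ValueError("sensor_snr must be positive")
        rois = list(self.active_roi_per_class.values())
        if len(set(rois)) != len(rois):
            raise ValueError("active ROIs must be distinct per class")


@dataclass
class GroundTruth:
    """What was planted: per-trial active ROI and source amplitudes."""

    active_roi: list[str]
    dipole_gain: np.ndarray  # (trials, dipoles) oscillation amplitude scale
    source_data: np.ndarray  # (trials, dipoles, samples) noise-free D
    seed: int


def _bandlimited_noise(rng: np.random.Generator, shape: tuple, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """White noise band-passed to ``band`` (zero-phase), unit variance."""
    pad = int(fs)  # one-second edge pad absorbs filter transients
    raw = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, raw, axis=-1)[..., pad:-pad]
    sd = out.std(axis=-1, keepdims=True)
    return out / np.where(sd > 0, sd, 1.0)


def _pink_noise(rng: np.random.Generator, shape: tuple, fs: float,
                exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent amplitude-shaped background noise, unit variance."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    spec = (rng.standard_normal(shape[:-1] + (freqs.size,))
            + 1j * rng.standard_normal(shape[:-1] + (freqs.size,))) * scale
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    return out / np.where(sd > 0, sd, 1.0)


def _patch_oscillations(rng, catalog, n_dip, lead_shape, fs, band):
    """Per-ROI coherent oscillations broadcast to each ROI's dipoles.

    Neighbouring pyramidal populations fire synchronously — that is what
    makes their fields sum into a measurable EEG signal — so dipoles of
    one patch share a single band-limited waveform (random phase per
    trial) while distinct patches stay mutually incoherent.  Dipoles not
    covered by any ROI get independent oscillations.
    """
    out = np.zeros(lead_shape[:-1] + (n_dip,) + lead_shape[-1:])
    covered = np.zeros(n_dip, dtype=bool)
    for roi in catalog:
        wave = _bandlimited_noise(rng, lead_shape, fs, band)
        out[..., roi.vertices, :] = wave[..., None, :]
        covered[roi.vertices] = True
    free = np.flatnonzero(~covered)
    if free.size:
        out[..., free, :] = np.moveaxis(
            _bandlimited_noise(rng, (free.size,) + lead_shape, fs, band),
            0, -2)
    return out


def _project_with_noise(rng, G, D, snr):
    """M = G D + per-channel white noise at the requested power SNR."""
    M = np.einsum("cd,...ds->...cs", G, D)
    sig_power = np.mean(M ** 2, axis=-1, keepdims=True)
    noise_sd = np.sqrt(sig_power / snr)
    return M + noise_sd * rng.standard_normal(M.shape)


def simulate_session(cfg: SimulationConfig, lf: LeadField,
                     catalog: ROICatalog):
    """Generate one labelled session plus resting baseline and ground truth.

    Returns ``(epochs, baseline, truth)``; fully deterministic for a
    fixed ``cfg.seed``.
    """
    for k, name in cfg.active_roi_per_class.items():
        if name not in catalog.names:
            raise ValueError(f"class {k}: unknown ROI {name!r}")
    catalog.validate_against(lf.n_dipoles)
    rng = np.random.default_rng(cfg.seed)
    n_trials = cfg.n_classes * cfg.trials_per_class
    n_samp = int(round(cfg.epoch_duration * cfg.fs))
    n_dip = lf.n_dipoles

    labels = np.repeat(np.arange(1, cfg.n_classes + 1), cfg.trials_per_class)
    rng.shuffle(labels)

    gain = np.ones((n_trials, n_dip))
    active = []
    for t, lab in enumerate(labels):
        roi = catalog[cfg.active_roi_per_class[int(lab)]]
        gain[t, roi.vertices] = 1.0 + cfg.erd_depth
        active.append(roi.name)

    osc = _patch_oscillations(rng, catalog, n_dip, (n_trials, n_samp),
                              cfg.fs, cfg.oscillation_band)
    bg = _pink_noise(rng, (n_trials, n_dip, n_samp), cfg.fs)
    D = gain[:, :, None] * osc + cfg.background_amplitude * bg
    M = _project_with_noise(rng, lf.G, D, cfg.sensor_snr)
    epochs = SensorEpochs(data=M, fs=cfg.fs, labels=labels, t0=0.5,
                          channel_names=list(lf.channel_names))

    n_base = int(round(cfg.baseline_duration * cfg.fs))
    osc_b = _patch_oscillations(rng, catalog, n_dip, (n_base,), cfg.fs,
                                cfg.oscillation_band)
    bg_b = _pink_noise(rng, (n_dip, n_base), cfg.fs)
    D_b = osc_b + cfg.background_amplitude * bg_b
    M_b = _project_with_noise(rng, lf.G, D_b, cfg.sensor_snr)
    baseline = ContinuousEEG(data=M_b, fs=cfg.fs,
                             channel_names=list(lf.channel_names))

    truth = GroundTruth(active_roi=active, dipole_gain=gain, source_data=D,
                        seed=cfg.seed)
    return epochs, baseline, truth


def _patch_positions(rng, n_rois, per_roi, radius=0.8, spread=0.08):
    """ROI centres quasi-uniform on a sphere; dipoles cluster around them.

    Spatial compactness matters: an inverse solution smears activity to
    spatially neighbouring dipoles, so a region must be a patch — not an
    arbitrary index set — for its time series to stay coherent.
    """
    i = np.arange(n_rois) + 0.5
    phi = np.arccos(1 - 2 * i / n_rois)
    theta = np.pi * (1 + 5 ** 0.5) * i
    centers = np.stack([np.cos(theta) * np.sin(phi),
                        np.sin(theta) * np.sin(phi),
                        np.cos(phi)], axis=1)
    positions = []
    for c in centers:
        for _ in range(per_roi):
            p = c + spread * rng.standard_normal(3)
            positions.append(p / np.linalg.norm(p))
    return radius * np.asarray(positions)


def make_benchmark_session(seed: int, trials_per_class: int = 72,
                           erd_depth: float = -0.8,
                           sensor_snr: float = 100.0):
    """One separable decoding session in the fixed template toy world.

    The benchmark world has 24 patch ROIs of 5 dipoles each (120 dipoles,
    16 channels) on the fixed template geometry, so every region can
    supply the full 8-filter one-vs-rest CSP.  Strong band-power
    modulation (default 80% suppression) at high sensor SNR makes the
    session separable end to end, which is what parameter-recovery
    experiments need: failures then indicate pipeline defects, not an
    unlearnable task.

    Returns ``(leadfield, catalog, epochs, baseline, truth)``.
    """
    lf, catalog = make_toy_world(n_channels=16, n_dipoles=120, n_rois=24,
                                 seed=BENCHMARK_WORLD_SEED)
    cfg = SimulationConfig(trials_per_class=trials_per_class,
                           erd_depth=erd_depth, sensor_snr=sensor_snr,
                           seed=seed)
    epochs, baseline, truth = simulate_session(cfg, lf, catalog)
    return lf, catalog, epochs, baseline, truth


def make_toy_world(n_channels: int = 16, n_dipoles: int = 48,
                   n_rois: int = 24, seed: int = 0):
    """Surrogate lead field plus a catalogue of disjoint patch ROIs.

    Dipoles are grouped into ``n_rois`` spatially compact patches of
    ``n_dipoles // n_rois`` dipoles each (the remainder is dropped so the
    partition stays even); names cycle over the 12 sensorimotor areas
    x {L, R}.
    """
    if n_rois > n_dipoles:
        raise ValueError("more ROIs than dipoles")
    per_roi = n_dipoles // n_rois
    n_used = per_roi * n_rois
    rng = np.random.default_rng(seed)
    positions = _patch_positions(rng, n_rois, per_roi)
    lf = surrogate_leadfield(n_channels=n_channels,
                             source_positions=positions, seed=seed)
    names = [f"{AREA_NAMES[i % len(AREA_NAMES)]}_"
             f"{'L' if (i // len(AREA_NAMES)) % 2 == 0 else 'R'}"
             for i in range(n_rois)]
    if len(set(names)) != len(names):  # more than 24 ROIs: suffix the reruns
        names = [f"{n}{i // 24}" if i >= 24 else n
                 for i, n in enumerate(names)]
    rois = [ROI(name=name, hemisphere=name.split("_")[1][0],
                vertices=np.arange(i * per_roi, (i + 1) * per_roi))
            for i, name in enumerate(names)]
    assert n_used == sum(r.size for r in rois)
    return lf, ROICatalog(rois=rois)
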