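"""Forward-model plumbing: lead fields and sensor noise covariance.

The inverse solver only needs a gain matrix ``G`` (sensors x dipoles) and
a noise covariance ``C``.  ``G`` normally comes from a boundary-element
forward solution on an anatomical template; here it can be loaded from
HDF5 / plain text, or generated by :func:`surrogate_leadfield`, a
dipole-like analytic falloff model that is *not* a physical BEM but
preserves the structure the decoding pipeline relies on (linearity,
distance falloff, fixed perpendicular orientations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ContinuousEEG, SensorEpochs

__all__ = [
    "ConductivityProfile",
    "LeadField",
    "NoiseCovariance",
    "surrogate_leadfield",
    "estimate_noise_covariance",
]


@dataclass(frozen=True)
class ConductivityProfile:
    """Scalp/skull/brain conductivities in S/m.

    Defaults follow the common three-compartment convention of
    0.33 / 0.0042 / 0.33 S/m (relative 1 : 1/15 : 1 after dividing the
    skull ratio by the usual scaling).
    """

    sigma_scalp: float = 0.33
    sigma_skull: float = 0.0042
    sigma_brain: float = 0.33

    def __post_init__(self):
        if min(self.sigma_scalp, self.sigma_skull, self.sigma_brain) <= 0:
            raise ValueError("conductivities must be positive")


@dataclass
class LeadField:
    """Gain matrix ``G`` (n_channels x n_dipoles) with source metadata."""

    G: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    source_positions: np.ndarray | None = None
    source_orientations: np.ndarray | None = None

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("lead field must be 2-D (channels x dipoles)")
        if self.G.shape[0] < 2:
            raise ValueError("lead field needs at least 2 channels")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("lead field contains non-finite entries")
        dead = np.flatnonzero(~np.any(self.G != 0.0, axis=0))
        if dead.size:
            raise ValueError(
                f"dipoles {dead.tolist()[:10]} are invisible to every sensor "
                "(all-zero lead-field columns)")
        if not self.channel_names:
            self.channel_names = [f"EEG{i:03d}" for i in range(self.G.shape[0])]
        if len(self.channel_names) != self.G.shape[0]:
            raise ValueError("channel_names length does not match G")

    @property
    def n_channels(self) -> int:
        return self.G.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.G.shape[1]


@dataclass
class NoiseCovariance:
    """Regularized sensor noise covariance (n_channels x n_channels)."""

    C: np.ndarray
    n_samples_used: int = 0

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("noise covariance must be square")
        if not np.allclose(self.C, self.C.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.C.shape[0]


def surrogate_leadfield(n_channels: int | None = None,
                        source_positions: np.ndarray | None = None,
                        source_orientations: np.ndarray | None = None,
                        sensor_positions: np.ndarray | None = None,
                        conductivity: ConductivityProfile | None = None,
                        seed: int = 0,
                        n_dipoles: int = 48) -> LeadField:
    """Analytic surrogate gain matrix with dipole-like 1/r^2 falloff.

    gain[c, d] = k(sigma) * (o_d . u_cd) / ||r_c - r_d||^2

    with ``u_cd`` the unit vector from dipole ``d`` to sensor ``c`` and
    ``k`` a conductivity-dependent global scale.  Geometry defaults to
    dipoles on a unit sphere of radius 0.8 (cortex) with outward
    orientations, sensors on radius 1.0 (scalp), both quasi-uniform and
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    conductivity = conductivity or ConductivityProfile()

    def _fibonacci_sphere(n, radius, jitter=0.0):
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5 ** 0.5) * i
        pts = np.stack([np.cos(theta) * np.sin(phi),
                        np.sin(theta) * np.sin(phi),
                        np.cos(phi)], axis=1)
        if jitter:
            pts = pts + jitter * rng.standard_normal(pts.shape)
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        return radius * pts

    if sensor_positions is None:
        if n_channels is None:
            raise ValueError("need n_channels or explicit sensor_positions")
        sensor_positions = _fibonacci_sphere(n_channels, 1.0)
    sensor_positions = np.asarray(sensor_positions, dtype=float)
    if source_positions is None:
        source_positions = _fibonacci_sphere(n_dipoles, 0.8, jitter=0.02)
    source_positions = np.asarray(source_positions, dtype=float)
    if source_orientations is None:
        # perpendicular to the (spherical) surface = radially outward
        source_orientations = source_positions / np.linalg.norm(
            source_positions, axis=1, keepdims=True)
    source_orientations = np.asarray(source_orientations, dtype=float)

    if not (np.all(np.isfinite(sensor_positions))
            and np.all(np.isfinite(source_positions))):
        raise ValueError("positions must be finite")
    diff = sensor_positions[:, None, :] - source_positions[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist < 1e-9):
        raise ValueError("coincident sensor and source positions")
    u = diff / dist[..., None]
    # conductivity enters only as a global scale in the surrogate
    k = 1.0 / (4 * np.pi * conductivity.sigma_brain)
    G = k * np.einsum("dk,cdk->cd", source_orientations, u) / dist ** 2
    return LeadField(G=G, source_positions=source_positions,
                     source_orientations=source_orientations)


def estimate_noise_covariance(baseline,
                              loading_fraction: float = 0.05) -> NoiseCovariance:
    """Sample covariance of a resting baseline plus diagonal loading.

    ``C = cov(baseline) + loading_fraction * mean(diag(cov)) * I``.  For a
    degenerate all-zero sample covariance the loading falls back to unit
    scale so the result stays invertible.
    """
    if isinstance(baseline, ContinuousEEG):
        X = baseline.data
    elif isinstance(baseline, SensorEpochs):
        X = np.concatenate(list(baseline.data), axis=1)
    else:
        X = np.asarray(baseline, dtype=float)
        if X.ndim != 2:
            raise ValueError("baseline array must be channels x samples")
    n_ch, n_samp = X.shape
    if n_samp == 0:
        raise ValueError("zero-length baseline")
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = max(n_samp - 1, 1)
    C = Xc @ Xc.T / denom
    C = 0.5 * (C + C.T)
    scale = float(np.mean(np.diag(C)))
    if scale <= 0:
        scale = 1.0
    C = C + loading_fraction * scale * np.eye(n_ch)
    return NoiseCovariance(C=C, n_samples_used=n_samp)
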