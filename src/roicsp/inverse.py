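"""Weighted minimum-norm (wMNE) inverse solution.

The forward model is ``M = G D`` with sensor data ``M`` (channels x
samples), gain matrix ``G`` and dipole current density ``D``.  With many
more dipoles than channels the problem is underdetermined; the wMNE
estimate is the minimizer of

    || C^{-1/2} (M - G D) ||^2  +  lambda2 * || R^{-1/2} D ||^2

whose closed form is  K = R G^T (G R G^T + lambda2 * C)^{-1},  D = K M.
``R = diag(||g_d||^{-2 * depth_exponent})`` is the depth-weighting prior
that counters the bias of plain MNE toward superficial sources; exponent
0 recovers plain MNE.  ``lambda2`` defaults to the common 1/SNR^2
convention with an assumed amplitude SNR of 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .containers import SensorEpochs, SourceEpochs
from .headmodel import LeadField, NoiseCovariance

__all__ = ["InverseConfig", "InverseOperator", "build_inverse_operator",
           "apply_inverse"]


@dataclass(frozen=True)
class InverseConfig:
    """Regularization and weighting choices for the inverse operator."""

    lambda2: float = 1.0 / 9.0  # 1/SNR^2 with amplitude SNR = 3
    depth_exponent: float = 0.5
    whiten: bool = False

    def __post_init__(self):
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be non-negative")
        if not 0 <= self.depth_exponent <= 1:
            raise ValueError("depth_exponent must lie in [0, 1]")


@dataclass
class InverseOperator:
    """Linear map K (dipoles x channels) taking sensor data to sources."""

    K: np.ndarray
    config: InverseConfig
    leadfield_id: str = ""

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if not np.all(np.isfinite(self.K)):
            raise ValueError("inverse operator has non-finite entries")

    @property
    def n_dipoles(self) -> int:
        return self.K.shape[0]

    @property
    def n_channels(self) -> int:
        return self.K.shape[1]


def _depth_weights(G: np.ndarray, exponent: float) -> np.ndarray:
    norms = np.linalg.norm(G, axis=0)
    if np.any(norms == 0):
        raise ValueError("lead field has an all-zero column")
    return norms ** (-2.0 * exponent)


def build_inverse_operator(L: LeadField, C: NoiseCovariance,
                           cfg: InverseConfig | None = None) -> InverseOperator:
    """Assemble K = R G^T (G R G^T + lambda2 C)^{-1}.

    With ``cfg.whiten`` the computation runs in the whitened sensor space
    (G and M pre-multiplied by C^{-1/2}); the two routes are algebraically
    identical and agree to numerical precision.
    """
    cfg = cfg or InverseConfig()
    G = L.G
    Cmat = C.C
    if Cmat.shape[0] != G.shape[0]:
        raise ValueError(
            f"noise covariance has {Cmat.shape[0]} channels, lead field "
            f"has {G.shape[0]}")
    r = _depth_weights(G, cfg.depth_exponent)  # diagonal of R

    if cfg.whiten:
        # C^{-1/2} via eigendecomposition; K = R Gw^T (Gw R Gw^T + l2 I)^{-1} W
        w, V = np.linalg.eigh(Cmat)
        if np.any(w <= 0):
            raise ValueError("noise covariance not positive definite; "
                             "increase diagonal loading")
        W = V @ np.diag(w ** -0.5) @ V.T
        Gw = W @ G
        A = (Gw * r) @ Gw.T + cfg.lambda2 * np.eye(Gw.shape[0])
        try:
            Ainv = scipy.linalg.inv(A)
        except scipy.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular system; increase lambda2 or covariance loading"
            ) from exc
        K = (r[:, None] * Gw.T) @ Ainv @ W
    else:
        A = (G * r) @ G.T + cfg.lambda2 * Cmat
        try:
            cho = scipy.linalg.cho_factor(A)
            Ainv = scipy.linalg.cho_solve(cho, np.eye(A.shape[0]))
        except scipy.linalg.LinAlgError:
            # fall back to a generic solve; raise if genuinely singular
            try:
                Ainv = scipy.linalg.inv(A)
            except scipy.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "singular system; increase lambda2 or covariance loading"
                ) from exc
        K = (r[:, None] * G.T) @ Ainv
    return InverseOperator(K=K, config=cfg)


def apply_inverse(K: InverseOperator, epochs: SensorEpochs) -> SourceEpochs:
    """Per-trial D = K M; labels, fs and timing carry through."""
    if epochs.n_channels != K.n_channels:
        raise ValueError(
            f"epochs have {epochs.n_channels} channels, inverse operator "
            f"expects {K.n_channels}")
    data = np.einsum("dc,tcs->tds", K.K, epochs.data)
    return SourceEpochs(data=data, fs=epochs.fs, labels=epochs.labels,
                        t0=epochs.t0)
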