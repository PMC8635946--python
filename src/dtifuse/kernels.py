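"""Gaussian interaction profile (GIP) kernels and convex kernel combination.

The GIP kernel measures how alike two drugs (or two targets) are in terms of
which partners they are known to interact with:

    K(i, j) = exp(-gamma * ||y_i - y_j||^2),
    gamma   = gamma_scale / mean_i ||y_i||^2,

where ``y_i`` is the binary interaction profile of entity ``i``.  The
bandwidth normalization by the mean squared profile norm makes the kernel
insensitive to overall dataset density.  The working kernels are convex
combinations of measured similarity (chemical or genomic) with the GIP
kernel:

    K_d = alpha_d * K_chemical + (1 - alpha_d) * K_GIP,d
    K_t = alpha_t * K_genomic  + (1 - alpha_t) * K_GIP,t
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg

log = logging.getLogger(__name__)


class DegenerateBandwidthError(ValueError):
    """All interaction profiles are zero, so the GIP bandwidth is undefined."""


def gip_kernel(profile_matrix: np.ndarray, gamma_scale: float = 1.0) -> np.ndarray:
    """GIP kernel over the rows of ``profile_matrix``.

    Raises :class:`DegenerateBandwidthError` when every profile is zero;
    complete such profiles first (e.g. with WNN).
    """
    P = np.asarray(profile_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("profile matrix must be 2-D with at least one row")
    sq_norms = np.einsum("ij,ij->i", P, P)
    mean_sq = sq_norms.mean()
    if mean_sq == 0.0:
        raise DegenerateBandwidthError(
            "all interaction profiles are zero; complete them (WNN) before "
            "building a GIP kernel"
        )
    gamma = gamma_scale / mean_sq
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(sq_dist, 0.0, out=sq_dist)
    K = np.exp(-gamma * sq_dist)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return K


def _combine(K_measured: np.ndarray, K_gip: np.ndarray, alpha: float) -> np.ndarray:
    K_measured = np.asarray(K_measured, dtype=float)
    K_gip = np.asarray(K_gip, dtype=float)
    if K_measured.shape != K_gip.shape:
        raise ValueError(
            f"kernel shape mismatch: {K_measured.shape} vs {K_gip.shape}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("combination weight must lie in [0, 1]")
    return alpha * K_measured + (1.0 - alpha) * K_gip


def combine_drug_kernel(K_chemical: np.ndarray, K_gip: np.ndarray,
                        alpha_d: float) -> np.ndarray:
    """K_d = alpha_d * K_chemical + (1 - alpha_d) * K_GIP,d."""
    return _combine(K_chemical, K_gip, alpha_d)


def combine_target_kernel(K_genomic: np.ndarray, K_gip: np.ndarray,
                          alpha_t: float) -> np.ndarray:
    """K_t = alpha_t * K_genomic + (1 - alpha_t) * K_GIP,t."""
    return _combine(K_genomic, K_gip, alpha_t)


def psd_clip(K: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by clipping eigenvalues.

    Measured chemical similarities (SIMCOMP-style) are often indefinite; they
    are used as-is in kernel combination and only projected where a solver
    requires positive semidefiniteness.
    """
    K = np.asarray(K, dtype=float)
    w, V = scipy.linalg.eigh((K + K.T) / 2.0)
    if w.min() < -tol:
        log.warning("clipping %d negative eigenvalues (min %g) to 0",
                    int((w < 0).sum()), w.min())
    return (V * np.maximum(w, 0.0)) @ V.T
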