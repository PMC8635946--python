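"""WNN-GIP: weighted-nearest-neighbor profile completion plus Kronecker RLS.

The GIP kernel is only informative for entities with at least one known
interaction.  New drugs (all-zero rows of Y) first receive an inferred
profile: training drugs are ranked by similarity to the new drug and their
profiles summed with geometrically decaying weights,

    y_WNN = sum_i T^(rank_i - 1) * y_i,   0 < T <= 1.

Prediction then runs regularized least squares over the Kronecker pair
kernel K = K_d (x) K_t,

    y_hat = K (K + sigma I)^-1 y,

computed through the eigendecomposition fast path instead of materializing
the n*m x n*m Kronecker system.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg

from .config import RunConfig
from .data import DTIDataset, ScoreMatrix, SourceTag
from .kernels import combine_drug_kernel, combine_target_kernel, gip_kernel

log = logging.getLogger(__name__)


def wnn_profile(
    new_drug_similarities: np.ndarray,
    Y: np.ndarray,
    decay_T: float = 0.7,
    weighting: str = "rank",
    clip: bool = True,
) -> np.ndarray:
    """Inferred interaction profile of a new drug.

    ``new_drug_similarities`` holds similarities to the training drugs whose
    rows form ``Y``.  With ``weighting='rank'`` (default) drug ``i`` at
    similarity rank ``r_i`` (descending, stable ties) gets weight
    ``decay_T**(r_i - 1)``; with ``'similarity'`` the raw similarities are the
    weights.  ``clip`` caps the result at 1.
    """
    s = np.asarray(new_drug_similarities, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("training interaction matrix must be non-empty")
    if s.shape != (Y.shape[0],):
        raise ValueError("similarity vector length must equal the drug count")
    if weighting == "rank":
        order = np.argsort(-s, kind="stable")
        weights = np.empty_like(s)
        weights[order] = decay_T ** np.arange(len(s))
    elif weighting == "similarity":
        weights = s
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    profile = weights @ Y
    if clip:
        profile = np.clip(profile, 0.0, 1.0)
    return profile


def rls_predict(K: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    """Regularized least-squares prediction y_hat = K (K + sigma I)^-1 y.

    Uses a symmetric linear solve, never an explicit inverse.  ``y`` may be a
    vector or a matrix of stacked label columns.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    A = K + sigma * np.eye(K.shape[0])
    return K @ scipy.linalg.solve(A, y, assume_a="sym")


def _clipped_eigh(K: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray]:
    if np.max(np.abs(K - K.T)) > 1e-8:
        raise ValueError(f"{name} kernel is not symmetric")
    w, V = scipy.linalg.eigh((K + K.T) / 2.0)
    if w.min() < -1e-10:
        log.warning("%s kernel indefinite (min eigenvalue %g); clipping to 0",
                    name, w.min())
    return np.maximum(w, 0.0), V


def kron_rls(K_d: np.ndarray, K_t: np.ndarray, Y: np.ndarray,
             sigma: float) -> np.ndarray:
    """Kronecker-kernel RLS over all drug-target pairs.

    Equivalent to ``rls_predict`` on the n*m Kronecker kernel with vec(Y),
    reshaped to n x m, but computed from the per-side eigendecompositions:
    with K_d = V_d diag(lam) V_d^T and K_t = V_t diag(mu) V_t^T the filter
    factors lam_i*mu_j / (lam_i*mu_j + sigma) act on V_d^T Y V_t.
    """
    Y = np.asarray(Y, dtype=float)
    lam, V_d = _clipped_eigh(np.asarray(K_d, float), "drug")
    mu, V_t = _clipped_eigh(np.asarray(K_t, float), "target")
    prod = lam[:, None] * mu[None, :]
    denom = prod + sigma
    with np.errstate(invalid="ignore", divide="ignore"):
        filt = np.where(denom > 0.0, prod / denom, 0.0)
    core = filt * (V_d.T @ Y @ V_t)
    return V_d @ core @ V_t.T


def complete_profiles(dataset: DTIDataset, cfg: RunConfig) -> np.ndarray:
    """Y with all-zero drug rows (and optionally target columns) replaced by
    WNN-inferred profiles."""
    Y = dataset.Y.astype(float)
    new_drugs = np.flatnonzero(Y.sum(axis=1) == 0)
    train_drugs = np.flatnonzero(Y.sum(axis=1) > 0)
    if new_drugs.size and train_drugs.size:
        for i in new_drugs:
            Y[i] = wnn_profile(
                dataset.S_d[i, train_drugs], dataset.Y[train_drugs],
                decay_T=cfg.wnn_decay, weighting=cfg.wnn_weighting,
                clip=cfg.wnn_clip,
            )
    if cfg.wnn_targets:
        new_t = np.flatnonzero(dataset.Y.sum(axis=0) == 0)
        train_t = np.flatnonzero(dataset.Y.sum(axis=0) > 0)
        if new_t.size and train_t.size:
            for j in new_t:
                Y[:, j] = wnn_profile(
                    dataset.S_t[j, train_t], dataset.Y[:, train_t].T,
                    decay_T=cfg.wnn_decay, weighting=cfg.wnn_weighting,
                    clip=cfg.wnn_clip,
                )
    return Y


def combined_kernels(dataset: DTIDataset, cfg: RunConfig,
                     profiles: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """The working kernels K_d, K_t from measured similarity plus GIP."""
    if profiles is None:
        profiles = dataset.Y.astype(float)
    K_gip_d = gip_kernel(profiles, cfg.gamma_scale)
    K_gip_t = gip_kernel(profiles.T, cfg.gamma_scale)
    K_d = combine_drug_kernel(dataset.S_d, K_gip_d, cfg.alpha_d)
    K_t = combine_target_kernel(dataset.S_t, K_gip_t, cfg.alpha_t)
    return K_d, K_t


def wnn_gip_score(dataset: DTIDataset, cfg: RunConfig | None = None) -> ScoreMatrix:
    """The WNN-GIP score matrix Y_3 for every drug-target pair."""
    cfg = cfg or RunConfig()
    profiles = complete_profiles(dataset, cfg)
    K_d, K_t = combined_kernels(dataset, cfg, profiles)
    scores = kron_rls(K_d, K_t, profiles, cfg.sigma)
    return ScoreMatrix(scores, SourceTag.WS)
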