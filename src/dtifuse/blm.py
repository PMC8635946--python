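"""Bipartite local models with neighbor-based interaction-profile inferring.

Each drug-target pair is scored twice: a drug-side local model (RLS over
targets with the drug's label row and the target kernel K_t) and a
target-side local model (RLS over drugs with the target's label column and
the drug kernel K_d).  An entity with no known interactions cannot train a
local model, so its label vector is first replaced by the NII profile — the
similarity-weighted mean of the training profiles, scaled by beta:

    y_nii = beta * (sum_i s_i y_i) / (sum_i s_i).

The two sides are combined per pair by max (default) or mean.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg

from .data import ScoreMatrix, SourceTag

log = logging.getLogger(__name__)


def nii_profile(similarities_to_training: np.ndarray, Y_block: np.ndarray,
                nii_beta: float = 1.0) -> np.ndarray:
    """Similarity-weighted mean of training profiles, scaled by ``nii_beta``.

    ``Y_block`` stacks the training entities' profiles as rows; entries of
    the result lie in [0, nii_beta].  All-zero similarities give a zero
    profile with a warning.
    """
    s = np.asarray(similarities_to_training, dtype=float)
    Y_block = np.asarray(Y_block, dtype=float)
    if s.shape[0] != Y_block.shape[0]:
        raise ValueError("similarity vector length must match profile count")
    total = s.sum()
    if total <= 0:
        log.warning("all similarities to training entities are zero; "
                    "NII profile is zero")
        return np.zeros(Y_block.shape[1])
    return nii_beta * (s @ Y_block) / total


def _effective_labels(Y: np.ndarray, S: np.ndarray, nii_beta: float) -> np.ndarray:
    """Rows of Y with all-zero rows replaced by their NII profiles."""
    Y_eff = Y.astype(float).copy()
    empty = np.flatnonzero(Y.sum(axis=1) == 0)
    train = np.flatnonzero(Y.sum(axis=1) > 0)
    if empty.size and train.size:
        for i in empty:
            Y_eff[i] = nii_profile(S[i, train], Y[train], nii_beta)
    return Y_eff


def _rls_operator(K: np.ndarray, sigma: float) -> np.ndarray:
    """M = K (K + sigma I)^-1, so that y_hat = M y for any label vector."""
    A = K + sigma * np.eye(K.shape[0])
    return scipy.linalg.solve(A, K, assume_a="sym").T


def blm_score(train_Y: np.ndarray, K_d: np.ndarray, K_t: np.ndarray,
              sigma: float = 1.0, nii_beta: float = 1.0,
              combine_rule: str = "max") -> ScoreMatrix:
    """BLM-NII scores for every drug-target pair.

    ``train_Y`` may be the binary revised matrix or a real-valued score
    matrix (the continuous-revision path); kernels come from the ``kernels``
    module.
    """
    train_Y = np.asarray(train_Y, dtype=float)
    n, m = train_Y.shape
    if K_d.shape != (n, n) or K_t.shape != (m, m):
        raise ValueError("kernel shapes must match the interaction matrix")
    if combine_rule not in ("max", "mean"):
        raise ValueError(f"unknown combine rule {combine_rule!r}")

    # drug-side: labels are rows over targets, kernel K_t
    rows = _effective_labels(train_Y, K_d, nii_beta)
    drug_side = rows @ _rls_operator(K_t, sigma)
    # target-side: labels are columns over drugs, kernel K_d
    cols = _effective_labels(train_Y.T, K_t, nii_beta)
    target_side = (cols @ _rls_operator(K_d, sigma)).T

    if combine_rule == "max":
        scores = np.maximum(drug_side, target_side)
    else:
        scores = (drug_side + target_side) / 2.0
    return ScoreMatrix(scores, SourceTag.BLM)
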