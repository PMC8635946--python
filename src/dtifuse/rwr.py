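"""Random walk with restart on the drug-target heterogeneous network.

The network joins the target-similarity layer and the drug-similarity layer
through known (or screening-revised) interaction edges.  The transition
matrix is block-structured over the m + n nodes (targets first, then drugs):

    W = [ W_TT  W_TD ]
        [ W_DT  W_DD ]

A node with at least one interaction keeps probability mass (1 - lambda) in
its own layer (row-normalized similarity) and sends lambda across the
interaction edges (row-normalized interaction profile); a node with no
interactions stays in its layer.  The walk iterates

    p_{t+1} = (1 - c) W^T p_t + c p_0

until ||p_{t+1} - p_t|| <= tol (default 1e-10).  One walk is run per drug
seed; the target block of the stationary vector scores that drug against
every target, giving the revised matrix Y_2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data import DTIDataset, ScoreMatrix, SourceTag


class ConvergenceError(RuntimeError):
    pass


def _row_normalize(M: np.ndarray) -> np.ndarray:
    """Rows scaled to sum 1; all-zero rows left as zeros."""
    sums = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, M / sums, 0.0)
    return out


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix with its four blocks exposed."""

    W: np.ndarray           # (m + n) x (m + n), targets first
    m_targets: int
    n_drugs: int
    jump_lambda: float

    @property
    def W_TT(self) -> np.ndarray:
        return self.W[: self.m_targets, : self.m_targets]

    @property
    def W_TD(self) -> np.ndarray:
        return self.W[: self.m_targets, self.m_targets:]

    @property
    def W_DT(self) -> np.ndarray:
        return self.W[self.m_targets:, : self.m_targets]

    @property
    def W_DD(self) -> np.ndarray:
        return self.W[self.m_targets:, self.m_targets:]


def build_transition(dataset: DTIDataset, jump_lambda: float = 0.5,
                     Y: np.ndarray | None = None) -> TransitionMatrix:
    """Heterogeneous-network transition matrix from (S_t, S_d, Y).

    ``Y`` overrides the dataset's interaction matrix (e.g. the
    screening-revised Y_1).  Rows that end up entirely zero (isolated node
    with zero similarity) get a self-loop so the matrix stays stochastic.
    """
    if not 0.0 <= jump_lambda <= 1.0:
        raise ValueError("jump_lambda must lie in [0, 1]")
    Y = dataset.Y if Y is None else np.asarray(Y)
    if (dataset.S_d < 0).any() or (dataset.S_t < 0).any():
        raise ValueError("similarity matrices must be nonnegative")
    n, m = dataset.n_drugs, dataset.m_targets

    St_norm = _row_normalize(dataset.S_t.astype(float))
    Sd_norm = _row_normalize(dataset.S_d.astype(float))
    YT_norm = _row_normalize(Y.T.astype(float))   # target -> drugs
    Y_norm = _row_normalize(Y.astype(float))      # drug -> targets

    t_linked = Y.sum(axis=0) > 0
    d_linked = Y.sum(axis=1) > 0

    W_TT = np.where(t_linked[:, None], (1 - jump_lambda) * St_norm, St_norm)
    W_TD = np.where(t_linked[:, None], jump_lambda * YT_norm, 0.0)
    W_DD = np.where(d_linked[:, None], (1 - jump_lambda) * Sd_norm, Sd_norm)
    W_DT = np.where(d_linked[:, None], jump_lambda * Y_norm, 0.0)

    W = np.block([[W_TT, W_TD], [W_DT, W_DD]])
    dangling = np.flatnonzero(W.sum(axis=1) == 0)
    W[dangling, dangling] = 1.0
    return TransitionMatrix(W, m, n, jump_lambda)


def restart_vector(dataset: DTIDataset, drug_index: int, eta: float = 0.5,
                   Y: np.ndarray | None = None) -> np.ndarray:
    """Restart distribution p_0 = [(1 - eta) u_0 ; eta v_0] for a drug seed.

    v_0 is the indicator of the seed drug; u_0 spreads the drug's known
    interactions over the target layer (uniform when it has none).
    """
    if not 0.0 < eta < 1.0:
        raise ValueError("eta must lie in (0, 1)")
    n, m = dataset.n_drugs, dataset.m_targets
    if not 0 <= drug_index < n:
        raise IndexError(f"drug index {drug_index} out of range for {n} drugs")
    Y = dataset.Y if Y is None else np.asarray(Y)
    row = Y[drug_index].astype(float)
    u0 = row / row.sum() if row.sum() > 0 else np.full(m, 1.0 / m)
    v0 = np.zeros(n)
    v0[drug_index] = 1.0
    return np.concatenate([(1.0 - eta) * u0, eta * v0])


def walk(W: np.ndarray | TransitionMatrix, p0: np.ndarray, restart_c: float = 0.7,
         tol: float = 1e-10, max_iter: int = 10_000) -> tuple[np.ndarray, int]:
    """Iterate the restart walk to its stationary vector.

    Returns ``(p_inf, iterations)``.  Raises :class:`ConvergenceError` when
    the gap has not fallen below ``tol`` within ``max_iter`` steps.
    """
    if isinstance(W, TransitionMatrix):
        W = W.W
    if not 0.0 < restart_c <= 1.0:
        raise ValueError("restart_c must lie in (0, 1]")
    p0 = np.asarray(p0, dtype=float)
    WT = W.T.copy()
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - restart_c) * (WT @ p) + restart_c * p0
        gap = np.linalg.norm(p_next - p)
        p = p_next
        if gap <= tol:
            return p, it
    raise ConvergenceError(
        f"walk did not converge in {max_iter} iterations (last gap {gap:g})"
    )


def closed_form_walk(W: np.ndarray | TransitionMatrix, p0: np.ndarray,
                     restart_c: float) -> np.ndarray:
    """Exact stationary vector c (I - (1-c) W^T)^-1 p_0 by dense solve."""
    if isinstance(W, TransitionMatrix):
        W = W.W
    N = W.shape[0]
    A = np.eye(N) - (1.0 - restart_c) * W.T
    return restart_c * scipy.linalg.solve(A, np.asarray(p0, float))


def rwr_score(dataset: DTIDataset, restart_c: float = 0.7, eta: float = 0.5,
              jump_lambda: float = 0.5, tol: float = 1e-10,
              max_iter: int = 10_000, Y: np.ndarray | None = None) -> ScoreMatrix:
    """The RWR score matrix Y_2: one walk per drug seed; row i is the target
    block of that walk's stationary vector."""
    trans = build_transition(dataset, jump_lambda, Y=Y)
    m = dataset.m_targets
    out = np.empty((dataset.n_drugs, m))
    for i in range(dataset.n_drugs):
        p0 = restart_vector(dataset, i, eta, Y=Y)
        p_inf, _ = walk(trans, p0, restart_c, tol, max_iter)
        out[i] = p_inf[:m]
    return ScoreMatrix(out, SourceTag.RS)
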