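"""Screening of unlabeled pairs, score normalization, and matrix fusion.

Three revised interaction matrices are produced from a training dataset:

* Y_1 — similarity screening: when two drugs are chemically similar enough,
  each inherits the other's known targets as putative positives.
* Y_2 — random walk with restart scores (``rwr`` module).
* Y_3 — WNN-GIP scores (``wnn_gip`` module).

They are fused into Y_final by a convex combination whose weights reflect
each source's estimated prediction quality (inner-CV AUPR), or by the AVE
(equal-weight) / VOTE (per-cell majority after binarization) baselines.
The top-scoring unlabeled pairs of Y_final are then promoted to positives,
yielding the revised training matrix the final predictor consumes.

The three sources live on incompatible scales (Y_1 is binary, Y_2 rows are
sub-probability vectors, Y_3 is an RLS score), so each matrix is min-max
normalized to [0, 1] before any fusion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .data import DTIDataset, ScoreMatrix, SourceTag

log = logging.getLogger(__name__)


@dataclass
class AddedPair:
    """Audit record for a pair promoted to positive."""

    drug_index: int
    target_index: int
    score: float
    rank: int


# ---------------------------------------------------------------------------
# similarity screening


def similarity_screen(
    dataset: DTIDataset,
    theta_sim: float | None = 0.7,
    top_k: int | None = None,
) -> tuple[ScoreMatrix, list[AddedPair]]:
    """Single-step propagation of known interactions across similar drugs.

    Exactly one of ``theta_sim`` / ``top_k`` selects the qualifying drug
    pairs: either every unordered pair with similarity >= theta_sim, or the
    ``top_k`` most similar unordered pairs.  For each qualifying pair (a, b)
    and target t with Y(a, t) = 1 and Y(b, t) = 0 the pair (b, t) is added.
    Propagation uses the original Y only (no transitive closure), so
    Y_1 >= Y elementwise and nothing is ever removed.
    """
    if (theta_sim is None) == (top_k is None):
        raise ValueError("exactly one of theta_sim / top_k must be given")
    n = dataset.n_drugs
    iu = np.triu_indices(n, k=1)
    sims = dataset.S_d[iu]
    if top_k is not None:
        if top_k < 0:
            raise ValueError("top_k must be nonnegative")
        # deterministic: similarity desc, then (row, col) lexicographic
        order = np.lexsort((iu[1], iu[0], -sims))[:top_k]
        pairs = list(zip(iu[0][order], iu[1][order]))
    else:
        keep = sims >= theta_sim
        pairs = list(zip(iu[0][keep], iu[1][keep]))

    Y = dataset.Y
    Y1 = Y.astype(np.int8).copy()
    added: list[AddedPair] = []
    for a, b in pairs:
        for src, dst in ((a, b), (b, a)):
            targets = np.flatnonzero((Y[src] == 1) & (Y[dst] == 0))
            for t in targets:
                if Y1[dst, t] == 0:
                    Y1[dst, t] = 1
                    added.append(AddedPair(int(dst), int(t),
                                           float(dataset.S_d[a, b]), 0))
    added.sort(key=lambda p: (-p.score, p.drug_index, p.target_index))
    for rank, p in enumerate(added, start=1):
        p.rank = rank
    return ScoreMatrix(Y1, SourceTag.SIM), added


def write_audit(added: list[AddedPair], dataset: DTIDataset, path: str) -> None:
    """Tab-separated audit list of promoted pairs."""
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\tscore\trank\n")
        for p in added:
            fh.write(f"{dataset.drug_ids[p.drug_index]}\t"
                     f"{dataset.target_ids[p.target_index]}\t"
                     f"{p.score:.17g}\t{p.rank}\n")


# ---------------------------------------------------------------------------
# normalization and fusion


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Affine map of a finite matrix onto [0, 1]; constant matrices map to 0."""
    M = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("scores must be finite")
    lo, hi = M.min(), M.max()
    if hi == lo:
        return np.zeros_like(M)
    return (M - lo) / (hi - lo)


def check_weights(weights, n_sources: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n_sources,):
        raise ValueError(f"expected {n_sources} weights, got shape {w.shape}")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("fusion weights must lie in [0, 1]")
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValueError(f"fusion weights must sum to 1 (got {w.sum()!r})")
    return w


def weighted_fuse(score_matrices, weights) -> ScoreMatrix:
    """Y_final = sum_i alpha_i * minmax(Y_i), with alpha in the simplex."""
    mats = [m.values if isinstance(m, ScoreMatrix) else np.asarray(m, float)
            for m in score_matrices]
    if not mats:
        raise ValueError("at least one score matrix required")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("score matrices must share a shape")
    w = check_weights(weights, len(mats))
    out = np.zeros(shape)
    for wi, m in zip(w, mats):
        out += wi * minmax_normalize(m)
    return ScoreMatrix(out, SourceTag.FUSED)


def _binarize_top(values: np.ndarray, fraction: float) -> np.ndarray:
    """Top ceil(fraction * N) cells set to 1 (score desc, then row, col)."""
    flat = values.ravel()
    k = math.ceil(fraction * flat.size)
    n_cols = values.shape[1]
    rows, cols = np.divmod(np.arange(flat.size), n_cols)
    order = np.lexsort((cols, rows, -flat))
    out = np.zeros(flat.size, dtype=np.int8)
    out[order[:k]] = 1
    return out.reshape(values.shape)


def vote_fuse(score_matrices, binarize_fraction: float = 0.01) -> ScoreMatrix:
    """Majority vote over per-source binarized matrices.

    Each source is binarized at its own top ``binarize_fraction`` of cells;
    a cell is 1 when at least ceil(k/2) of the k (odd, >= 3) sources vote 1.
    """
    mats = [m.values if isinstance(m, ScoreMatrix) else np.asarray(m, float)
            for m in score_matrices]
    k = len(mats)
    if k < 3 or k % 2 == 0:
        raise ValueError("vote fusion needs an odd number (>= 3) of sources")
    votes = sum(_binarize_top(m, binarize_fraction) for m in mats)
    majority = math.ceil(k / 2)
    return ScoreMatrix((votes >= majority).astype(float), SourceTag.FUSED)


# ---------------------------------------------------------------------------
# performance-based weights


def performance_weights(
    dataset: DTIDataset,
    score_fns: dict[str, "callable"],
    inner_folds: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Fusion weights proportional to each source's inner-CV AUPR.

    Known positives of the training data are split into ``inner_folds``
    groups; each group is masked to 0 in turn, every source scores the masked
    dataset, and the masked positives (label 1) are ranked against the pairs
    unlabeled in the full training matrix (label 0).  alpha_i is the mean
    AUPR of source i normalized across sources.  When every AUPR is zero the
    weights fall back to equal, with a warning.
    """
    from .evaluation import aupr_score  # local import avoids a module cycle

    if len(score_fns) < 2:
        raise ValueError("performance weighting needs at least two sources")
    rng = np.random.default_rng(seed)
    pos = np.argwhere(dataset.Y == 1)
    if len(pos) < inner_folds:
        log.warning("too few positives (%d) for %d inner folds; equal weights",
                    len(pos), inner_folds)
        return np.full(len(score_fns), 1.0 / len(score_fns))
    pos = pos[rng.permutation(len(pos))]
    folds = [pos[i::inner_folds] for i in range(inner_folds)]
    unlabeled = dataset.Y == 0

    auprs = {name: [] for name in score_fns}
    for fold in folds:
        Y_masked = dataset.Y.copy()
        Y_masked[fold[:, 0], fold[:, 1]] = 0
        masked = dataset.with_interactions(Y_masked)
        for name, fn in score_fns.items():
            values = fn(masked)
            values = values.values if isinstance(values, ScoreMatrix) else values
            scores = np.concatenate([values[fold[:, 0], fold[:, 1]],
                                     values[unlabeled]])
            labels = np.concatenate([np.ones(len(fold)),
                                     np.zeros(int(unlabeled.sum()))])
            auprs[name].append(aupr_score(scores, labels))

    mean_auprs = np.array([np.mean(auprs[name]) for name in score_fns])
    total = mean_auprs.sum()
    if total <= 0:
        log.warning("all inner-CV AUPRs are zero; falling back to equal weights")
        return np.full(len(score_fns), 1.0 / len(score_fns))
    return mean_auprs / total


# ---------------------------------------------------------------------------
# training-matrix revision


def revise_training_matrix(
    Y: np.ndarray,
    Y_final: np.ndarray | ScoreMatrix,
    select_fraction: float = 0.01,
) -> tuple[np.ndarray, list[AddedPair]]:
    """Promote the top fraction of unlabeled pairs to positives.

    The top ``ceil(select_fraction * n_unlabeled)`` pairs ranked by Y_final
    (score desc, ties by row then column) are set to 1 on a copy of Y; known
    positives are never touched, so the added sets nest as the fraction
    grows.
    """
    if not 0.0 <= select_fraction <= 1.0:
        raise ValueError("select_fraction must lie in [0, 1]")
    Y = np.asarray(Y)
    values = Y_final.values if isinstance(Y_final, ScoreMatrix) else np.asarray(Y_final)
    if values.shape != Y.shape:
        raise ValueError("score matrix shape must match the interaction matrix")
    revised = Y.astype(np.int8).copy()
    unl = np.argwhere(Y == 0)
    k = math.ceil(select_fraction * len(unl)) if select_fraction > 0 else 0
    if k == 0:
        return revised, []
    scores = values[unl[:, 0], unl[:, 1]]
    order = np.lexsort((unl[:, 1], unl[:, 0], -scores))[:k]
    added = []
    for rank, idx in enumerate(order, start=1):
        i, j = int(unl[idx, 0]), int(unl[idx, 1])
        revised[i, j] = 1
        added.append(AddedPair(i, j, float(scores[idx]), rank))
    return revised, added
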