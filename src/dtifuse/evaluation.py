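"""Evaluation protocol: k-fold cross-validation, AUC, AUPR, and top-fraction
thresholded confusion metrics.

Pairs are cross-validated pair-wise by default (drug-wise and target-wise
splits are available for new-entity scenarios): the held-out pairs' entries
are masked to 0 in the training matrix — unknowns are unlabeled, not
negative — the pipeline runs on the masked dataset, and only the held-out
pairs are scored.  Ranked predictions are thresholded at a top fraction
(1% by convention) to produce accuracy, sensitivity, specificity, and
precision as percentages.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import RunConfig
from .data import DTIDataset

log = logging.getLogger(__name__)


def auc_score(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties counted 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def aupr_score(scores, labels) -> float:
    """Step-wise area under the precision-recall curve."""
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, float)))


@dataclass
class ThresholdedMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.accuracy, self.sensitivity, self.specificity, self.precision)


def thresholded_metrics(scores, labels, top_fraction: float = 0.01) -> ThresholdedMetrics:
    """Confusion metrics (percent) after calling the top fraction positive.

    The top ``ceil(top_fraction * N)`` scores are predicted positive; ties at
    the cutoff are broken by score descending then original index, so the
    result is deterministic.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    N = scores.size
    k = math.ceil(top_fraction * N)
    order = np.lexsort((np.arange(N), -scores))
    pred = np.zeros(N, dtype=int)
    pred[order[:k]] = 1

    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())

    def pct(num, den):
        return 100.0 * num / den if den else 0.0

    return ThresholdedMetrics(
        accuracy=pct(tp + tn, N),
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        precision=pct(tp, tp + fp),
    )


@dataclass
class FoldResult:
    fold: int
    n_test: int
    n_pos: int
    auc: float
    aupr: float
    metrics: ThresholdedMetrics


@dataclass
class EvalReport:
    """Aggregate and per-fold cross-validation metrics."""

    auc: float
    aupr: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    top_fraction: float
    n_folds: int
    method: str
    per_fold: list[FoldResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def make_folds(dataset: DTIDataset, n_folds: int, seed: int,
               granularity: str = "pair") -> list[np.ndarray]:
    """Deterministic fold assignment.

    Pair-wise folds are stratified by label (positives and negatives dealt
    round-robin after a seeded shuffle) and partition all n*m pairs exactly
    once.  Drug-wise / target-wise folds hold out whole rows / columns.
    """
    rng = np.random.default_rng(seed)
    n, m = dataset.n_drugs, dataset.m_targets
    if granularity == "pair":
        flat = np.arange(n * m)
        labels = dataset.Y.ravel()
        folds: list[list[int]] = [[] for _ in range(n_folds)]
        for cls in (1, 0):
            idx = flat[labels == cls]
            idx = idx[rng.permutation(len(idx))]
            for i, p in enumerate(idx):
                folds[i % n_folds].append(int(p))
        return [np.array(sorted(f)) for f in folds]
    if granularity in ("drug", "target"):
        count = n if granularity == "drug" else m
        entities = rng.permutation(count)
        groups = [entities[i::n_folds] for i in range(n_folds)]
        out = []
        for g in groups:
            if granularity == "drug":
                pairs = [d * m + t for d in g for t in range(m)]
            else:
                pairs = [d * m + t for t in g for d in range(n)]
            out.append(np.array(sorted(pairs)))
        return out
    raise ValueError(f"unknown granularity {granularity!r}")


def _score_masked(masked: DTIDataset, cfg: RunConfig, method: str) -> np.ndarray:
    from .pipeline import (compute_sources, predict_pipeline,
                           single_source_config)

    if method == "fused":
        return predict_pipeline(masked, cfg).scores.values
    if method in ("sim", "rs", "ws"):
        return predict_pipeline(masked, single_source_config(cfg, method)).scores.values
    if method in ("sim_raw", "rs_raw", "ws_raw"):
        src = compute_sources(masked, cfg)
        return src.sources[method[:-4]].values.astype(float)
    raise ValueError(f"unknown evaluation method {method!r}")


def cross_validate(dataset: DTIDataset, cfg: RunConfig | None = None,
                   n_folds: int | None = None, seed: int | None = None,
                   method: str = "fused") -> EvalReport:
    """k-fold cross-validation of the pipeline (or one of its ablations).

    ``method``: "fused" is the full weighted-fusion pipeline; "sim"/"rs"/"ws"
    revise the training matrix by a single source before BLM-NII;
    "*_raw" score held-out pairs directly with one source matrix.
    All test-pair entries are masked to 0 during training, so a held-out
    pair's own label can never influence its score.
    """
    cfg = cfg or RunConfig()
    n_folds = cfg.n_folds if n_folds is None else n_folds
    seed = cfg.seed if seed is None else seed
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    m = dataset.m_targets
    labels_flat = dataset.Y.ravel()
    folds = make_folds(dataset, n_folds, seed, cfg.cv_granularity)

    per_fold: list[FoldResult] = []
    for fi, test_idx in enumerate(folds):
        y_true = labels_flat[test_idx]
        if len(np.unique(y_true)) < 2:
            log.warning("fold %d has a single class; skipped", fi)
            continue
        Y_masked = dataset.Y.copy()
        Y_masked[test_idx // m, test_idx % m] = 0
        masked = dataset.with_interactions(Y_masked)
        fold_cfg = cfg.replace(seed=int((seed * 1_000 + fi) % (2**31 - 1)))
        values = _score_masked(masked, fold_cfg, method)
        y_score = values.ravel()[test_idx]
        per_fold.append(FoldResult(
            fold=fi, n_test=len(test_idx), n_pos=int(y_true.sum()),
            auc=auc_score(y_score, y_true),
            aupr=aupr_score(y_score, y_true),
            metrics=thresholded_metrics(y_score, y_true, cfg.top_fraction),
        ))

    if not per_fold:
        raise ValueError("every fold was single-class; cannot evaluate")

    def mean(fn):
        return float(np.mean([fn(f) for f in per_fold]))

    return EvalReport(
        auc=mean(lambda f: f.auc),
        aupr=mean(lambda f: f.aupr),
        accuracy=mean(lambda f: f.metrics.accuracy),
        sensitivity=mean(lambda f: f.metrics.sensitivity),
        specificity=mean(lambda f: f.metrics.specificity),
        precision=mean(lambda f: f.metrics.precision),
        top_fraction=cfg.top_fraction,
        n_folds=n_folds,
        method=method,
        per_fold=per_fold,
    )
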