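"""End-to-end prediction pipeline.

The full chain on a training dataset:

1. similarity screening of unlabeled pairs  -> Y_1 (and the revised-positive
   training matrix used by the two other scorers);
2. random walk with restart on the heterogeneous network -> Y_2;
3. WNN-GIP Kronecker RLS -> Y_3;
4. weighted fusion of the min-max-normalized sources -> Y_final
   (weights from inner-CV AUPR, fixed, equal, or majority vote);
5. promotion of the top-scoring unlabeled pairs -> revised training matrix;
6. BLM-NII trained on the revised matrix -> final scores.

Every intermediate is retained on the result object for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fusion, rwr
from .blm import blm_score
from .config import RunConfig
from .data import DTIDataset, ScoreMatrix, SourceTag
from .fusion import AddedPair
from .wnn_gip import combined_kernels, complete_profiles, wnn_gip_score

SOURCE_NAMES = ("sim", "rs", "ws")


@dataclass
class PipelineResult:
    """All intermediates of one pipeline run."""

    y1: ScoreMatrix                 # screening-revised binary matrix
    y2: ScoreMatrix                 # RWR scores
    y3: ScoreMatrix                 # WNN-GIP scores
    weights: np.ndarray             # fusion weights over (sim, rs, ws)
    y_final: ScoreMatrix            # fused scores
    revised_Y: np.ndarray           # training matrix handed to BLM-NII
    screen_added: list[AddedPair] = field(default_factory=list)
    revision_added: list[AddedPair] = field(default_factory=list)
    scores: ScoreMatrix | None = None  # BLM-NII output

    @property
    def sources(self) -> dict[str, ScoreMatrix]:
        return dict(zip(SOURCE_NAMES, (self.y1, self.y2, self.y3)))


def _screen(dataset: DTIDataset, cfg: RunConfig):
    if not cfg.screen:
        return ScoreMatrix(dataset.Y.copy(), SourceTag.SIM), []
    if cfg.screen_top_k is not None:
        return fusion.similarity_screen(dataset, theta_sim=None,
                                        top_k=cfg.screen_top_k)
    return fusion.similarity_screen(dataset, theta_sim=cfg.theta_sim)


def compute_sources(dataset: DTIDataset, cfg: RunConfig) -> PipelineResult:
    """Steps 1-3: the three revised score matrices.

    Screening-selected pairs are added to the positives before the walk and
    the WNN-GIP fit, so Y_2 and Y_3 are computed on the revised training
    matrix Y_1.
    """
    y1, screen_added = _screen(dataset, cfg)
    revised = dataset.with_interactions(y1.values.astype(np.int8))
    y2 = rwr.rwr_score(revised, restart_c=cfg.restart_c, eta=cfg.eta,
                       jump_lambda=cfg.jump_lambda, tol=cfg.rwr_tol,
                       max_iter=cfg.rwr_max_iter)
    y3 = wnn_gip_score(revised, cfg)
    return PipelineResult(
        y1=y1, y2=y2, y3=y3,
        weights=np.full(3, 1.0 / 3.0),
        y_final=y1, revised_Y=dataset.Y.copy(),
        screen_added=screen_added,
    )


def _source_fns(cfg: RunConfig) -> dict[str, "callable"]:
    """Per-source scoring closures for inner-CV performance weighting."""

    def sim_fn(ds: DTIDataset) -> np.ndarray:
        y1, _ = _screen(ds, cfg)
        return y1.values.astype(float)

    def rs_fn(ds: DTIDataset) -> np.ndarray:
        y1, _ = _screen(ds, cfg)
        rev = ds.with_interactions(y1.values.astype(np.int8))
        return rwr.rwr_score(rev, restart_c=cfg.restart_c, eta=cfg.eta,
                             jump_lambda=cfg.jump_lambda, tol=cfg.rwr_tol,
                             max_iter=cfg.rwr_max_iter).values

    def ws_fn(ds: DTIDataset) -> np.ndarray:
        y1, _ = _screen(ds, cfg)
        rev = ds.with_interactions(y1.values.astype(np.int8))
        return wnn_gip_score(rev, cfg).values

    return {"sim": sim_fn, "rs": rs_fn, "ws": ws_fn}


def fuse_sources(dataset: DTIDataset, result: PipelineResult,
                 cfg: RunConfig) -> PipelineResult:
    """Step 4: fusion weights and Y_final."""
    mats = [result.y1.values.astype(float), result.y2.values, result.y3.values]
    if cfg.fusion_mode == "vote":
        result.weights = np.full(3, 1.0 / 3.0)
        result.y_final = fusion.vote_fuse(mats, cfg.vote_fraction)
        return result
    if cfg.fusion_mode == "ave":
        w = np.full(3, 1.0 / 3.0)
    elif cfg.fusion_mode == "fixed":
        w = fusion.check_weights(cfg.fusion_weights, 3)
    else:  # weighted
        w = fusion.performance_weights(dataset, _source_fns(cfg),
                                       inner_folds=cfg.inner_folds,
                                       seed=cfg.seed)
    result.weights = w
    result.y_final = fusion.weighted_fuse(mats, w)
    return result


def predict_pipeline(dataset: DTIDataset, cfg: RunConfig | None = None) -> PipelineResult:
    """Run the full chain and return all intermediates plus final scores."""
    cfg = cfg or RunConfig()
    result = compute_sources(dataset, cfg)
    result = fuse_sources(dataset, result, cfg)

    revised, revision_added = fusion.revise_training_matrix(
        dataset.Y, result.y_final, cfg.select_fraction)
    result.revision_added = revision_added

    if cfg.binarize_revision:
        train = revised.astype(float)
    else:
        # continuous path: known positives clamped to 1 over the fused scores
        train = np.maximum(result.y_final.values, dataset.Y.astype(float))
    result.revised_Y = revised

    train_ds = dataset.with_interactions(revised)
    profiles = complete_profiles(train_ds, cfg)
    K_d, K_t = combined_kernels(train_ds, cfg, profiles)
    result.scores = blm_score(train, K_d, K_t, sigma=cfg.blm_sigma,
                              nii_beta=cfg.nii_beta,
                              combine_rule=cfg.combine_rule)
    return result


def single_source_config(cfg: RunConfig, source: str) -> RunConfig:
    """A config whose fusion collapses onto one source (the SIM/RS/WS
    ablation axes): fixed one-hot weights, everything else unchanged."""
    if source not in SOURCE_NAMES:
        raise ValueError(f"unknown source {source!r}; expected one of {SOURCE_NAMES}")
    onehot = tuple(1.0 if s == source else 0.0 for s in SOURCE_NAMES)
    return cfg.replace(fusion_mode="fixed", fusion_weights=onehot)
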