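"""Run configuration: every tunable of the fusion pipeline in one place.

Defaults are the package's standard operating point; each field documents its
admissible range.  Configs round-trip through YAML and every CLI flag
overrides the corresponding field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class RunConfig:
    # kernel combination (convex weights between measured similarity and GIP)
    alpha_d: float = 0.5          # [0, 1] weight of chemical similarity in K_d
    alpha_t: float = 0.5          # [0, 1] weight of sequence similarity in K_t
    gamma_scale: float = 1.0      # > 0, GIP bandwidth multiplier

    # WNN-GIP
    sigma: float = 1.0            # >= 0, Kronecker RLS regularization
    wnn_decay: float = 0.7        # (0, 1], rank-decay T of WNN weights
    wnn_weighting: str = "rank"   # {rank, similarity}
    wnn_targets: bool = False     # also complete all-zero target columns
    wnn_clip: bool = True         # cap inferred profiles at 1

    # random walk with restart
    restart_c: float = 0.7        # (0, 1] restart probability
    eta: float = 0.5              # (0, 1) drug-vs-target seed mass split
    jump_lambda: float = 0.5      # [0, 1] inter-network transition mass
    rwr_tol: float = 1e-10        # stopping threshold on ||p_{t+1} - p_t||
    rwr_max_iter: int = 10_000

    # similarity screening
    screen: bool = True
    theta_sim: float = 0.7        # [0, 1] similarity threshold
    screen_top_k: int | None = None  # alternative: top-k most similar drug pairs

    # fusion
    fusion_mode: str = "weighted"    # {weighted, ave, vote, fixed}
    fusion_weights: tuple[float, float, float] | None = None  # for mode=fixed
    inner_folds: int = 3             # inner CV folds for performance weights
    vote_fraction: float = 0.01      # per-source binarization fraction for VOTE

    # training-matrix revision and final predictor
    select_fraction: float = 0.01    # top fraction of unlabeled pairs promoted
    binarize_revision: bool = True   # BLM-NII consumes binary revised Y (else Y_final)
    blm_sigma: float = 1.0           # local RLS regularization
    nii_beta: float = 1.0            # [0, 1] weight of inferred profiles
    combine_rule: str = "max"        # {max, mean}

    # evaluation
    n_folds: int = 10
    top_fraction: float = 0.01       # top-1% thresholding of ranked predictions
    cv_granularity: str = "pair"     # {pair, drug, target}
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def in_range(name, lo, hi, lo_open=False, hi_open=False):
            v = getattr(self, name)
            ok = (v > lo if lo_open else v >= lo) and (v < hi if hi_open else v <= hi)
            if not ok:
                raise ValueError(f"{name}={v} outside its admissible range")

        in_range("alpha_d", 0, 1)
        in_range("alpha_t", 0, 1)
        if self.gamma_scale <= 0:
            raise ValueError("gamma_scale must be positive")
        if self.sigma < 0 or self.blm_sigma < 0:
            raise ValueError("RLS regularization must be nonnegative")
        in_range("wnn_decay", 0, 1, lo_open=True)
        in_range("restart_c", 0, 1, lo_open=True)
        in_range("eta", 0, 1, lo_open=True, hi_open=True)
        in_range("jump_lambda", 0, 1)
        in_range("theta_sim", 0, 1)
        in_range("nii_beta", 0, 1)
        in_range("select_fraction", 0, 1)
        in_range("vote_fraction", 0, 1, lo_open=True)
        in_range("top_fraction", 0, 1, lo_open=True)
        if self.rwr_tol <= 0:
            raise ValueError("rwr_tol must be positive")
        if self.fusion_mode not in ("weighted", "ave", "vote", "fixed"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.fusion_mode == "fixed" and self.fusion_weights is None:
            raise ValueError("fusion_mode='fixed' requires fusion_weights")
        if self.wnn_weighting not in ("rank", "similarity"):
            raise ValueError(f"unknown wnn_weighting {self.wnn_weighting!r}")
        if self.combine_rule not in ("max", "mean"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")
        if self.cv_granularity not in ("pair", "drug", "target"):
            raise ValueError(f"unknown cv_granularity {self.cv_granularity!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be at least 2")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["fusion_weights"] is not None:
            d["fusion_weights"] = list(d["fusion_weights"])
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if d.get("fusion_weights") is not None:
            d = dict(d)
            d["fusion_weights"] = tuple(d["fusion_weights"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
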