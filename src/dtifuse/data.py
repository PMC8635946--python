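"""Core dataset container and labeled matrix text I/O.

A DTI dataset is the triplet ``(S_d, S_t, Y)``: a drug-drug chemical
similarity matrix, a target-target sequence similarity matrix, and a binary
drug-target interaction matrix, with aligned identifier lists.  Files follow
the Yamanishi gold-standard flat-file style: tab-separated, one header row of
column labels and one leading column of row labels.
"""

from __future__ import annotations

import enum
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8


class ValidationError(ValueError):
    """A dataset matrix violates its structural invariants."""


class AlignmentError(ValueError):
    """Identifier sets of the three matrices cannot be reconciled."""


class SourceTag(enum.Enum):
    """Provenance of a score matrix within the fusion pipeline."""

    SIM = "sim"      # drug-similarity screening (Y_1)
    RS = "rs"        # random walk with restart (Y_2)
    WS = "ws"        # WNN-GIP (Y_3)
    FUSED = "fused"  # weighted fusion (Y_final)
    BLM = "blm"      # BLM-NII final scores


@dataclass
class ScoreMatrix:
    """Real-valued drug x target prediction/revision matrix."""

    values: np.ndarray
    source_tag: SourceTag

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("score matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("score matrix contains non-finite values")


def _check_similarity(S: np.ndarray, name: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError(f"{name} must be square, got shape {S.shape}")
    asym = np.max(np.abs(S - S.T)) if S.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValidationError(
            f"{name} asymmetric beyond tolerance: max |S - S^T| = {asym:g}"
        )
    if asym > 0:
        log.warning("%s asymmetric by %g; symmetrizing as (S + S^T)/2", name, asym)
        S = (S + S.T) / 2.0
    if S.size and (S.min() < -1e-12 or S.max() > 1.0 + 1e-12):
        raise ValidationError(f"{name} entries must lie in [0, 1]")
    if S.size and np.max(np.abs(np.diag(S) - 1.0)) > 1e-8:
        raise ValidationError(f"{name} diagonal must equal 1")
    return np.clip(S, 0.0, 1.0)


@dataclass
class DTIDataset:
    """The (S_d, S_t, Y) triplet with aligned drug/target identifiers.

    Drugs are rows of ``Y`` everywhere internally; ``S_d`` is n x n over
    drugs, ``S_t`` is m x m over targets.
    """

    drug_ids: list[str]
    target_ids: list[str]
    Y: np.ndarray
    S_d: np.ndarray
    S_t: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.target_ids = [str(t) for t in self.target_ids]
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValidationError("duplicate drug identifiers")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValidationError("duplicate target identifiers")
        Y = np.asarray(self.Y)
        n, m = len(self.drug_ids), len(self.target_ids)
        if Y.shape != (n, m):
            raise ValidationError(
                f"interaction matrix shape {Y.shape} does not match "
                f"{n} drugs x {m} targets"
            )
        if Y.size and not np.isin(Y, (0, 1)).all():
            raise ValidationError("interaction matrix entries must be 0 or 1")
        self.Y = Y.astype(np.int8)
        self.S_d = _check_similarity(self.S_d, "drug similarity matrix")
        self.S_t = _check_similarity(self.S_t, "target similarity matrix")
        if self.S_d.shape[0] != n:
            raise ValidationError("drug similarity matrix does not match drug count")
        if self.S_t.shape[0] != m:
            raise ValidationError("target similarity matrix does not match target count")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def m_targets(self) -> int:
        return len(self.target_ids)

    def with_interactions(self, Y: np.ndarray) -> "DTIDataset":
        """A copy of this dataset with a replacement interaction matrix."""
        return DTIDataset(
            list(self.drug_ids), list(self.target_ids),
            np.asarray(Y), self.S_d.copy(), self.S_t.copy(),
        )


@dataclass
class DatasetStats:
    n_drugs: int
    m_targets: int
    n_interactions: int
    n_unknown: int


def dataset_stats(dataset: DTIDataset) -> DatasetStats:
    """Summary counts: drugs, targets, known interactions, unknown pairs."""
    known = int(dataset.Y.sum())
    total = dataset.n_drugs * dataset.m_targets
    return DatasetStats(dataset.n_drugs, dataset.m_targets, known, total - known)


# ---------------------------------------------------------------------------
# Labeled tab-separated matrix files


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read one labeled tab-separated matrix.

    Tolerates both presence and absence of a corner cell above the row-label
    column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df.astype(float)


def write_matrix(values: np.ndarray, row_ids, col_ids, path: str | os.PathLike) -> None:
    """Write one labeled tab-separated matrix at full precision."""
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep="\t", float_format="%.17g")


def _align_report(kind: str, have: set[str], want: set[str]) -> str:
    missing = sorted(want - have)
    extra = sorted(have - want)
    parts = [f"{kind} identifier mismatch between interaction and similarity files"]
    if missing:
        parts.append(f"missing from interaction file: {missing[:10]}")
    if extra:
        parts.append(f"only in interaction file: {extra[:10]}")
    return "; ".join(parts)


def read_dataset(
    interaction_path: str | os.PathLike,
    drug_sim_path: str | os.PathLike,
    target_sim_path: str | os.PathLike,
    drugs_are_rows: bool = True,
) -> DTIDataset:
    """Read and align the three matrices of a DTI dataset.

    Drug order is taken from the drug-similarity file and target order from
    the target-similarity file; the interaction matrix is reordered to match.
    ``drugs_are_rows`` states the orientation of the interaction file (hosted
    files vary); internally drugs are always rows.
    """
    inter = read_matrix(interaction_path)
    if not drugs_are_rows:
        inter = inter.T
    sd = read_matrix(drug_sim_path)
    st = read_matrix(target_sim_path)

    drug_ids = [str(d) for d in sd.index]
    target_ids = [str(t) for t in st.index]
    if set(inter.index) != set(drug_ids):
        raise AlignmentError(_align_report("drug", set(inter.index), set(drug_ids)))
    if set(inter.columns) != set(target_ids):
        raise AlignmentError(_align_report("target", set(inter.columns), set(target_ids)))

    Y = inter.loc[drug_ids, target_ids].to_numpy()
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValidationError(f"non-binary entries in {interaction_path}")
    sd = sd.loc[drug_ids, drug_ids]
    st = st.loc[target_ids, target_ids]
    return DTIDataset(drug_ids, target_ids, Y, sd.to_numpy(), st.to_numpy())


INTERACTION_FILE = "interactions.tsv"
DRUG_SIM_FILE = "drug_similarity.tsv"
TARGET_SIM_FILE = "target_similarity.tsv"


def write_dataset(dataset: DTIDataset, directory: str | os.PathLike) -> dict[str, str]:
    """Write the dataset as three labeled tab-separated files.

    Returns a mapping from role ("interactions", "drug_similarity",
    "target_similarity") to the written path.
    """
    if dataset.n_drugs == 0 or dataset.m_targets == 0:
        raise ValidationError("refusing to write a dataset with an empty axis")
    os.makedirs(directory, exist_ok=True)
    paths = {
        "interactions": os.path.join(directory, INTERACTION_FILE),
        "drug_similarity": os.path.join(directory, DRUG_SIM_FILE),
        "target_similarity": os.path.join(directory, TARGET_SIM_FILE),
    }
    write_matrix(dataset.Y.astype(int), dataset.drug_ids, dataset.target_ids,
                 paths["interactions"])
    write_matrix(dataset.S_d, dataset.drug_ids, dataset.drug_ids,
                 paths["drug_similarity"])
    write_matrix(dataset.S_t, dataset.target_ids, dataset.target_ids,
                 paths["target_similarity"])
    return paths


def read_dataset_dir(directory: str | os.PathLike) -> DTIDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    return read_dataset(
        os.path.join(directory, INTERACTION_FILE),
        os.path.join(directory, DRUG_SIM_FILE),
        os.path.join(directory, TARGET_SIM_FILE),
    )
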