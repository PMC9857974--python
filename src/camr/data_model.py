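"""Core domain types, feature-table I/O and preprocessing transforms.

A cohort couples three per-patient feature blocks — histopathology-image
features (``P``), gene expression (``G``) and copy-number alteration (``C``)
— with right-censored survival labels. Feature tables are delimited text
(patients as rows, first column the patient id); preprocessing covers
z-score standardization and trichotomization of expression values into
over- / baseline / under-expression calls.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

MODALITIES = ("P", "G", "C")


@dataclasses.dataclass
class ModalityBlock:
    """One modality's feature matrix (patients x features)."""

    modality_tag: str
    features: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.modality_tag not in MODALITIES:
            raise ValueError(f"unknown modality tag {self.modality_tag!r}; expected one of {MODALITIES}")
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix (patients x features)")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match feature count")
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"modality {self.modality_tag}: non-finite feature values")

    @property
    def n_patients(self) -> int:
        return self.features.shape[0]

    @property
    def feature_count(self) -> int:
        return self.features.shape[1]


@dataclasses.dataclass
class SurvivalLabels:
    """Right-censored survival outcomes, aligned to cohort row order."""

    time: np.ndarray
    event: np.ndarray
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.event = np.asarray(self.event, dtype=np.int64)
        if not (len(self.time) == len(self.event) == len(self.patient_ids)):
            raise ValueError("time, event and patient_ids must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be strictly positive")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValueError("event indicators must be 0 (censored) or 1 (event)")

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, idx: np.ndarray) -> "SurvivalLabels":
        return SurvivalLabels(self.time[idx], self.event[idx],
                              [self.patient_ids[i] for i in np.atleast_1d(idx)])


@dataclasses.dataclass
class MultimodalCohort:
    """Aligned feature blocks for the three modalities plus survival labels."""

    blocks: Mapping[str, ModalityBlock]
    labels: SurvivalLabels

    def __post_init__(self) -> None:
        if set(self.blocks) != set(MODALITIES):
            raise ValueError(f"cohort requires blocks for modalities {MODALITIES}")
        n = len(self.labels)
        for tag, block in self.blocks.items():
            if block.n_patients != n:
                raise ValueError(f"block {tag} has {block.n_patients} rows but labels have {n}")
        if len(set(self.labels.patient_ids)) != n:
            raise ValueError("patient_ids must be unique")

    @property
    def n_patients(self) -> int:
        return len(self.labels)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {pid: i for i, pid in enumerate(self.labels.patient_ids)}
        return np.array([lookup[p] for p in ids], dtype=np.intp)


@dataclasses.dataclass
class FoldSplit:
    """One round of 5-fold cross-validation: disjoint train/val/test ids."""

    fold_index: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/val/test id lists must be pairwise disjoint")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


# --------------------------------------------------------------------- I/O


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")
    df = df.set_index(df.columns[0])
    return df


def load_cohort(feature_paths: Mapping[str, str | Path],
                label_path: str | Path) -> MultimodalCohort:
    """Load three feature tables and a label table into an aligned cohort.

    Rows are canonicalized to sorted patient-id order so that files with
    shuffled rows yield identical cohorts. All four files must cover the
    same patient set.
    """
    if set(feature_paths) != set(MODALITIES):
        raise ValueError(f"feature_paths must provide exactly the modalities {MODALITIES}")
    tables = {tag: _read_table(p) for tag, p in feature_paths.items()}
    label_df = _read_table(label_path)

    id_sets = {tag: set(df.index) for tag, df in tables.items()}
    id_sets["labels"] = set(label_df.index)
    reference = id_sets["labels"]
    for name, ids in id_sets.items():
        diff = ids ^ reference
        if diff:
            raise ValueError(
                f"patient sets differ between {name!r} and the label table; "
                f"symmetric difference: {sorted(diff)}"
            )
    order = sorted(reference)

    blocks = {}
    for tag, df in tables.items():
        df = df.loc[order]
        numeric = df.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            r, c = next(zip(*np.where(numeric.isna().to_numpy())))
            raise ValueError(
                f"non-numeric or missing value in modality {tag} at "
                f"patient {df.index[r]!r}, column {df.columns[c]!r}"
            )
        blocks[tag] = ModalityBlock(tag, numeric.to_numpy(float), list(df.columns))

    label_df = label_df.loc[order]
    for col in ("time", "event"):
        if col not in label_df.columns:
            raise ValueError(f"label table must have a {col!r} column")
    labels = SurvivalLabels(label_df["time"].to_numpy(float),
                            label_df["event"].to_numpy(),
                            list(order))
    return MultimodalCohort(blocks, labels)


def write_cohort(cohort: MultimodalCohort, out_dir: str | Path,
                 fmt: str = "csv") -> dict[str, Path]:
    """Write a cohort back to the delimited-text layout `load_cohort` reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sep = "\t" if fmt == "tsv" else ","
    paths: dict[str, Path] = {}
    for tag, block in cohort.blocks.items():
        df = pd.DataFrame(block.features, index=cohort.labels.patient_ids,
                          columns=block.feature_names)
        df.index.name = "id"
        p = out_dir / f"features_{tag}.{fmt}"
        df.to_csv(p, sep=sep, float_format="%.17g")
        paths[tag] = p
    lab = pd.DataFrame({"time": cohort.labels.time, "event": cohort.labels.event},
                       index=cohort.labels.patient_ids)
    lab.index.name = "id"
    p = out_dir / f"labels.{fmt}"
    lab.to_csv(p, sep=sep, float_format="%.17g")
    paths["labels"] = p
    return paths


# ------------------------------------------------------------ preprocessing


def zscore_normalize(block: ModalityBlock, ddof: int = 0) -> ModalityBlock:
    """Standardize each feature column to mean 0, sd 1 (population divisor).

    Constant columns (zero variance) become all-zero rather than dividing
    by zero.
    """
    if block.n_patients == 0 or block.feature_count == 0:
        raise ValueError("cannot normalize an empty block")
    x = block.features
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    out = np.zeros_like(x)
    # relative tolerance: fp noise makes a constant column's sd ~1e-16*|mu|
    nz = sd > 1e-12 * np.maximum(np.abs(mu), 1.0)
    out[:, nz] = (x[:, nz] - mu[nz]) / sd[nz]
    return ModalityBlock(block.modality_tag, out, list(block.feature_names))


def trichotomize(block: ModalityBlock, threshold: float = 1.0) -> ModalityBlock:
    """Map standardized values to calls: 1 (> threshold), -1 (< -threshold), else 0.

    The boundary is strict: a value exactly at +/- threshold maps to 0.
    """
    if threshold <= 0:
        raise ValueError("trichotomization threshold must be > 0")
    x = block.features
    out = np.where(x > threshold, 1.0, np.where(x < -threshold, -1.0, 0.0))
    return ModalityBlock(block.modality_tag, out, list(block.feature_names))


def preprocess_cohort(cohort: MultimodalCohort,
                      trichotomize_tags: Sequence[str] = (),
                      threshold: float = 1.0) -> MultimodalCohort:
    """Standard preprocessing: z-score every block, then trichotomize the
    blocks named in `trichotomize_tags` (typically gene expression)."""
    blocks = {}
    for tag, block in cohort.blocks.items():
        zb = zscore_normalize(block)
        blocks[tag] = trichotomize(zb, threshold) if tag in trichotomize_tags else zb
    return MultimodalCohort(blocks, cohort.labels)


def make_fold_splits(cohort: MultimodalCohort, seed: int) -> list[FoldSplit]:
    """Seeded 5-fold split; within each round, 20% of non-test patients are validation.

    Test sets partition the cohort across the five folds.
    """
    n = cohort.n_patients
    if n < 10:
        raise ValueError(f"need at least 10 patients for 5-fold splits, got {n}")
    ids = np.array(cohort.labels.patient_ids)
    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    splits = []
    for k, (rest_idx, test_idx) in enumerate(kf.split(ids)):
        rng = np.random.default_rng(seed * 1000 + k)
        rest = rng.permutation(rest_idx)
        n_val = int(round(0.2 * len(rest)))
        val_idx, train_idx = rest[:n_val], rest[n_val:]
        splits.append(FoldSplit(
            fold_index=k,
            train_ids=sorted(ids[train_idx].tolist()),
            val_ids=sorted(ids[val_idx].tolist()),
            test_ids=sorted(ids[test_idx].tolist()),
        ))
    return splits
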