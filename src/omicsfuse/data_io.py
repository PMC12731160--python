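"""Labeled multi-omics dataset containers and their CSV layout.

A dataset is a directory of per-omics feature tables plus one label file::

    <name>/mrna.csv      # rows = samples, columns = features
    <name>/meth.csv
    <name>/mirna.csv
    <name>/labels.csv    # columns: sample_id, label

Every table is comma-separated UTF-8 with a mandatory header row whose first
column is ``sample_id``.  Matrices must be complete: a NaN or non-numeric cell
is an error, not something to impute.  Class names are mapped to indices
lexicographically so the encoding never depends on file row order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InputError, ValidationError

SAMPLE_COL = "sample_id"


@dataclass
class OmicsMatrix:
    """One omics layer: an N x d real matrix with sample and feature IDs."""

    omics_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n, d = self.values.shape
        if n < 2:
            raise ValidationError(f"omics '{self.omics_name}': need at least 2 samples, got {n}")
        if len(self.sample_ids) != n or len(self.feature_ids) != d:
            raise ValidationError(f"omics '{self.omics_name}': ID/shape mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValidationError(f"omics '{self.omics_name}': duplicate sample IDs")
        if len(set(self.feature_ids)) != d:
            raise ValidationError(f"omics '{self.omics_name}': duplicate feature IDs")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"omics '{self.omics_name}': non-finite value at sample "
                f"'{self.sample_ids[i]}', feature '{self.feature_ids[j]}'"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def reordered(self, sample_ids: list[str]) -> "OmicsMatrix":
        """Return a copy with rows in the given sample order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise AlignmentError(
                f"omics '{self.omics_name}': samples missing: {missing}"
            )
        idx = [pos[s] for s in sample_ids]
        return OmicsMatrix(self.omics_name, list(sample_ids),
                           list(self.feature_ids), self.values[idx])


@dataclass
class LabelVector:
    """Integer class labels (0..Q-1) per sample plus the class-name table."""

    sample_ids: list[str]
    y: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int64)
        q = len(self.class_names)
        if q < 2:
            raise ValidationError(f"need at least 2 classes, got {q}")
        if len(self.y) != len(self.sample_ids):
            raise ValidationError("label/sample count mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs in labels")
        present = set(np.unique(self.y))
        if present != set(range(q)):
            raise ValidationError(
                f"classes {sorted(set(range(q)) - present)} have no samples"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class MultiOmicsDataset:
    """M aligned omics layers sharing one sample ordering, plus labels."""

    omics: list[OmicsMatrix]
    labels: LabelVector

    def __post_init__(self):
        if not self.omics:
            raise ValidationError("need at least one omics layer")
        ref = self.labels.sample_ids
        for om in self.omics:
            if om.sample_ids != ref:
                raise AlignmentError(
                    f"omics '{om.omics_name}' sample order differs from labels"
                )

    @property
    def n_samples(self) -> int:
        return len(self.labels.sample_ids)

    @property
    def n_omics(self) -> int:
        return len(self.omics)

    def subset_omics(self, names: list[str]) -> "MultiOmicsDataset":
        """Dataset restricted to the named omics layers (order preserved)."""
        keep = [om for om in self.omics if om.omics_name in set(names)]
        if len(keep) != len(names):
            have = {om.omics_name for om in self.omics}
            raise ValidationError(f"unknown omics: {sorted(set(names) - have)}")
        return MultiOmicsDataset(keep, self.labels)


def read_omics_csv(path: str, omics_name: str) -> OmicsMatrix:
    """Read one omics feature table; validates IDs and finiteness."""
    if not os.path.exists(path):
        raise InputError(f"omics file not found: {path}")
    df = pd.read_csv(path, index_col=0, dtype={0: str})
    raw = df.to_numpy()
    if raw.dtype == object or not np.issubdtype(raw.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at row '{df.index[i]}', column '{df.columns[j]}'"
        )
    if np.isnan(raw).any():
        i, j = np.argwhere(np.isnan(raw))[0]
        raise ValidationError(
            f"{path}: missing value at row '{df.index[i]}', column '{df.columns[j]}'"
        )
    return OmicsMatrix(omics_name, [str(s) for s in df.index],
                       [str(c) for c in df.columns], raw.astype(np.float64))


def write_omics_csv(matrix: OmicsMatrix, path: str) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.feature_ids)
    df.index.name = SAMPLE_COL
    df.to_csv(path, float_format="%.17g")


def read_labels_csv(path: str) -> LabelVector:
    """Read (sample_id, label) pairs; class names map to indices lexicographically."""
    if not os.path.exists(path):
        raise InputError(f"label file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected two columns, got {df.shape[1]}")
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    raw_labels = [str(v) for v in df.iloc[:, 1]]
    class_names = sorted(set(raw_labels))
    index = {c: i for i, c in enumerate(class_names)}
    y = np.array([index[v] for v in raw_labels], dtype=np.int64)
    return LabelVector(sample_ids, y, class_names)


def write_labels_csv(labels: LabelVector, path: str) -> None:
    df = pd.DataFrame({
        SAMPLE_COL: labels.sample_ids,
        "label": [labels.class_names[q] for q in labels.y],
    })
    df.to_csv(path, index=False)


def assemble_dataset(matrices: list[OmicsMatrix], labels: LabelVector) -> MultiOmicsDataset:
    """Align every omics layer to the label sample order.

    Each matrix must cover exactly the labeled sample set (any row order);
    the result carries all layers in the labels' order.  Idempotent.
    """
    label_set = set(labels.sample_ids)
    aligned = []
    for m in matrices:
        extra = sorted(set(m.sample_ids) - label_set)
        if extra:
            raise AlignmentError(f"omics '{m.omics_name}': unlabeled samples: {extra}")
        aligned.append(m.reordered(labels.sample_ids))
    return MultiOmicsDataset(aligned, labels)


def load_dataset_dir(path: str) -> MultiOmicsDataset:
    """Load ``<path>/<omics>.csv`` layers plus ``<path>/labels.csv``."""
    if not os.path.isdir(path):
        raise InputError(f"dataset directory not found: {path}")
    labels = read_labels_csv(os.path.join(path, "labels.csv"))
    matrices = []
    for fname in sorted(os.listdir(path)):
        if not fname.endswith(".csv") or fname == "labels.csv":
            continue
        name = fname[:-4]
        matrices.append(read_omics_csv(os.path.join(path, fname), name))
    if not matrices:
        raise InputError(f"no omics tables found in {path}")
    return assemble_dataset(matrices, labels)


def write_dataset_dir(dataset: MultiOmicsDataset, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    for om in dataset.omics:
        write_omics_csv(om, os.path.join(path, f"{om.omics_name}.csv"))
    write_labels_csv(dataset.labels, os.path.join(path, "labels.csv"))
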