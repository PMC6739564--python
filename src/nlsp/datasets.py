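"""Multilabel dataset container and delimited-text I/O.

The central object is :class:`MultiLabelDataset`: a real-valued feature
matrix (samples x features) paired with a binary label matrix (samples x
labels).  In the ATC drug-classification setting the features are 42
similarity scores (three 14-wide blocks: maximum chemical-chemical
interaction, structural similarity and fingerprint similarity toward the
drugs of each of the 14 top-level ATC classes) and the labels are the 14
ATC classes, of which every drug carries at least one.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 14 top-level ATC class codes, used as default label names when M=14.
ATC_CLASSES: tuple[str, ...] = (
    "A", "B", "C", "D", "G", "H", "J", "L", "M", "N", "P", "R", "S", "V",
)

#: Prefix marking label columns in the single-file dataset variant.
LABEL_PREFIX = "label:"


@dataclass
class MultiLabelDataset:
    """Feature matrix + binary label matrix + names.

    Parameters
    ----------
    features : ndarray of shape (N, d)
        Real-valued features (unitless similarity scores in the drug
        instance).
    labels : ndarray of shape (N, M)
        Binary label assignments; every row should have at least one 1.
    label_names, sample_ids, feature_names : sequences of str
    """

    features: np.ndarray
    labels: np.ndarray
    label_names: list[str]
    sample_ids: list[str]
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features.reshape(len(self.features), 0)
        self.labels = np.asarray(self.labels)
        self.label_names = [str(x) for x in self.label_names]
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.feature_names = [str(x) for x in self.feature_names]
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.features.shape[1])]

    # -- basic dimensions -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def label_sets(self) -> list[frozenset]:
        """Per-sample label sets L_k (as frozensets of label names)."""
        names = np.asarray(self.label_names, dtype=object)
        return [frozenset(names[row.astype(bool)]) for row in self.labels]

    def __eq__(self, other) -> bool:  # field-identical comparison
        if not isinstance(other, MultiLabelDataset):
            return NotImplemented
        return (
            self.features.shape == other.features.shape
            and np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
            and self.label_names == other.label_names
            and self.sample_ids == other.sample_ids
            and self.feature_names == other.feature_names
        )


def default_label_names(m: int) -> list[str]:
    """ATC top-level codes when m=14, generic names otherwise."""
    if m == len(ATC_CLASSES):
        return list(ATC_CLASSES)
    return [f"L{i}" for i in range(m)]


def validate_dataset(
    dataset: MultiLabelDataset, allow_zero_label_rows: bool = False
) -> list[str]:
    """Check dataset invariants; return a list of human-readable violations.

    Deterministic and side-effect free: it never raises and never mutates
    the dataset.  With ``allow_zero_label_rows`` set, rows without any
    label produce warnings instead of violations (useful for
    prediction-time inputs whose labels are unknown).
    """
    v: list[str] = []
    X, Y = dataset.features, dataset.labels
    if Y.ndim != 2:
        return [f"labels must be 2-dimensional, got ndim={Y.ndim}"]
    n, m = Y.shape
    if X.shape[0] != n:
        v.append(f"feature rows ({X.shape[0]}) != label rows ({n})")
    if len(dataset.sample_ids) != n:
        v.append(f"{len(dataset.sample_ids)} sample_ids for {n} rows")
    if len(dataset.label_names) != m:
        v.append(f"{len(dataset.label_names)} label_names for {m} label columns")
    if len(dataset.feature_names) != X.shape[1]:
        v.append(
            f"{len(dataset.feature_names)} feature_names for {X.shape[1]} columns"
        )
    if len(set(dataset.label_names)) != len(dataset.label_names):
        dupes = sorted(
            {x for x in dataset.label_names if dataset.label_names.count(x) > 1}
        )
        v.append(f"duplicate label names: {dupes}")
    if len(set(dataset.sample_ids)) != len(dataset.sample_ids):
        v.append("duplicate sample ids")
    if np.issubdtype(X.dtype, np.floating) and not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))[:5]
        v.append(f"non-finite feature values at (row, col) {bad.tolist()}")
    vals = np.unique(Y[~pd.isna(Y)]) if Y.dtype == object else np.unique(Y)
    if pd.isna(Y).any():
        v.append("missing values in labels")
    elif not np.isin(vals, (0, 1)).all():
        bad = sorted(set(vals) - {0, 1})
        v.append(f"non-binary label values: {bad}")
    else:
        zero_rows = np.flatnonzero(Y.sum(axis=1) == 0)
        for i in zero_rows:
            sid = dataset.sample_ids[i] if i < len(dataset.sample_ids) else i
            msg = f"sample {sid!r} (row {i}) has no label"
            if allow_zero_label_rows:
                warnings.warn(msg, stacklevel=2)
            else:
                v.append(msg)
    return v


def _require_valid(dataset: MultiLabelDataset, allow_zero_label_rows: bool) -> None:
    violations = validate_dataset(dataset, allow_zero_label_rows)
    if violations:
        raise ValueError("invalid dataset:\n  " + "\n  ".join(violations))


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    # round_trip float parsing preserves every bit written by %.17g
    return pd.read_csv(
        path, sep=_sep_for(path), index_col=0, float_precision="round_trip"
    )


def _check_binary_frame(df: pd.DataFrame, path) -> None:
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary label value {arr[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )


def read_dataset(
    features_path: str | os.PathLike,
    labels_path: str | os.PathLike | None = None,
    allow_zero_label_rows: bool = False,
) -> MultiLabelDataset:
    """Read a dataset from delimited text files.

    Dialect is auto-detected from the extension (``.csv`` comma, otherwise
    tab).  The first column of each file is the sample identifier; the
    labels file is reordered to match the feature file's row order.  With
    ``labels_path=None`` a single-file variant is read in which label
    columns carry the ``label:`` prefix.
    """
    feat = _read_table(features_path)
    if labels_path is None:
        lab_cols = [c for c in feat.columns if str(c).startswith(LABEL_PREFIX)]
        if not lab_cols:
            raise ValueError(
                f"{features_path}: no '{LABEL_PREFIX}'-prefixed label columns"
            )
        lab = feat[lab_cols].rename(
            columns={c: str(c)[len(LABEL_PREFIX):] for c in lab_cols}
        )
        feat = feat.drop(columns=lab_cols)
    else:
        lab = _read_table(labels_path)
        missing = feat.index.difference(lab.index)
        extra = lab.index.difference(feat.index)
        if len(missing) or len(extra):
            raise ValueError(
                f"sample id mismatch between {features_path} and {labels_path}: "
                f"missing from labels {list(missing[:10])}, "
                f"only in labels {list(extra[:10])}"
            )
        lab = lab.loc[feat.index]
    if feat.shape[1] and feat.isna().any().any():
        r, c = next(zip(*np.where(feat.isna().to_numpy())))
        raise ValueError(
            f"{features_path}: missing value at row {feat.index[r]!r}, "
            f"column {feat.columns[c]!r}"
        )
    _check_binary_frame(lab, labels_path or features_path)
    ds = MultiLabelDataset(
        features=feat.to_numpy(dtype=float),
        labels=lab.to_numpy(dtype=np.int8),
        label_names=[str(c) for c in lab.columns],
        sample_ids=[str(i) for i in feat.index],
        feature_names=[str(c) for c in feat.columns],
    )
    _require_valid(ds, allow_zero_label_rows)
    return ds


def write_dataset(
    dataset: MultiLabelDataset,
    features_path: str | os.PathLike,
    labels_path: str | os.PathLike,
) -> None:
    """Write the dataset so that :func:`read_dataset` reproduces it exactly.

    Floats are written with ``repr`` (shortest round-trip) precision.
    """
    feat = pd.DataFrame(
        dataset.features, index=dataset.sample_ids, columns=dataset.feature_names
    )
    lab = pd.DataFrame(
        dataset.labels.astype(int),
        index=dataset.sample_ids,
        columns=dataset.label_names,
    )
    feat.index.name = "sample_id"
    lab.index.name = "sample_id"
    # %.17g round-trips any float64 exactly
    feat.to_csv(features_path, sep=_sep_for(features_path), float_format="%.17g")
    lab.to_csv(labels_path, sep=_sep_for(labels_path))
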