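"""The NLSP classifier: label-powerset models per label community.

Training: (1) build the label co-occurrence graph on the training
labels; (2) partition the label set into communities with a community
detector; (3) for each community, restrict the label columns to its
members and treat every distinct observed combination as one multiclass
class (label powerset); (4) fit one base predictor per community on the
full feature matrix.  Prediction is the union over communities of each
community model's decoded label combination: b(S) = U_i b_i(S).

The degenerate clusterers recover the classical problem
transformations: ``none`` (a single community of all labels) is plain
label powerset, ``singletons`` (one community per label) is binary
relevance.
"""

from __future__ import annotations

import io
import json
import os
import warnings
import zipfile
from dataclasses import dataclass

import joblib
import numpy as np

from .community import (
    CommunityPartition,
    async_label_propagation,
    louvain_partition,
)
from .datasets import MultiLabelDataset
from .label_space import build_cooccurrence_graph
from .learners import BaseLearnerSpec, make_base_learner

MODEL_FORMAT_VERSION = 1

CLUSTERERS = ("lpa", "louvain", "none", "singletons")


def label_powerset_encode(
    label_submatrix: np.ndarray,
) -> tuple[np.ndarray, dict[tuple[int, ...], int]]:
    """Map each distinct observed label combination to a class index.

    Class indices follow first-occurrence order, so the encoding is
    deterministic in the row order.  Returns the class vector and the
    bijection from bit patterns to indices.
    """
    Y = np.asarray(label_submatrix)
    if Y.ndim != 2 or Y.shape[1] < 1:
        raise ValueError("need an N x m binary matrix with m >= 1")
    table: dict[tuple[int, ...], int] = {}
    classes = np.empty(Y.shape[0], dtype=np.int64)
    for i, row in enumerate(Y):
        key = tuple(int(b) for b in row)
        if key not in table:
            table[key] = len(table)
        classes[i] = table[key]
    return classes, table


class _ConstantClassifier:
    """Predicts a single class with probability one (degenerate LP case,
    including the always-absent model for labels unseen in training)."""

    def __init__(self, cls: int = 0):
        self.classes_ = np.array([cls])

    def fit(self, X, y):  # pragma: no cover - nothing to learn
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.classes_[0])

    def predict_proba(self, X):
        return np.ones((np.asarray(X).shape[0], 1))


@dataclass
class LabelPowersetModel:
    """One community's label-powerset model.

    ``combination_table`` is the bijection between observed label
    combinations (bit patterns over ``community_labels``) and class
    indices; ``estimator`` is the fitted base predictor.
    """

    community_labels: tuple[str, ...]
    combination_table: dict[tuple[int, ...], int]
    estimator: object

    def __post_init__(self) -> None:
        self._inverse = {v: k for k, v in self.combination_table.items()}
        if len(self._inverse) != len(self.combination_table):
            raise ValueError("combination_table is not a bijection")

    def decode(self, class_index: int) -> tuple[int, ...]:
        return self._inverse[int(class_index)]

    def predict_sets(self, X: np.ndarray) -> list[frozenset]:
        classes = self.estimator.predict(X)
        out = []
        for c in classes:
            bits = self.decode(c)
            out.append(
                frozenset(l for l, b in zip(self.community_labels, bits) if b)
            )
        return out

    def label_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-label scores: sum of class probabilities over the classes
        whose combination contains the label.  Shape (Q, len(community))."""
        if not hasattr(self.estimator, "predict_proba"):
            raise TypeError(
                "base learner has no predict_proba; use a probability-capable "
                "family (ERT, RF, SVM, XGB, MLP)"
            )
        proba = np.asarray(self.estimator.predict_proba(X))
        classes = getattr(self.estimator, "classes_", np.arange(proba.shape[1]))
        scores = np.zeros((proba.shape[0], len(self.community_labels)))
        for col, c in enumerate(classes):
            bits = self.decode(int(c))
            for j, b in enumerate(bits):
                if b:
                    scores[:, j] += proba[:, col]
        return np.clip(scores, 0.0, 1.0)


@dataclass
class NLSPModel:
    """Fitted NLSP ensemble: a label partition plus one label-powerset
    model per community; prediction is the union over communities."""

    partition: CommunityPartition
    members: list[LabelPowersetModel]
    base_spec: BaseLearnerSpec
    label_names: tuple[str, ...]
    n_features: int
    clusterer: str = ""
    seed: int | None = None
    format_version: int = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        if len(self.members) != self.partition.k:
            raise ValueError("one member model per community required")
        covered = set().union(*map(set, self.partition.communities))
        if covered != set(self.label_names):
            raise ValueError("partition does not cover the label set")

    @property
    def k(self) -> int:
        return self.partition.k

    def predict(self, features: np.ndarray) -> list[frozenset]:
        return predict_nlsp(self, features)

    def scores(self, features: np.ndarray) -> np.ndarray:
        return label_scores(self, features)

    def save(self, path: str | os.PathLike) -> None:
        save_model(self, path)


def _partition_for(
    graph, labels: tuple[str, ...], clusterer: str, seed: int
) -> CommunityPartition:
    if clusterer == "none":
        return CommunityPartition([tuple(labels)], algorithm="none", seed=seed)
    if clusterer == "singletons":
        return CommunityPartition(
            [(l,) for l in labels], algorithm="singletons", seed=seed
        )
    if clusterer == "lpa":
        return async_label_propagation(graph, seed=seed)
    if clusterer == "louvain":
        return louvain_partition(graph, seed=seed)
    raise ValueError(f"unknown clusterer {clusterer!r}; choose one of {CLUSTERERS}")


def fit_nlsp(
    dataset: MultiLabelDataset,
    clusterer: str = "lpa",
    base_spec: BaseLearnerSpec | None = None,
    weighted_graph: bool = True,
    seed: int = 0,
) -> NLSPModel:
    """Fit the NLSP ensemble on a multilabel dataset.

    ``clusterer`` selects the label partition: ``lpa`` or ``louvain``
    (community detection on the co-occurrence graph), ``none`` (plain
    label powerset) or ``singletons`` (binary relevance).  ``seed``
    drives the clusterer; the base learners use ``base_spec.seed``.
    Labels with zero positive training samples are forced into singleton
    communities predicting always-absent (with a warning).
    """
    if base_spec is None:
        base_spec = BaseLearnerSpec("XGB", seed=seed)
    if clusterer not in CLUSTERERS:
        raise ValueError(
            f"unknown clusterer {clusterer!r}; choose one of {CLUSTERERS}"
        )
    Y = dataset.labels
    names = tuple(dataset.label_names)
    present = Y.sum(axis=0) > 0
    absent_labels = tuple(n for n, p in zip(names, present) if not p)
    if absent_labels:
        warnings.warn(
            f"labels with no positive training sample: {absent_labels}; "
            "forcing singleton always-absent models",
            stacklevel=2,
        )
    active = [n for n, p in zip(names, present) if p]
    sub = MultiLabelDataset(
        features=dataset.features,
        labels=Y[:, present],
        label_names=active,
        sample_ids=dataset.sample_ids,
        feature_names=dataset.feature_names,
    )
    graph = build_cooccurrence_graph(sub, weighted=weighted_graph)
    part = _partition_for(graph, tuple(active), clusterer, seed)
    communities = list(part.communities) + [(l,) for l in absent_labels]
    partition = CommunityPartition(
        communities, algorithm=part.algorithm, seed=seed
    )

    col = {n: i for i, n in enumerate(names)}
    factory = make_base_learner(base_spec, dataset.n_features)
    members: list[LabelPowersetModel] = []
    for comm in partition.communities:
        if set(comm) <= set(absent_labels):
            members.append(
                LabelPowersetModel(
                    community_labels=comm,
                    combination_table={(0,) * len(comm): 0},
                    estimator=_ConstantClassifier(0),
                )
            )
            continue
        Y_sub = Y[:, [col[l] for l in comm]]
        classes, table = label_powerset_encode(Y_sub)
        if len(table) == 1:
            est: object = _ConstantClassifier(0)
        else:
            est = factory()
            est.fit(dataset.features, classes)
        members.append(
            LabelPowersetModel(
                community_labels=comm, combination_table=table, estimator=est
            )
        )
    return NLSPModel(
        partition=partition,
        members=members,
        base_spec=base_spec,
        label_names=names,
        n_features=dataset.n_features,
        clusterer=clusterer,
        seed=seed,
    )


def _check_width(model: NLSPModel, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match the {model.n_features} training features"
        )
    return X


def predict_nlsp(model: NLSPModel, features: np.ndarray) -> list[frozenset]:
    """Predicted label set per sample: the union over communities of the
    decoded label combination each community model assigns (an empty
    union is permitted)."""
    X = _check_width(model, features)
    unions: list[set] = [set() for _ in range(X.shape[0])]
    for member in model.members:
        for i, s in enumerate(member.predict_sets(X)):
            unions[i] |= s
    return [frozenset(s) for s in unions]


def label_scores(model: NLSPModel, features: np.ndarray) -> np.ndarray:
    """Q x M matrix of per-label scores in [0, 1].

    A label's score within a community is the summed probability of the
    classes whose combination contains it; a label lying in several
    communities takes the maximum across them.  These scores feed
    label-wise ROC analysis and are deliberately independent of
    :func:`predict_nlsp` (class-argmax then union), which is the
    prediction rule.
    """
    X = _check_width(model, features)
    pos = {n: i for i, n in enumerate(model.label_names)}
    out = np.zeros((X.shape[0], len(model.label_names)))
    for member in model.members:
        s = member.label_scores(X)
        for j, label in enumerate(member.community_labels):
            out[:, pos[label]] = np.maximum(out[:, pos[label]], s[:, j])
    return out


# -- persistence ----------------------------------------------------------


def save_model(model: NLSPModel, path: str | os.PathLike) -> None:
    """Persist the model as a single versioned zip archive (JSON metadata
    plus joblib-serialized predictors)."""
    meta = {
        "format_version": model.format_version,
        "clusterer": model.clusterer,
        "seed": model.seed,
        "label_names": list(model.label_names),
        "n_features": model.n_features,
        "partition": json.loads(model.partition.to_json()),
        "base_spec": {
            "family": model.base_spec.family,
            "hyperparameters": model.base_spec.hyperparameters,
            "seed": model.base_spec.seed,
        },
        "members": [
            {
                "community_labels": list(m.community_labels),
                "combination_table": [
                    [list(k), v] for k, v in m.combination_table.items()
                ],
            }
            for m in model.members
        ],
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=2))
        buf = io.BytesIO()
        joblib.dump([m.estimator for m in model.members], buf)
        zf.writestr("estimators.joblib", buf.getvalue())


def load_model(path: str | os.PathLike) -> NLSPModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {meta['format_version']}"
            )
        estimators = joblib.load(io.BytesIO(zf.read("estimators.joblib")))
    spec = BaseLearnerSpec(
        family=meta["base_spec"]["family"],
        hyperparameters=meta["base_spec"]["hyperparameters"],
        seed=meta["base_spec"]["seed"],
        allow_outside_grid=True,
    )
    members = [
        LabelPowersetModel(
            community_labels=tuple(m["community_labels"]),
            combination_table={
                tuple(k): v for k, v in m["combination_table"]
            },
            estimator=est,
        )
        for m, est in zip(meta["members"], estimators)
    ]
    return NLSPModel(
        partition=CommunityPartition.from_json(json.dumps(meta["partition"])),
        members=members,
        base_spec=spec,
        label_names=tuple(meta["label_names"]),
        n_features=meta["n_features"],
        clusterer=meta["clusterer"],
        seed=meta["seed"],
    )
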