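"""Resampling validation: jackknife and repeated k-fold cross-validation.

The co-occurrence graph, the label partition and all base predictors are
refit inside every training fold, so no information about held-out
samples leaks into the community structure.  Multilabel metrics use the
jackknife (leave-one-out) protocol; label-wise binary metrics use
repeated 10-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .datasets import MultiLabelDataset
from .ensemble import fit_nlsp, label_scores, predict_nlsp
from .learners import BaseLearnerSpec
from .metrics import (
    MultiLabelMetricReport,
    auc_trapezoidal,
    binary_metrics,
    multilabel_metrics,
)


@dataclass
class ModelConfig:
    """Clusterer + base learner, the two knobs of an NLSP run."""

    clusterer: str = "lpa"
    base_spec: BaseLearnerSpec | None = None
    weighted_graph: bool = True


def _subset(dataset: MultiLabelDataset, idx: np.ndarray) -> MultiLabelDataset:
    return MultiLabelDataset(
        features=dataset.features[idx],
        labels=dataset.labels[idx],
        label_names=dataset.label_names,
        sample_ids=[dataset.sample_ids[i] for i in idx],
        feature_names=dataset.feature_names,
    )


def _fit_predict(
    dataset: MultiLabelDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: ModelConfig,
    seed: int,
    with_scores: bool = False,
):
    model = fit_nlsp(
        _subset(dataset, train_idx),
        clusterer=config.clusterer,
        base_spec=config.base_spec,
        weighted_graph=config.weighted_graph,
        seed=seed,
    )
    X_test = dataset.features[test_idx]
    preds = predict_nlsp(model, X_test)
    scores = label_scores(model, X_test) if with_scores else None
    return preds, scores


def jackknife_evaluate(
    dataset: MultiLabelDataset,
    config: ModelConfig | None = None,
    seed: int = 0,
    subsample: int | None = None,
    return_predictions: bool = False,
) -> MultiLabelMetricReport | tuple[MultiLabelMetricReport, list]:
    """Leave-one-out evaluation of the multilabel metrics.

    For each evaluated sample i the whole model (graph, partition,
    predictors) is refit on the remaining N-1 samples and sample i is
    predicted; the metrics are the means over all collected (true,
    predicted) pairs.  ``subsample`` evaluates only a seeded random
    subset of samples (the training folds are unchanged: still all-but-i).
    """
    config = config or ModelConfig()
    n = dataset.n_samples
    if n < 2:
        raise ValueError("jackknife needs at least 2 samples")
    rng = np.random.default_rng(seed)
    if subsample is not None and subsample < n:
        eval_idx = np.sort(rng.choice(n, size=subsample, replace=False))
    else:
        eval_idx = np.arange(n)
    true_sets = dataset.label_sets()
    collected_true, collected_pred = [], []
    all_idx = np.arange(n)
    for i in eval_idx:
        train = np.delete(all_idx, i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rare labels may vanish per fold
            preds, _ = _fit_predict(dataset, train, np.array([i]), config, seed)
        collected_true.append(true_sets[i])
        collected_pred.append(preds[0])
    report = multilabel_metrics(collected_true, collected_pred, dataset.n_labels)
    if return_predictions:
        return report, collected_pred
    return report


def _fold_indices(n: int, k: int, rng: np.random.Generator):
    """Shuffled partition into k near-equal folds (sizes differ by <= 1)."""
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def kfold_evaluate(
    dataset: MultiLabelDataset,
    config: ModelConfig | None = None,
    k: int = 10,
    repeats: int = 1,
    seed: int = 0,
    pooled: bool = False,
) -> MultiLabelMetricReport:
    """Repeated k-fold cross-validation of the multilabel metrics.

    Per-fold metric averaging by default; ``pooled`` instead collects
    every (true, predicted) pair across folds and scores them once.
    """
    config = config or ModelConfig()
    n = dataset.n_samples
    if k < 2 or n < k:
        raise ValueError(f"need 2 <= k <= N, got k={k}, N={n}")
    true_sets = dataset.label_sets()
    ss = np.random.SeedSequence(seed)
    fold_reports: list[MultiLabelMetricReport] = []
    pooled_true, pooled_pred = [], []
    for rep_ss in ss.spawn(repeats):
        rng = np.random.default_rng(rep_ss)
        for test_idx in _fold_indices(n, k, rng):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                preds, _ = _fit_predict(dataset, train_idx, test_idx, config, seed)
            fold_true = [true_sets[i] for i in test_idx]
            if pooled:
                pooled_true += fold_true
                pooled_pred += preds
            else:
                fold_reports.append(
                    multilabel_metrics(fold_true, preds, dataset.n_labels)
                )
    if pooled:
        return multilabel_metrics(pooled_true, pooled_pred, dataset.n_labels)
    return MultiLabelMetricReport(
        aiming=float(np.mean([r.aiming for r in fold_reports])),
        coverage=float(np.mean([r.coverage for r in fold_reports])),
        accuracy=float(np.mean([r.accuracy for r in fold_reports])),
        absolute_true=float(np.mean([r.absolute_true for r in fold_reports])),
        hamming_loss=float(np.mean([r.hamming_loss for r in fold_reports])),
        n_samples=n,
        n_labels=dataset.n_labels,
    )


def repeated_kfold_labelwise(
    dataset: MultiLabelDataset,
    config: ModelConfig | None = None,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    stratified: bool = False,
) -> pd.DataFrame:
    """Per-label binary metrics under repeated k-fold cross-validation.

    Each repeat reshuffles with a repeat-specific derived seed and splits
    into k near-equal folds.  Per fold, the model is refit on the
    training part; per-label TP/TN/FP/FN come from the predicted label
    sets and the per-label AUC from the probability scores.  The returned
    table (one row per label) averages each metric over the k*repeats
    fold evaluations; AUC is averaged over folds where both classes occur
    in the held-out truth.  Folds are plain random by default;
    ``stratified`` stratifies them on the per-sample label count, a
    compromise that helps keep rare labels represented in every fold.
    """
    config = config or ModelConfig()
    n, m = dataset.n_samples, dataset.n_labels
    if k < 2 or n < k:
        raise ValueError(f"need 2 <= k <= N, got k={k}, N={n}")
    Y = dataset.labels
    acc = {name: {f: [] for f in ("accuracy", "specificity", "recall", "f1", "auc")}
           for name in dataset.label_names}
    ss = np.random.SeedSequence(seed)
    for rep_ss in ss.spawn(repeats):
        rep_seed = int(rep_ss.generate_state(1)[0] % (2**31))
        if stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=rep_seed)
            splits = splitter.split(np.zeros(n), Y.sum(axis=1))
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=rep_seed)
            splits = splitter.split(np.zeros(n))
        for train_idx, test_idx in splits:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                preds, scores = _fit_predict(
                    dataset, train_idx, test_idx, config, seed, with_scores=True
                )
            pred_mat = np.zeros((len(test_idx), m), dtype=int)
            name_pos = {nm: j for j, nm in enumerate(dataset.label_names)}
            for i, s in enumerate(preds):
                for lab in s:
                    pred_mat[i, name_pos[lab]] = 1
            truth = Y[test_idx]
            for j, name in enumerate(dataset.label_names):
                t, p = truth[:, j], pred_mat[:, j]
                tp = int(np.sum((t == 1) & (p == 1)))
                tn = int(np.sum((t == 0) & (p == 0)))
                fp = int(np.sum((t == 0) & (p == 1)))
                fn = int(np.sum((t == 1) & (p == 0)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = binary_metrics(tp, tn, fp, fn)
                acc[name]["accuracy"].append(rep.accuracy)
                acc[name]["specificity"].append(rep.specificity)
                acc[name]["recall"].append(rep.recall)
                acc[name]["f1"].append(rep.f1)
                if len(np.unique(t)) == 2:
                    acc[name]["auc"].append(auc_trapezoidal(scores[:, j], t))
    rows = {}
    for name, metrics_lists in acc.items():
        rows[name] = {
            f: (float(np.mean(v)) if v else float("nan"))
            for f, v in metrics_lists.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[dataset.label_names]
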