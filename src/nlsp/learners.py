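"""Base-learner configuration for the NLSP ensemble.

Five probability-capable multiclass families are supported, with the
tuning grids used for the drug-classification task:

======  ==========================  =======================
family  tuned hyperparameter        grid
======  ==========================  =======================
ERT     n_trees                     500, 1000
RF      n_trees                     500, 1000
SVM     C (RBF, gamma=1/n_features) 0.01, 0.1, 1, 10, 100
XGB     n_trees                     10, 20, ..., 100
MLP     hidden_layer_size           50, 100, 200, 500, 1000
======  ==========================  =======================

Other hyperparameters stay at the library defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

FAMILIES = ("ERT", "RF", "SVM", "XGB", "MLP")

GRIDS: dict[str, dict[str, list]] = {
    "ERT": {"n_trees": [500, 1000]},
    "RF": {"n_trees": [500, 1000]},
    "SVM": {"C": [0.01, 0.1, 1, 10, 100]},
    "XGB": {"n_trees": list(range(10, 101, 10))},
    "MLP": {"hidden_layer_size": [50, 100, 200, 500, 1000]},
}

_DEFAULTS: dict[str, dict] = {
    "ERT": {"n_trees": 500},
    "RF": {"n_trees": 500},
    "SVM": {"C": 1},
    "XGB": {"n_trees": 100},
    "MLP": {"hidden_layer_size": 100},
}


@dataclass
class BaseLearnerSpec:
    """A base-learner family, its hyperparameters and its seed.

    Hyperparameters outside the declared tuning grid trigger a warning
    unless ``allow_outside_grid`` is set.
    """

    family: str = "XGB"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    allow_outside_grid: bool = False

    def __post_init__(self) -> None:
        self.family = self.family.upper()
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown base-learner family {self.family!r}; "
                f"choose one of {FAMILIES}"
            )
        params = dict(_DEFAULTS[self.family])
        params.update(self.hyperparameters)
        unknown = set(params) - set(_DEFAULTS[self.family])
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)}"
            )
        if not self.allow_outside_grid:
            for name, value in params.items():
                grid = GRIDS[self.family][name]
                if value not in grid:
                    warnings.warn(
                        f"{self.family} {name}={value} is outside the tuning "
                        f"grid {grid}",
                        stacklevel=2,
                    )
        self.hyperparameters = params


def svm_gamma(n_features: int) -> float:
    """RBF kernel width: gamma = 1 / n_features."""
    return 1.0 / n_features


def make_base_learner(spec: BaseLearnerSpec, n_features: int) -> Callable[[], object]:
    """Return a factory producing fresh, seeded scikit-learn-style
    multiclass predictors with ``predict_proba`` support."""
    p = spec.hyperparameters
    if spec.family == "ERT":
        return lambda: ExtraTreesClassifier(
            n_estimators=p["n_trees"], random_state=spec.seed
        )
    if spec.family == "RF":
        return lambda: RandomForestClassifier(
            n_estimators=p["n_trees"], random_state=spec.seed
        )
    if spec.family == "SVM":
        return lambda: SVC(
            C=p["C"],
            kernel="rbf",
            gamma=svm_gamma(n_features),
            probability=True,
            random_state=spec.seed,
        )
    if spec.family == "XGB":
        return lambda: XGBClassifier(
            n_estimators=p["n_trees"],
            random_state=spec.seed,
            n_jobs=1,
            tree_method="hist",
        )
    if spec.family == "MLP":
        return lambda: MLPClassifier(
            hidden_layer_sizes=(p["hidden_layer_size"],),
            random_state=spec.seed,
            max_iter=1000,
        )
    raise AssertionError(spec.family)  # unreachable; __post_init__ validates
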