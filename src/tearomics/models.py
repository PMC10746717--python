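"""Severity classifiers: gradient-boosted stump ensembles.

Four models are trained per analysis: one multiclass classifier over the
severity levels present (typically {2, 3, 4}) and one one-vs-rest binary
classifier per level.  Hyperparameters are deliberately minimal:
``num_leaves=2`` (every tree is a single-split stump, which limits
overfitting and keeps attributions exactly computable) and
``is_unbalance=True`` to counter the skewed level composition.  All other
hyperparameters stay at library defaults.

Models are fitted and evaluated on the same data by design: the goal is
to explain structure in the cohort at hand ("microscope" use of ML), not
to build a deployable predictor, so no train/test split exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, f1_score, matthews_corrcoef

from tearomics.preprocess import PreprocessedMatrix


@dataclass
class TaskSpec:
    """What to train: multiclass over all levels or one-vs-rest for one."""

    kind: str = "multiclass"  # "multiclass" | "one_vs_rest"
    target_level: int | None = None
    max_leaves_per_tree: int = 2
    imbalance_weighting: bool = True
    seed: int = 0
    extra_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in ("multiclass", "one_vs_rest"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind == "one_vs_rest" and self.target_level is None:
            raise ValueError("one_vs_rest task needs a target_level")


@dataclass
class TrainingMetrics:
    balanced_accuracy: float
    f1: float
    mcc: float

    def to_json_dict(self) -> dict:
        return {"balanced_accuracy": self.balanced_accuracy, "f1": self.f1, "mcc": self.mcc}


def binarize_labels(levels, target_level: int) -> np.ndarray:
    """1 where level == target_level else 0 (one-vs-rest encoding)."""
    levels = np.asarray(levels, dtype=int)
    if target_level not in levels:
        raise ValueError(f"target level {target_level} absent from labels")
    return (levels == int(target_level)).astype(int)


@dataclass
class FittedModel:
    """A fitted LightGBM classifier with its task metadata."""

    task: TaskSpec
    estimator: lgb.LGBMClassifier
    class_labels: np.ndarray
    feature_names: list[str]

    @property
    def booster(self) -> lgb.Booster:
        return self.estimator.booster_

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def _as_array(self, X) -> pd.DataFrame:
        if isinstance(X, PreprocessedMatrix):
            X = X.values
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != list(self.feature_names):
                raise ValueError("feature set does not match the fitted model")
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError("feature count does not match the fitted model")
        return pd.DataFrame(X, columns=self.feature_names)

    def predict_probabilities(self, X) -> np.ndarray:
        """Samples x classes probability matrix, columns in class_labels order."""
        return self.estimator.predict_proba(self._as_array(X))

    def raw_margin(self, X) -> np.ndarray:
        """Samples x raw-outputs margin matrix (log-odds scale).

        Binary models have one raw output (positive class); multiclass
        models one per class (softmax inputs).
        """
        raw = self.booster.predict(self._as_array(X), raw_score=True)
        raw = np.asarray(raw, dtype=float)
        return raw[:, None] if raw.ndim == 1 else raw

    def predict(self, X) -> np.ndarray:
        """Argmax class; probability ties resolve to the lowest label."""
        proba = self.predict_probabilities(X)
        return self.class_labels[np.argmax(proba, axis=1)]


def train_classifier(X, y, task: TaskSpec) -> FittedModel:
    """Fit a gradient-boosted stump ensemble per the task spec."""
    task.validate()
    if isinstance(X, PreprocessedMatrix):
        X = X.values
    if isinstance(X, pd.DataFrame):
        feature_names = [str(c) for c in X.columns]
        X = pd.DataFrame(X.to_numpy(dtype=float), columns=feature_names)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = [f"f{i}" for i in range(X.shape[1])]
        X = pd.DataFrame(X, columns=feature_names)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must align with y")
    if task.kind == "one_vs_rest":
        y = binarize_labels(y, task.target_level)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to train")

    params = dict(
        num_leaves=task.max_leaves_per_tree,
        is_unbalance=task.imbalance_weighting,
        random_state=task.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbosity=-1,
    )
    params.update(task.extra_params)
    est = lgb.LGBMClassifier(**params)
    est.fit(X, y)
    return FittedModel(task=task, estimator=est,
                       class_labels=np.asarray(est.classes_, dtype=int),
                       feature_names=feature_names)


def metrics_from_predictions(y_true, y_pred, binary: bool = False) -> TrainingMetrics:
    """Balanced accuracy, F1 and MCC from label vectors.

    ``binary=True`` scores F1 on the positive class (label 1); otherwise
    the class-support-weighted average is used.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    average = "binary" if binary else "weighted"
    return TrainingMetrics(
        balanced_accuracy=float(balanced_accuracy_score(y_true, y_pred)),
        f1=float(f1_score(y_true, y_pred, average=average)),
        mcc=float(matthews_corrcoef(y_true, y_pred)),
    )


def evaluate_training_fit(model: FittedModel, X, y) -> TrainingMetrics:
    """Training-set metrics of argmax predictions on (X, y)."""
    y = np.asarray(y, dtype=int)
    if model.task.kind == "one_vs_rest":
        y = binarize_labels(y, model.task.target_level)
    binary = model.n_classes == 2 and set(model.class_labels) == {0, 1}
    return metrics_from_predictions(y, model.predict(X), binary=binary)
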