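"""The seven classical classifiers on stored global feature vectors.

Configured hyperparameters: LR random_state=9; LDA solver='svd';
KNN n_neighbors=5; DT library defaults; RF n_estimators=200, random_state=0;
GaussianNB var_smoothing=1e-9; SVM linear kernel, C=1, random_state=0.
Feature matrices are min-max rescaled to [0, 1] (fitted on the training
partition only) before fitting, since KNN/SVM/LR need comparable scales
across the histogram, Hu and Haralick blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, ConsistencyError, DegenerateTrainingError, ValidationError
from .evaluation import EvalReport, classification_report
from .features import load_features
from .preprocess import LabelCodec, SplitIndex

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("LR", "LDA", "KNN", "DT", "RF", "NB", "SVM")

_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "LR": {"random_state": 9, "max_iter": 5000},
    "LDA": {"solver": "svd"},
    "KNN": {"n_neighbors": 5},
    "DT": {},
    "RF": {"n_estimators": 200, "random_state": 0},
    "NB": {"var_smoothing": 1e-9},
    "SVM": {"kernel": "linear", "C": 1, "random_state": 0},
}

_FACTORIES = {
    "LR": LogisticRegression,
    "LDA": LinearDiscriminantAnalysis,
    "KNN": KNeighborsClassifier,
    "DT": DecisionTreeClassifier,
    "RF": RandomForestClassifier,
    "NB": GaussianNB,
    "SVM": SVC,
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier's name and hyperparameter mapping."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in _FACTORIES:
            raise ConfigurationError(
                f"unknown classifier {self.name!r}; known: {CLASSIFIER_NAMES}"
            )

    @classmethod
    def default(cls, name: str) -> "ClassifierSpec":
        return cls(name=name, hyperparameters=dict(_DEFAULT_HYPERPARAMETERS[name]))


def default_specs() -> list[ClassifierSpec]:
    """All seven classifiers with their configured hyperparameters."""
    return [ClassifierSpec.default(n) for n in CLASSIFIER_NAMES]


@dataclass
class FittedModel:
    """A trained classifier plus its training class order."""

    spec: ClassifierSpec
    classes: tuple[str, ...]
    pipeline: Pipeline


def train(spec: ClassifierSpec, X: np.ndarray, y, scale: bool = True) -> FittedModel:
    """Fit one classifier (optionally behind a train-fitted min-max scaler)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError(f"X {X.shape} does not match y ({len(y)})")
    if not np.isfinite(X).all():
        raise ValidationError("X contains NaN or Inf")
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise DegenerateTrainingError(f"need >= 2 classes, got {classes}")
    steps = [("scale", MinMaxScaler())] if scale else []
    steps.append(("clf", _FACTORIES[spec.name](**spec.hyperparameters)))
    pipeline = Pipeline(steps)
    pipeline.fit(X, y)
    return FittedModel(spec=spec, classes=classes, pipeline=pipeline)


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if len(X) == 0:
        return np.array([], dtype=object)
    n_expected = model.pipeline.named_steps["clf"].n_features_in_
    if X.ndim != 2 or X.shape[1] != n_expected:
        raise ValidationError(f"X has shape {X.shape}, expected (*, {n_expected})")
    return model.pipeline.predict(X)


def run_ml_suite(
    store_path,
    split: SplitIndex,
    specs: list[ClassifierSpec] | None = None,
    codec: LabelCodec | None = None,
) -> dict[str, EvalReport]:
    """Train every spec on the split's train partition, report on test."""
    specs = specs if specs is not None else default_specs()
    codec = codec or LabelCodec()
    vectors = load_features(store_path)
    by_id = {v.image_id: v for v in vectors}
    missing = [i for i in (*split.train_ids, *split.test_ids) if i not in by_id]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} split id(s) absent from feature store, e.g. {missing[:5]}"
        )
    X_train = np.stack([by_id[i].values for i in split.train_ids])
    y_train = np.array([by_id[i].label for i in split.train_ids])
    X_test = np.stack([by_id[i].values for i in split.test_ids])
    y_test = np.array([by_id[i].label for i in split.test_ids])

    reports: dict[str, EvalReport] = {}
    for spec in specs:
        model = train(spec, X_train, y_train)
        y_pred = predict(model, X_test)
        reports[spec.name] = classification_report(y_test, y_pred, codec)
    ranking = sorted(reports.items(), key=lambda kv: kv[1].accuracy, reverse=True)
    logger.info(
        "classifier ranking by test accuracy: %s",
        ", ".join(f"{n}={r.accuracy:.4f}" for n, r in ranking),
    )
    return reports


def render_accuracy_table(reports: dict[str, EvalReport]) -> str:
    """One-row accuracy table in classifier order (LR ... SVM)."""
    names = [n for n in CLASSIFIER_NAMES if n in reports] + [
        n for n in reports if n not in CLASSIFIER_NAMES
    ]
    head = "".join(f"{n:>10}" for n in names)
    row = "".join(f"{reports[n].accuracy:>10.5f}" for n in names)
    return f"{'':>12}{head}\n{'accuracy':>12}{row}\n"
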