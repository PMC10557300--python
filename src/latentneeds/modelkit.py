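"""The three comparison classifiers behind one train/predict surface.

Families and defaults:

- ``naive_bayes``  — multinomial with add-one (Laplace) smoothing.
- ``svm``          — support vector machine, linear kernel, C = 1.0.
- ``random_forest``— 100 trees, seeded.

Hyperparameters are deliberately the common library defaults; no tuning
is in scope, and every report embeds the resolved spec so runs are
auditable.  A trained model remembers a fingerprint of the vocabulary it
was fitted on and refuses matrices with a different one — predictions on
a column space the model never saw would be silently meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import joblib
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC

from .features import DocTermMatrix

FAMILIES = ("naive_bayes", "svm", "random_forest")

_DEFAULTS = {
    "naive_bayes": {"alpha": 1.0},
    "svm": {"kernel": "linear", "C": 1.0},
    "random_forest": {"n_estimators": 100},
}


class VocabularyMismatchError(ValueError):
    """Prediction matrix vocabulary differs from the training vocabulary."""


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        merged = {**_DEFAULTS[self.family], **self.hyperparameters}
        object.__setattr__(self, "hyperparameters", merged)


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    vocabulary_fingerprint: str


def _build_estimator(spec: ModelSpec):
    hp = spec.hyperparameters
    if spec.family == "naive_bayes":
        return MultinomialNB(alpha=hp["alpha"])
    if spec.family == "svm":
        return SVC(kernel=hp["kernel"], C=hp["C"], random_state=spec.seed)
    return RandomForestClassifier(
        n_estimators=hp["n_estimators"], random_state=spec.seed
    )


def train(matrix: DocTermMatrix, spec: ModelSpec) -> TrainedModel:
    """Fit one classifier family on a (train-restricted) matrix."""
    labels = matrix.labels
    if any(l is None for l in labels):
        raise ValueError("training matrix contains unlabelled rows")
    if len(set(labels)) < 2:
        raise ValueError("training data contains a single class")
    estimator = _build_estimator(spec)
    estimator.fit(matrix.weights, labels)
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        vocabulary_fingerprint=matrix.vocabulary_fingerprint,
    )


def predict(model: TrainedModel, matrix: DocTermMatrix) -> list[str]:
    """Predict one yes/no label per row; deterministic for a fixed model."""
    if matrix.vocabulary_fingerprint != model.vocabulary_fingerprint:
        raise VocabularyMismatchError(
            "matrix vocabulary does not match the model's training vocabulary"
        )
    if matrix.weights.shape[0] == 0:
        return []
    return [str(l) for l in model.estimator.predict(matrix.weights)]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist spec, fitted state and vocabulary fingerprint in one file."""
    joblib.dump(
        {
            "spec": model.spec,
            "estimator": model.estimator,
            "vocabulary_fingerprint": model.vocabulary_fingerprint,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    return TrainedModel(
        spec=blob["spec"],
        estimator=blob["estimator"],
        vocabulary_fingerprint=blob["vocabulary_fingerprint"],
    )


def write_predictions_tsv(
    path: str | Path, record_ids, true_labels, predicted_labels
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("record_id\ttrue\tpredicted\n")
        for rid, t, p in zip(record_ids, true_labels, predicted_labels):
            fh.write(f"{rid}\t{t}\t{p}\n")


def read_predictions_tsv(path: str | Path) -> tuple[list[str], list[str], list[str]]:
    ids, true, pred = [], [], []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("record_id\t"):
            raise ValueError(f"{path}: not a predictions TSV")
        for line in fh:
            rid, t, p = line.rstrip("\n").split("\t")
            ids.append(rid)
            true.append(t)
            pred.append(p)
    return ids, true, pred
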