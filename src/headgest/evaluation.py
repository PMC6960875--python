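"""Leave-one-subject-out (LOSO) evaluation and recognition/error rates.

Each fold holds out every recording of one subject; a model is trained on
the remaining subjects only (template averaging and PCA fitting included)
and evaluated on the held-out subject.  Per-class recognition is the
diagonal count over the row sum of the aggregated confusion matrix; the
error rate is its complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .dba import DBAConfig, TemplateClassifier
from .ensemble import train_bagged, vote
from .pca import PCAClassifier, TwoStagePCAClassifier
from .sequences import OrientationSequence

__all__ = ["EvaluationReport", "loso_cv", "rates", "evaluate_method"]


@dataclass
class EvaluationReport:
    """Aggregated LOSO result.

    confusion : (C, C) integer matrix, rows = true class, columns =
        predicted class, in the order of ``classes``.
    """

    classes: list[str]
    confusion: np.ndarray
    per_class_error: dict[str, float]
    total_error: float
    folds: int

    @property
    def total_recognition(self) -> float:
        return 1.0 - self.total_error

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "per_class_error": self.per_class_error,
            "total_error": self.total_error,
            "total_recognition": self.total_recognition,
            "folds": self.folds,
        }


def rates(confusion: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class and total error rates from a confusion matrix.

    Per-class recognition = diagonal / row sum; error = 1 - recognition.
    Total recognition = trace / grand sum; total error = 1 - total
    recognition.  Rows with zero sum are an error (no such class was seen).
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.size == 0:
        raise ValueError("empty confusion matrix")
    row_sums = confusion.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("confusion matrix has a zero row sum")
    per_class_error = 1.0 - np.diag(confusion) / row_sums
    total_error = 1.0 - np.trace(confusion) / confusion.sum()
    return per_class_error, float(total_error)


def loso_cv(
    dataset: list[OrientationSequence],
    trainer: Callable[[list[OrientationSequence]], object],
    classifier: Callable[[object, OrientationSequence], str],
) -> EvaluationReport:
    """Leave-one-subject-out cross-validation.

    Parameters
    ----------
    dataset : labeled recordings carrying subject ids.
    trainer : training recordings -> fitted model (called once per fold,
        never seeing the held-out subject).
    classifier : (model, recording) -> predicted label.

    Folds are ordered by subject id for determinism.  Every class must be
    present in every training fold.
    """
    subjects = sorted({r.subject for r in dataset})
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least two subjects")
    classes = sorted({r.label for r in dataset})
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)

    for held_out in subjects:
        train = [r for r in dataset if r.subject != held_out]
        test = [r for r in dataset if r.subject == held_out]
        train_classes = {r.label for r in train}
        missing = set(classes) - train_classes
        if missing:
            raise ValueError(
                f"training fold holding out {held_out!r} lacks class(es) "
                f"{sorted(missing)}"
            )
        model = trainer(train)
        for rec in test:
            predicted = classifier(model, rec)
            confusion[index[rec.label], index[predicted]] += 1

    per_class_error, total_error = rates(confusion)
    return EvaluationReport(
        classes=classes,
        confusion=confusion,
        per_class_error={c: float(per_class_error[i]) for i, c in enumerate(classes)},
        total_error=total_error,
        folds=len(subjects),
    )


def _method_fns(method: str, **params):
    """trainer/classifier pair for one of the built-in pipelines."""
    if method == "dtw":
        config = params.get("dba_config", DBAConfig())
        return (
            lambda train: TemplateClassifier.train(train, config),
            lambda model, rec: model.predict(rec),
        )
    if method == "dtwb":
        config = params.get("dba_config", DBAConfig())
        return (
            lambda train: train_bagged(train, config),
            lambda model, rec: vote(rec, model)[0],
        )
    if method == "pca":
        k = params.get("k", 15)
        L = params.get("resample_length", 100)
        est = params.get("estimator")

        def train_pca(train):
            trajs = [r.to_spatial() for r in train]
            return PCAClassifier(k=k, resample_length=L, estimator=est).fit(
                trajs, [r.label for r in train]
            )

        return train_pca, lambda model, rec: model.predict(rec.to_spatial())
    if method == "pca2":
        k2 = params.get("k", 15)
        L = params.get("resample_length", 100)
        est = params.get("estimator")

        def train_pca2(train):
            trajs = [r.to_spatial() for r in train]
            return TwoStagePCAClassifier(
                k2=k2, resample_length=L, estimator=est
            ).fit(trajs, [r.label for r in train])

        return train_pca2, lambda model, rec: model.predict(rec.to_spatial())
    raise ValueError(f"unknown method {method!r}; expected dtw, dtwb, pca or pca2")


def evaluate_method(
    dataset: list[OrientationSequence], method: str, **params
) -> EvaluationReport:
    """LOSO evaluation of one of the built-in pipelines.

    ``method`` is one of ``"dtw"`` (single template per class), ``"dtwb"``
    (bagged per-subject voting), ``"pca"`` (eigen-features + 1-NN) or
    ``"pca2"`` (two-stage PCA + 1-NN).
    """
    trainer, classifier = _method_fns(method, **params)
    return loso_cv(dataset, trainer, classifier)
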