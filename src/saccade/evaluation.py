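"""Evaluation protocols and metrics: accuracy, Cohen's kappa, confusion matrix,
subject-dependent and leave-one-subject-out splits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalReport", "score", "subject_dependent_split", "loso_split"]


@dataclass
class EvalReport:
    """Metrics for one prediction set; confusion rows are true classes."""

    accuracy: float
    kappa: float
    confusion: np.ndarray
    n: int
    degenerate_kappa: bool = False

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "confusion": self.confusion.tolist(),
            "n": self.n,
            "degenerate_kappa": self.degenerate_kappa,
        }


def score(predictions, labels, num_classes: int) -> EvalReport:
    """Accuracy, Cohen's kappa and the confusion matrix of a prediction set.

    Kappa is ``(p_o - p_e) / (1 - p_e)`` with the expected agreement ``p_e``
    computed from the confusion-matrix marginals.  The degenerate case
    ``p_e == 1`` is reported as 1 when agreement is perfect and 0 otherwise,
    with ``degenerate_kappa`` set.
    """
    predictions = np.asarray(predictions, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if predictions.shape != labels.shape or predictions.ndim != 1:
        raise ValueError(
            f"predictions {predictions.shape} and labels {labels.shape} must be "
            "equal-length 1-D vectors"
        )
    n = predictions.size
    if n == 0:
        raise ValueError("cannot score an empty prediction set")
    if predictions.min() < 0 or predictions.max() >= num_classes:
        raise ValueError("prediction outside 0..num_classes-1")
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError("label outside 0..num_classes-1")
    confusion = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(confusion, (labels, predictions), 1)
    p_o = float(np.trace(confusion)) / n
    p_e = float(confusion.sum(axis=1) @ confusion.sum(axis=0)) / n**2
    if p_e >= 1.0 - 1e-12:
        return EvalReport(
            accuracy=p_o,
            kappa=1.0 if p_o >= 1.0 - 1e-12 else 0.0,
            confusion=confusion,
            n=n,
            degenerate_kappa=True,
        )
    return EvalReport(
        accuracy=p_o, kappa=(p_o - p_e) / (1.0 - p_e), confusion=confusion, n=n
    )


def _key(ep) -> tuple[int, int, int, int]:
    return (ep.subject, ep.session, ep.run, ep.trial)


def subject_dependent_split(dataset: list) -> dict[int, tuple[list, list]]:
    """Per subject: earliest session trains, the next session tests.

    Raises when any subject has fewer than two sessions.
    """
    by_subject: dict[int, list] = {}
    for ep in dataset:
        by_subject.setdefault(ep.subject, []).append(ep)
    splits: dict[int, tuple[list, list]] = {}
    for subject in sorted(by_subject):
        eps = by_subject[subject]
        sessions = sorted({ep.session for ep in eps})
        if len(sessions) < 2:
            raise ValueError(f"subject {subject} has sessions {sessions}; need >= 2")
        train_session, test_session = sessions[0], sessions[1]
        train = [ep for ep in eps if ep.session == train_session]
        test = [ep for ep in eps if ep.session == test_session]
        splits[subject] = (train, test)
    return splits


def loso_split(dataset: list) -> list[tuple[list, list]]:
    """Leave-one-subject-out folds, ordered by held-out subject id."""
    subjects = sorted({ep.subject for ep in dataset})
    if len(subjects) < 2:
        raise ValueError(f"need >= 2 subjects for leave-one-subject-out, got {subjects}")
    folds = []
    for held_out in subjects:
        train = [ep for ep in dataset if ep.subject != held_out]
        test = [ep for ep in dataset if ep.subject == held_out]
        folds.append((train, test))
    return folds
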