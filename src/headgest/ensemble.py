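"""Bagged DTW classifier: per-subject weak classifiers combined by voting.

Instead of averaging every subject's style into one template per class, a
"weak" template classifier is trained per training subject (on that
subject's recordings only), and an input gesture is assigned to the class
chosen by the plurality of weak classifiers.  Subject-specific motion styles
are thus preserved rather than averaged away.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .dba import DBAConfig, GestureTemplate, classify, dba_train
from .sequences import OrientationSequence

__all__ = ["BaggedModel", "train_bagged", "vote"]


@dataclass
class BaggedModel:
    """members: subject id -> that subject's per-class templates."""

    members: dict[str, list[GestureTemplate]]

    @property
    def classes(self) -> list[str]:
        first = next(iter(self.members.values()))
        return [t.label for t in first]


def train_bagged(
    recordings: list[OrientationSequence],
    config: DBAConfig | None = None,
) -> BaggedModel:
    """Train one weak template classifier per subject.

    Every subject must contribute at least one recording of every class;
    a missing class is a hard error (silently skipping a subject's member
    would bias the vote).
    """
    by_subject: dict[str, dict[str, list[OrientationSequence]]] = {}
    classes: set[str] = set()
    for r in recordings:
        if r.subject is None or r.label is None:
            raise ValueError("bagged training requires subject and class labels")
        by_subject.setdefault(r.subject, {}).setdefault(r.label, []).append(r)
        classes.add(r.label)

    members: dict[str, list[GestureTemplate]] = {}
    for subject in sorted(by_subject):
        missing = classes - set(by_subject[subject])
        if missing:
            raise ValueError(
                f"subject {subject!r} is missing class(es) {sorted(missing)}; "
                "every subject must cover every class"
            )
        members[subject] = [
            dba_train(by_subject[subject][lbl], lbl, config)
            for lbl in sorted(classes)
        ]
    return BaggedModel(members=members)


def vote(
    seq: OrientationSequence, model: BaggedModel
) -> tuple[str, dict[str, int]]:
    """Classify by majority vote over the model's weak classifiers.

    Each member classifies the input independently; the plurality label
    wins.  Ties are broken by the smallest mean normalized DTW distance
    among the tied labels, averaged over the members that voted for them
    (reuses distances the members already computed; deterministic and
    independent of member iteration order).
    """
    if not model.members:
        raise ValueError("cannot vote with an empty model")
    votes: list[tuple[str, float]] = []
    for subject in sorted(model.members):
        label, distances = classify(seq, model.members[subject])
        votes.append((label, distances[label]))

    tally = Counter(lbl for lbl, _ in votes)
    top = max(tally.values())
    tied = sorted(lbl for lbl, c in tally.items() if c == top)
    if len(tied) == 1:
        return tied[0], dict(tally)
    mean_dist = {
        lbl: float(np.mean([d for l, d in votes if l == lbl])) for lbl in tied
    }
    winner = min(tied, key=lambda lbl: (mean_dist[lbl], lbl))
    return winner, dict(tally)
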