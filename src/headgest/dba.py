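"""Template learning by quaternion-aware DTW barycenter averaging (DBA).

One template per gesture class is distilled from the class's training
recordings: starting from the medoid recording, every recording is aligned
to the current template by DTW under the quaternion cost, the quaternions
matched to each template position are pooled, and each position is replaced
by their norm-preserving eigen-average (Markley mean).  Averaging therefore
never leaves the unit sphere and is blind to the q / -q sign ambiguity.

Classification is done in the spatial domain: the input recording and each
template are mapped to 3-D direction-vector trajectories and compared by
normalized Euclidean-cost DTW; the nearest template's label wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quaternion as hq
from .dtw import dtw, dtw_distance
from .sequences import OrientationSequence

__all__ = ["DBAConfig", "GestureTemplate", "dba_train", "classify", "TemplateClassifier"]


@dataclass(frozen=True)
class DBAConfig:
    """DBA iteration controls: at most ``max_iter`` refinement steps, stop
    early when the relative objective improvement falls below ``tol``."""

    max_iter: int = 10
    tol: float = 1e-4


@dataclass
class GestureTemplate:
    """A learned class template.

    quat_template : (L, 4) unit quaternions (the DBA barycenter).
    spatial_template : (L, 3) direction-vector image of the template.
    objective_trace : summed normalized DTW distance of the training
        recordings to the template, one entry per accepted DBA state;
        non-increasing by construction.
    """

    label: str
    quat_template: np.ndarray
    spatial_template: np.ndarray
    objective_trace: list[float] = field(default_factory=list)


def _medoid_index(quats: list[np.ndarray]) -> int:
    """Index of the recording with minimal summed DTW distance to the rest."""
    n = len(quats)
    if n == 1:
        return 0
    sums = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(quats[i], quats[j], cost="quaternion")
            sums[i] += d
            sums[j] += d
    return int(np.argmin(sums))


def _align_pass(
    quats: list[np.ndarray], template: np.ndarray
) -> tuple[float, list[list[np.ndarray]]]:
    """Align every recording to the template; return the objective (sum of
    normalized distances) and, per template position, the matched samples."""
    groups: list[list[np.ndarray]] = [[] for _ in range(len(template))]
    objective = 0.0
    for q in quats:
        dist, path = dtw(q, template, cost="quaternion")
        objective += dist
        for i, j in path.pairs:
            groups[j].append(q[i])
    return objective, groups


def dba_train(
    recordings: list[OrientationSequence],
    label: str,
    config: DBAConfig | None = None,
) -> GestureTemplate:
    """Learn one class template from the class's recordings.

    The template length equals the medoid recording's length (DTW needs no
    uniform length).  Iterations that fail to lower the objective are
    rejected and end the run, so ``objective_trace`` is non-increasing.
    """
    if not recordings:
        raise ValueError(f"cannot train a template for {label!r} from zero recordings")
    if config is None:
        config = DBAConfig()
    quats = [hq.normalize(r.quaternions) for r in recordings]
    template = quats[_medoid_index(quats)].copy()

    objective, groups = _align_pass(quats, template)
    trace = [objective]
    for _ in range(config.max_iter):
        candidate = np.stack(
            [hq.markley_mean(np.stack(g)) for g in groups]
        )
        new_objective, new_groups = _align_pass(quats, candidate)
        if new_objective > objective:
            break  # keep the previous template: monotone safeguard
        template, groups = candidate, new_groups
        rel_change = (objective - new_objective) / max(objective, 1e-30)
        objective = new_objective
        trace.append(objective)
        if objective == 0.0 or rel_change < config.tol:
            break

    return GestureTemplate(
        label=label,
        quat_template=template,
        spatial_template=hq.to_spatial(template),
        objective_trace=trace,
    )


def classify(
    seq: OrientationSequence, templates: list[GestureTemplate]
) -> tuple[str, dict[str, float]]:
    """Nearest-template classification in the spatial domain.

    The input is converted to its direction-vector trajectory and compared
    to every template's spatial trajectory by normalized Euclidean-cost DTW.
    Returns the argmin label and the full label -> distance map.  Ties are
    broken by template order.
    """
    if not templates:
        raise ValueError("classify requires at least one template")
    if len(seq) == 0:
        raise ValueError("cannot classify an empty sequence")
    spatial = seq.to_spatial().vectors
    distances = {
        t.label: dtw_distance(spatial, t.spatial_template, cost="euclidean")
        for t in templates
    }
    best = min(distances, key=lambda lbl: distances[lbl])
    return best, distances


@dataclass
class TemplateClassifier:
    """Plain DTW classifier: one DBA template per class, nearest wins."""

    templates: list[GestureTemplate]

    @classmethod
    def train(
        cls,
        recordings: list[OrientationSequence],
        config: DBAConfig | None = None,
    ) -> "TemplateClassifier":
        """Train one template per class over all recordings (any subject)."""
        by_class: dict[str, list[OrientationSequence]] = {}
        for r in recordings:
            if r.label is None:
                raise ValueError("all training recordings must carry a class label")
            by_class.setdefault(r.label, []).append(r)
        templates = [
            dba_train(recs, lbl, config) for lbl, recs in sorted(by_class.items())
        ]
        return cls(templates=templates)

    def predict(self, seq: OrientationSequence) -> str:
        return classify(seq, self.templates)[0]
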