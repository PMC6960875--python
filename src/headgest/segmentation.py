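"""Gesture segmentation from continuous orientation streams.

A continuous recording typically contains several gestures separated by
still periods.  Segmentation thresholds the median-filtered inter-sample
angular velocity: runs of filtered velocity above ``t1`` degrees/sample that
last at least ``t2`` samples become gesture segments.  The defaults
(``mk=15``, ``t1=1``, ``t2=10``) suit ~45 Hz acquisition; other sampling
rates may need retuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import quaternion as hq
from .sequences import OrientationSequence

__all__ = [
    "SegmentationParams",
    "Segment",
    "angular_velocity_series",
    "median_filter",
    "segment",
    "apply_segments",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the velocity-threshold segmenter.

    mk : odd median-filter window, in samples.
    t1 : angular-velocity threshold, degrees per sample.
    t2 : minimal run length, in samples.
    """

    mk: int = 15
    t1: float = 1.0
    t2: int = 10

    def __post_init__(self) -> None:
        if self.mk < 1 or self.mk % 2 == 0:
            raise ValueError("mk must be an odd integer >= 1")
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if self.t2 < 1:
            raise ValueError("t2 must be >= 1")


@dataclass(frozen=True)
class Segment:
    """Half-open sample range ``[start, end)`` of one detected gesture."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("segment must satisfy 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start


def angular_velocity_series(seq: OrientationSequence) -> np.ndarray:
    """Per-step angular velocity in degrees; element ``i`` is the rotation
    angle between samples ``i`` and ``i+1``.  Length is ``len(seq) - 1``."""
    if len(seq) < 2:
        raise ValueError("angular velocity needs at least two samples")
    return np.degrees(hq.consecutive_angles(seq.quaternions))


def median_filter(series: np.ndarray, mk: int) -> np.ndarray:
    """Centered running median with window ``mk``, truncated at boundaries.

    Boundary windows shrink rather than pad, so no data is invented at the
    stream edges.  ``mk=1`` is the identity.
    """
    if mk < 1 or mk % 2 == 0:
        raise ValueError("median filter window must be odd and >= 1")
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot filter an empty series")
    return (
        pd.Series(series).rolling(mk, center=True, min_periods=1).median().to_numpy()
    )


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, as half-open index pairs."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def segment(
    seq: OrientationSequence, params: SegmentationParams | None = None
) -> list[Segment]:
    """Detect gesture segments in a continuous stream.

    Pipeline: angular-velocity series -> median filter (window ``mk``) ->
    maximal runs strictly above ``t1`` -> discard runs shorter than ``t2``
    velocity samples.  A surviving run ``[i, j)`` in velocity indices covers
    stream samples ``[i, j+1)`` (both quaternions of the last velocity step).

    Returns a sorted list of non-overlapping segments; streams too short to
    segment yield an empty list.
    """
    if params is None:
        params = SegmentationParams()
    if len(seq) <= params.t2:
        return []
    velocity = angular_velocity_series(seq)
    filtered = median_filter(velocity, params.mk)
    segments = [
        Segment(i, j + 1)
        for i, j in _runs_above(filtered > params.t1)
        if j - i >= params.t2
    ]
    return segments


def apply_segments(
    seq: OrientationSequence, segments: list[Segment]
) -> list[OrientationSequence]:
    """Cut a stream into per-gesture recordings, each re-referenced so its
    first rotation is the identity."""
    out = []
    for s in segments:
        if s.end > len(seq):
            raise ValueError(f"segment [{s.start}, {s.end}) out of range for "
                             f"stream of length {len(seq)}")
        out.append(seq.slice(s.start, s.end).rereference())
    return out
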