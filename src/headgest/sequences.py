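"""In-memory containers for orientation recordings and derived trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import quaternion as hq

__all__ = ["OrientationSequence", "SpatialSequence"]


@dataclass
class OrientationSequence:
    """One recording: an ordered stream of unit quaternions with metadata.

    Attributes
    ----------
    quaternions : (N, 4) float array, [x, y, z, w] rows, unit norm.
    timestamps_ms : optional (N,) acquisition times in milliseconds.
    subject : optional subject identifier.
    label : optional gesture-class label.
    """

    quaternions: np.ndarray
    timestamps_ms: np.ndarray | None = None
    subject: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.ndim != 2 or self.quaternions.shape[1] != 4:
            raise ValueError("quaternions must be an (N, 4) array")
        if self.timestamps_ms is not None:
            self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
            if self.timestamps_ms.shape != (len(self.quaternions),):
                raise ValueError("timestamps length must match quaternion count")

    def __len__(self) -> int:
        return len(self.quaternions)

    def rereference(self) -> "OrientationSequence":
        """Left-multiply by the inverse of the first sample (start at identity)."""
        return replace(self, quaternions=hq.rereference(self.quaternions))

    def to_spatial(self) -> "SpatialSequence":
        """Direction-vector trajectory of the reference axis [0, 0, 1]."""
        return SpatialSequence(
            vectors=hq.to_spatial(hq.normalize(self.quaternions)),
            timestamps_ms=self.timestamps_ms,
            subject=self.subject,
            label=self.label,
        )

    def slice(self, start: int, end: int) -> "OrientationSequence":
        """Sub-recording for samples ``[start, end)``."""
        ts = None if self.timestamps_ms is None else self.timestamps_ms[start:end]
        return replace(self, quaternions=self.quaternions[start:end], timestamps_ms=ts)


@dataclass
class SpatialSequence:
    """Unit-vector trajectory on the sphere ("where the nose points")."""

    vectors: np.ndarray
    timestamps_ms: np.ndarray | None = None
    subject: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("vectors must be an (N, 3) array")

    def __len__(self) -> int:
        return len(self.vectors)
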