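"""Eigen-feature classification of spatial gesture trajectories.

Every recording's direction-vector trajectory is resampled to a common
length ``m``, flattened column-major into a vector of length ``3m``, and
projected onto the top-``k`` principal axes of the training set:

    s_k = X · (s - V)

where ``V`` is the training mean and the rows of ``X`` are the ``k``
leading eigenvectors of the training covariance.  Features are classified
by exhaustive nearest-neighbour search by default, or by any user-supplied
estimator with a fit/predict interface.

A two-stage variant first reduces the three spatial channels to two with a
per-sample PCA (pooled over all training samples), then applies the same
flatten/project/classify pipeline on the 2-channel series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import SpatialSequence

__all__ = [
    "FeatureProjection",
    "resample",
    "flatten",
    "fit_projection",
    "unflatten",
    "project",
    "nn_classify",
    "PCAClassifier",
    "TwoStagePCAClassifier",
]


@dataclass
class FeatureProjection:
    """A fitted PCA projection of flattened trajectories.

    mean_vector : (n·m,) training mean V.
    eigenvectors : (k, n·m) matrix X with orthonormal rows, ordered by
        descending eigenvalue, sign fixed so each row's largest-magnitude
        component is positive.
    eigenvalues : (k,) descending.
    """

    mean_vector: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    k: int
    resample_length: int
    channels: int


def resample(seq: SpatialSequence, L: int) -> SpatialSequence:
    """Resample a trajectory to ``L`` samples by per-coordinate linear
    interpolation on normalized index time [0, 1], then renormalize each
    sample to the unit sphere.  Endpoints are preserved exactly."""
    if len(seq) < 2:
        raise ValueError("resampling needs at least two samples")
    if L < 2:
        raise ValueError("target length must be >= 2")
    t_old = np.linspace(0.0, 1.0, len(seq))
    t_new = np.linspace(0.0, 1.0, L)
    out = np.column_stack(
        [np.interp(t_new, t_old, seq.vectors[:, c]) for c in range(3)]
    )
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    out = np.divide(out, norms, out=out, where=norms > 0)
    return SpatialSequence(
        vectors=out, subject=seq.subject, label=seq.label
    )


def flatten(seq_or_array) -> np.ndarray:
    """Column-major flattening: all samples of channel 1, then 2, then 3.

    Accepts a :class:`SpatialSequence` or an (m, n) array and returns a
    vector of length n·m.
    """
    arr = seq_or_array.vectors if isinstance(seq_or_array, SpatialSequence) else seq_or_array
    arr = np.asarray(arr, dtype=float)
    return arr.T.reshape(-1)


def unflatten(vec: np.ndarray, channels: int = 3) -> np.ndarray:
    """Inverse of :func:`flatten`: vector of length n·m -> (m, n) array."""
    vec = np.asarray(vec, dtype=float)
    return vec.reshape(channels, -1).T


def fit_projection(training: list[np.ndarray] | np.ndarray, k: int,
                   resample_length: int = 0, channels: int = 3) -> FeatureProjection:
    """Fit the PCA projection from flattened training vectors.

    Covariance uses the 1/(N-1) estimator on the mean-centred matrix.
    Eigenvector signs are fixed deterministically (largest-magnitude
    component positive) so results do not depend on solver internals.
    """
    A = np.asarray(training, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("need at least two training vectors")
    dim = A.shape[1]
    if not (1 <= k <= dim):
        raise ValueError(f"k must be in [1, {dim}], got {k}")
    V = A.mean(axis=0)
    C = np.cov(A - V, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(C))
    order = np.argsort(eigvals)[::-1][:k]
    vals = eigvals[order]
    vecs = eigvecs[:, order].T  # rows are eigenvectors
    for row in vecs:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return FeatureProjection(
        mean_vector=V,
        eigenvectors=vecs,
        eigenvalues=vals,
        k=k,
        resample_length=resample_length,
        channels=channels,
    )


def project(s: np.ndarray, p: FeatureProjection) -> np.ndarray:
    """Feature vector ``X · (s - V)`` of a flattened trajectory."""
    s = np.asarray(s, dtype=float)
    if s.shape[-1] != p.mean_vector.shape[0]:
        raise ValueError("vector length does not match the projection")
    return (s - p.mean_vector) @ p.eigenvectors.T


def nn_classify(
    features: np.ndarray, training: np.ndarray, labels: list[str]
) -> str:
    """Label of the Euclidean-nearest training vector, by exhaustive search
    (no spatial index — acceleration would not change the answer).  Ties go
    to the earliest training item."""
    if len(training) == 0:
        raise ValueError("nearest-neighbour search needs training data")
    d2 = np.sum((np.asarray(training) - np.asarray(features)) ** 2, axis=1)
    return labels[int(np.argmin(d2))]


class _NearestNeighbour:
    """Minimal fit/predict wrapper around :func:`nn_classify`."""

    def fit(self, X, y):
        self._X = np.asarray(X, dtype=float)
        self._y = list(y)
        return self

    def predict(self, X):
        return [nn_classify(x, self._X, self._y) for x in np.atleast_2d(X)]


@dataclass
class PCAClassifier:
    """Resample -> flatten -> PCA(k) -> classify (default 1-NN).

    Any estimator with sklearn-style ``fit(X, y)`` / ``predict(X)`` may be
    plugged in via ``estimator`` (e.g. a neural network or random forest);
    the eigen-feature front end is unchanged.
    """

    k: int = 15
    resample_length: int = 100
    estimator: object | None = None
    projection: FeatureProjection | None = field(default=None, repr=False)

    def fit(self, trajectories: list[SpatialSequence], labels: list[str]) -> "PCAClassifier":
        vectors = np.stack(
            [flatten(resample(t, self.resample_length)) for t in trajectories]
        )
        self.projection = fit_projection(
            vectors, self.k, resample_length=self.resample_length, channels=3
        )
        feats = np.stack([project(v, self.projection) for v in vectors])
        self.estimator = (self.estimator or _NearestNeighbour()).fit(feats, labels)
        return self

    def predict(self, trajectory: SpatialSequence) -> str:
        if self.projection is None:
            raise ValueError("classifier is not fitted")
        feat = project(flatten(resample(trajectory, self.resample_length)), self.projection)
        return self.estimator.predict([feat])[0]


@dataclass
class TwoStagePCAClassifier:
    """Per-sample channel reduction (3 -> 2) followed by the eigen-feature
    pipeline on the 2-channel series.

    Stage 1 pools every sample of every training trajectory into an (N·m, 3)
    cloud, fits a 2-component PCA, and maps each trajectory to an (m, 2)
    series.  Stage 2 flattens (length 2m), projects to ``k2`` eigen-features
    and classifies (default 1-NN).
    """

    k2: int = 15
    resample_length: int = 100
    stage1: FeatureProjection | None = field(default=None, repr=False)
    stage2: PCAClassifier | None = field(default=None, repr=False)
    estimator: object | None = None

    def _reduce(self, traj: SpatialSequence) -> np.ndarray:
        r = resample(traj, self.resample_length)
        return (r.vectors - self.stage1.mean_vector) @ self.stage1.eigenvectors.T

    def fit(self, trajectories: list[SpatialSequence], labels: list[str]) -> "TwoStagePCAClassifier":
        pooled = np.concatenate(
            [resample(t, self.resample_length).vectors for t in trajectories]
        )
        self.stage1 = fit_projection(pooled, k=2, channels=3)
        vectors = np.stack([flatten(self._reduce(t)) for t in trajectories])
        self._proj2 = fit_projection(
            vectors, self.k2, resample_length=self.resample_length, channels=2
        )
        feats = np.stack([project(v, self._proj2) for v in vectors])
        self.estimator = (self.estimator or _NearestNeighbour()).fit(feats, labels)
        return self

    def predict(self, trajectory: SpatialSequence) -> str:
        if self.stage1 is None:
            raise ValueError("classifier is not fitted")
        feat = project(flatten(self._reduce(trajectory)), self._proj2)
        return self.estimator.predict([feat])[0]
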