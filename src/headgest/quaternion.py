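"""Unit-quaternion algebra for head-orientation streams.

Quaternions are stored as ``[x, y, z, w]`` (vector part first, scalar last),
matching the on-disk recording dialect.  A quaternion ``q`` and its negation
``-q`` encode the same rotation; every operation here that compares rotations
is invariant to that sign ambiguity.

The product implemented by :func:`multiply` follows the component formula
used throughout the recognition pipeline.  Its composition convention is
fixed empirically (see the rotation-matrix oracle tests): the rotation matrix
of ``multiply(a, b)`` equals ``R(b) @ R(a)``, i.e. ``multiply(a, b)`` is the
rotation "apply *a*, then *b*".
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "qnorm",
    "normalize",
    "multiply",
    "inverse",
    "angle",
    "consecutive_angles",
    "rotate_to_vector",
    "to_spatial",
    "markley_mean",
    "rereference",
]

#: The identity rotation [x, y, z, w].
IDENTITY = np.array([0.0, 0.0, 0.0, 1.0])


def qnorm(q: np.ndarray) -> np.ndarray:
    """Euclidean norm of quaternion(s), shape ``(..., 4)`` -> ``(...)``."""
    q = np.asarray(q, dtype=float)
    return np.sqrt(np.sum(q * q, axis=-1))


def normalize(q: np.ndarray) -> np.ndarray:
    """Scale quaternion(s) to unit norm.

    Raises
    ------
    ValueError
        If any quaternion has zero norm; the message names the offending
        index for array inputs.
    """
    q = np.asarray(q, dtype=float)
    n = qnorm(q)
    if np.any(n == 0.0):
        if n.ndim == 0:
            raise ValueError("cannot normalize zero-norm quaternion")
        idx = int(np.flatnonzero(n == 0.0)[0])
        raise ValueError(f"cannot normalize zero-norm quaternion at index {idx}")
    return q / n[..., np.newaxis]


def multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Quaternion product, broadcasting over leading axes.

    Implements the component formula

    ``[w2*x1 + x2*w1 + y2*z1 - z2*y1,
       w2*y1 + y2*w1 + z2*x1 - x2*z1,
       w2*z1 + z2*w1 + x2*y1 - y2*x1,
       w2*w1 - x2*x1 - y2*y1 - z2*z1]``

    so that ``R(multiply(a, b)) == R(b) @ R(a)`` ("apply a, then b").
    The result's norm is the product of the operand norms.
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    x1, y1, z1, w1 = q1[..., 0], q1[..., 1], q1[..., 2], q1[..., 3]
    x2, y2, z2, w2 = q2[..., 0], q2[..., 1], q2[..., 2], q2[..., 3]
    return np.stack(
        [
            w2 * x1 + x2 * w1 + y2 * z1 - z2 * y1,
            w2 * y1 + y2 * w1 + z2 * x1 - x2 * z1,
            w2 * z1 + z2 * w1 + x2 * y1 - y2 * x1,
            w2 * w1 - x2 * x1 - y2 * y1 - z2 * z1,
        ],
        axis=-1,
    )


def inverse(q: np.ndarray) -> np.ndarray:
    """Multiplicative inverse ``[-x, -y, -z, w] / (x² + y² + z² + w²)``.

    For unit quaternions this is the conjugate.  Raises ``ValueError`` on
    zero-norm input.
    """
    q = np.asarray(q, dtype=float)
    d = np.sum(q * q, axis=-1)
    if np.any(d == 0.0):
        raise ValueError("cannot invert zero-norm quaternion")
    conj = q * np.array([-1.0, -1.0, -1.0, 1.0])
    return conj / d[..., np.newaxis]


def angle(q1: np.ndarray, q2: np.ndarray) -> float:
    """Rotation angle between two quaternions, in radians, range [0, π].

    Computes ``q3 = U(q1) · U(q2)⁻¹`` and the rotation angle ``2·acos(w3)``,
    with angles above π mapped to the equivalent rotation ``2π - α``.  The
    angle is evaluated as ``2·atan2(|vec(q3)|, |w3|)`` — the same quantity,
    but numerically stable near 0 and π where acos loses precision.
    Symmetric and invariant to sign flips of either argument.
    """
    q3 = multiply(normalize(q1), inverse(normalize(q2)))
    vec = np.sqrt(np.sum(q3[..., :3] ** 2, axis=-1))
    alpha = 2.0 * np.arctan2(vec, np.abs(q3[..., 3]))
    return float(alpha) if np.ndim(alpha) == 0 else alpha


def consecutive_angles(Q: np.ndarray) -> np.ndarray:
    """Angles (radians) between each pair of neighbouring quaternions.

    Vectorized equivalent of ``[angle(Q[i], Q[i+1]) for i in range(N-1)]``;
    output length is ``len(Q) - 1``.
    """
    Q = normalize(np.asarray(Q, dtype=float))
    if len(Q) < 2:
        raise ValueError("need at least two samples for consecutive angles")
    q3 = multiply(Q[:-1], inverse(Q[1:]))
    vec = np.sqrt(np.sum(q3[..., :3] ** 2, axis=-1))
    return 2.0 * np.arctan2(vec, np.abs(q3[..., 3]))


def rotate_to_vector(q: np.ndarray) -> np.ndarray:
    """Image of the reference direction [0, 0, 1] under rotation ``q``.

    Implements ``qr = (q* · qv) · q`` with ``qv = [0, 0, 1, 0]`` and
    ``q* = [-x, -y, -z, w]``, returning the vector part ``[xr, yr, zr]``.
    This is "where the nose points" for a head rotation sample.

    Requires unit input (norm within 1e-6 of 1).
    """
    q = np.asarray(q, dtype=float)
    if np.any(np.abs(qnorm(q) - 1.0) > 1e-6):
        raise ValueError(
            "rotate_to_vector requires unit quaternions; normalize() the input first"
        )
    conj = q * np.array([-1.0, -1.0, -1.0, 1.0])
    qv = np.array([0.0, 0.0, 1.0, 0.0])
    qr = multiply(multiply(conj, qv), q)
    return qr[..., :3]


def to_spatial(Q: np.ndarray) -> np.ndarray:
    """Vectorized :func:`rotate_to_vector` for a sequence, ``(N,4) -> (N,3)``."""
    return rotate_to_vector(Q)


def markley_mean(Q: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Norm-preserving average of unit quaternions (principal-eigenvector form).

    Accumulates ``M = Σ wᵢ qᵢ qᵢᵀ`` and returns the unit eigenvector of ``M``
    with the largest eigenvalue.  Because ``q qᵀ`` is blind to the sign of
    ``q``, the mean is invariant to sign flips of any input — the property
    that makes it the right average for rotation data.

    Parameters
    ----------
    Q : (n, 4) array of unit quaternions, n >= 1.
    weights : optional (n,) non-negative weights, not all zero (default: 1).

    Returns
    -------
    (4,) unit quaternion with ``w >= 0`` (first nonzero coordinate positive
    if ``w == 0``), for deterministic output across eigensolvers.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if Q.shape[0] == 0:
        raise ValueError("markley_mean of empty set is undefined")
    if weights is None:
        weights = np.ones(Q.shape[0])
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape[0] != Q.shape[0]:
            raise ValueError("weights length must match number of quaternions")
        if np.any(weights < 0) or not np.any(weights > 0):
            raise ValueError("weights must be non-negative and not all zero")
    M = (Q * weights[:, np.newaxis]).T @ Q
    try:
        eigvals, eigvecs = np.linalg.eigh(M)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - eigh on 4x4 PSD
        raise ValueError(
            f"eigen-solver failed on accumulator matrix (cond={np.linalg.cond(M):.3e})"
        ) from exc
    mean = eigvecs[:, -1]  # eigh sorts ascending
    # deterministic sign: scalar part non-negative
    if mean[3] < 0:
        mean = -mean
    elif mean[3] == 0:
        nz = np.flatnonzero(mean)
        if len(nz) and mean[nz[0]] < 0:
            mean = -mean
    return mean / np.linalg.norm(mean)


def rereference(Q: np.ndarray) -> np.ndarray:
    """Re-reference a recording so its first rotation is the identity.

    Returns ``Qr[a] = Q[0]⁻¹ · Q[a]`` for every sample; the first output is
    [0, 0, 0, 1] and all inter-sample angles are preserved (the product with
    a fixed quaternion is an isometry of the rotation angle).
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] == 0:
        raise ValueError("rereference requires a non-empty (N, 4) sequence")
    return multiply(inverse(Q[0])[np.newaxis, :], Q)
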