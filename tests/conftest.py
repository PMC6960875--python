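import numpy as np
import pytest

from headgest import OrientationSequence
from headgest import quaternion as hq


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_unit_quaternions(rng, n):
    return hq.normalize(rng.normal(size=(n, 4)))


@pytest.fixture
def random_sequence(rng):
    """A 40-sample random-walk orientation recording (small rotations)."""
    return make_random_walk(rng, 40)


def make_random_walk(rng, n, step_deg=3.0):
    """Random orientation walk: compose small random-axis rotations."""
    q = np.array([0.0, 0.0, 0.0, 1.0])
    out = [q]
    for _ in range(n - 1):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        half = np.radians(rng.uniform(0, step_deg)) / 2
        step = np.concatenate([np.sin(half) * axis, [np.cos(half)]])
        q = hq.multiply(q, step)
        out.append(q)
    return OrientationSequence(quaternions=np.stack(out))


def jaccard(a, b) -> float:
    """Overlap of two half-open index segments."""
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = max(a.end, b.end) - min(a.start, b.start)
    return inter / union
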