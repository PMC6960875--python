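"""Synthetic head-gesture generator.

Emulates a ~45 Hz IMU head-orientation dataset: seven gesture classes
(clockwise / counterclockwise circles, left / right horizontal sweeps, a
nod, and two m-shaped curves), twelve subjects with individual styles
(amplitude, tempo, a tilt of the gesture plane), irregular sampling
intervals (22.06 ± 5.83 ms), smooth angular jitter, and recording lengths
in a realistic band.  Class pairs that differ only in direction of travel
(clockwise/counterclockwise, left/right, m-left/m-right) trace *identical
point sets in reversed temporal order*, so they are indistinguishable
without temporal information — the property that motivates time-warping
classifiers.

All shapes start and end at the neutral direction (yaw 0, pitch 0), so
gestures splice continuously into still periods and a re-referenced
recording starts at the identity rotation.

Angle conventions: yaw positive to the subject's left (rotation about the
vertical y axis), pitch positive upward; the neutral gaze direction is
[0, 0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import quaternion as hq
from .segmentation import Segment
from .sequences import OrientationSequence

__all__ = [
    "CLASSES",
    "SyntheticConfig",
    "SubjectStyle",
    "direction_to_quaternion",
    "shape_curve",
    "generate_recording",
    "generate_dataset",
    "generate_stream",
]

CLASSES = (
    "clockwise",
    "counterclockwise",
    "left",
    "right",
    "nod",
    "m_left",
    "m_right",
)

# Relative gesture durations: nods are quick (the shortest recordings in
# real data), circles and sweeps take about one full tempo unit.
_DURATION = {
    "clockwise": 1.0,
    "counterclockwise": 1.0,
    "left": 1.0,
    "right": 1.0,
    "nod": 0.55,
    "m_left": 1.0,
    "m_right": 1.0,
}

# Piecewise-linear shape waypoints (t, yaw°, pitch°).  Waypoint curves keep
# the angular speed roughly constant inside a gesture, as deliberate
# gestures do, so the velocity-threshold segmenter sees one coherent run.
_WAYPOINTS = {
    "left": ([0.0, 0.25, 0.75, 1.0], [0.0, 60.0, -60.0, 0.0], [0.0, 0.0, 0.0, 0.0]),
    "right": ([0.0, 0.25, 0.75, 1.0], [0.0, -60.0, 60.0, 0.0], [0.0, 0.0, 0.0, 0.0]),
    "nod": ([0.0, 0.5, 1.0], [0.0, 0.0, 0.0], [0.0, -40.0, 0.0]),
    "m_left": (
        [0.0, 0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875, 1.0],
        [0.0, 15.0, 30.0, 15.0, 0.0, -15.0, -30.0, -15.0, 0.0],
        [0.0, -12.5, -25.0, -12.5, 0.0, -12.5, -25.0, -12.5, 0.0],
    ),
    "m_right": (
        [0.0, 0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875, 1.0],
        [0.0, -15.0, -30.0, -15.0, 0.0, 15.0, 30.0, 15.0, 0.0],
        [0.0, -12.5, -25.0, -12.5, 0.0, -12.5, -25.0, -12.5, 0.0],
    ),
}


def shape_curve(label: str, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Idealized (yaw°, pitch°) curve of one class at parameter ``t`` in [0, 1].

    Circles: radius 30° about a point 30° below neutral, traversed once
    (clockwise vs counterclockwise differ only in direction).  Sweeps, nod
    and m-curves are piecewise-linear waypoint paths.  Every curve starts
    and ends at (0, 0) and stays within the semi-hemispherical motion range.
    """
    t = np.asarray(t, dtype=float)
    if label == "clockwise":
        return 30.0 * np.sin(2 * np.pi * t), -30.0 + 30.0 * np.cos(2 * np.pi * t)
    if label == "counterclockwise":
        return -30.0 * np.sin(2 * np.pi * t), -30.0 + 30.0 * np.cos(2 * np.pi * t)
    if label in _WAYPOINTS:
        tw, yw, pw = _WAYPOINTS[label]
        return np.interp(t, tw, yw), np.interp(t, tw, pw)
    raise ValueError(f"unknown gesture class {label!r}")


@dataclass(frozen=True)
class SubjectStyle:
    """One subject's habitual way of performing gestures."""

    amp_yaw: float = 1.0
    amp_pitch: float = 1.0
    speed: float = 1.0
    tilt_deg: float = 0.0  # rotation of the gesture plane
    warp_bias: float = 0.0  # habitual tempo asymmetry (see time_warp)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults define the standard benchmark.

    noise_angle_deg is the standard deviation of the smooth per-sample
    angular jitter added to yaw and pitch (Gaussian-filtered white noise,
    ``noise_smooth_sigma`` samples wide).  base_length is the nominal
    sample count of a tempo-1.0 gesture at the nominal sampling rate.
    time_warp controls nonuniform within-gesture tempo: each recording's
    shape parameter is warped by the smooth monotone map
    ``u -> u + a·sin(2πu)/2π`` with ``a`` drawn around the subject's
    habitual bias — performers speed up and slow down unevenly, which
    time-warping classifiers absorb and fixed-grid resampling does not.
    """

    subjects: int = 12
    reps_per_class: int = 10
    classes: tuple[str, ...] = CLASSES
    noise_angle_deg: float = 2.0
    noise_smooth_sigma: float = 5.0
    amplitude_range: tuple[float, float] = (0.65, 1.35)
    speed_range: tuple[float, float] = (0.8, 1.25)
    tilt_range_deg: tuple[float, float] = (-20.0, 20.0)
    time_warp: float = 0.4
    rec_amp_jitter: float = 0.06  # per-recording amplitude spread (fraction)
    rec_tempo_jitter: float = 0.08  # per-recording tempo spread (fraction)
    dt_mean_ms: float = 22.06
    dt_sd_ms: float = 5.83
    base_length: int = 110
    length_bounds: tuple[int, int] = (50, 530)
    still_noise_deg: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("amplitude_range", "speed_range", "length_bounds"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if self.noise_angle_deg < 0 or self.still_noise_deg < 0:
            raise ValueError("noise levels must be non-negative")


def direction_to_quaternion(yaw_deg, pitch_deg) -> np.ndarray:
    """Zero-roll unit quaternion whose spatial image is the direction at
    (yaw, pitch): ``rotate_to_vector`` of the result equals
    ``[cos(p)·sin(y), sin(p), cos(p)·cos(y)]``.

    Built as pitch about the x axis followed by yaw about the y axis.
    Accepts scalars or arrays; |pitch| must stay below 90° (gimbal).
    """
    yaw = np.radians(np.asarray(yaw_deg, dtype=float))
    pitch = np.radians(np.asarray(pitch_deg, dtype=float))
    if np.any(np.abs(pitch) >= np.pi / 2):
        raise ValueError("pitch must satisfy |pitch| < 90 degrees")
    half_p = -pitch / 2.0  # x-rotation by -pitch lifts [0,0,1] toward +y
    half_y = yaw / 2.0
    zeros = np.zeros_like(yaw)
    q_pitch = np.stack([np.sin(half_p), zeros, zeros, np.cos(half_p)], axis=-1)
    q_yaw = np.stack([zeros, np.sin(half_y), zeros, np.cos(half_y)], axis=-1)
    return hq.multiply(q_pitch, q_yaw)  # apply pitch, then yaw


def _smooth_noise(n: int, sd_deg: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to the requested sd."""
    white = rng.standard_normal(n)
    if sd_deg == 0.0 or n < 2:
        return np.zeros(n)
    smooth = gaussian_filter1d(white, sigma, mode="nearest")
    s = smooth.std()
    return smooth * (sd_deg / s) if s > 0 else np.zeros(n)


def _sample_intervals(n: int, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """n-1 sampling intervals in ms: normal(dt_mean, dt_sd), floored at 1 ms."""
    return np.maximum(
        rng.normal(config.dt_mean_ms, config.dt_sd_ms, size=n - 1), 1.0
    )


def _angles_to_sequence(
    yaw: np.ndarray,
    pitch: np.ndarray,
    timestamps: np.ndarray,
    subject: str | None,
    label: str | None,
) -> OrientationSequence:
    quats = direction_to_quaternion(yaw, np.clip(pitch, -85.0, 85.0))
    return OrientationSequence(
        quaternions=hq.rereference(quats),
        timestamps_ms=timestamps,
        subject=subject,
        label=label,
    )


def _gesture_angles(
    label: str,
    style: SubjectStyle,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(yaw, pitch, timestamps) of one noisy gesture performance."""
    tempo = style.speed * rng.uniform(
        1 - config.rec_tempo_jitter, 1 + config.rec_tempo_jitter
    )
    n = int(round(config.base_length * _DURATION[label] / tempo))
    n = int(np.clip(n, config.length_bounds[0], config.length_bounds[1]))
    intervals = _sample_intervals(n, config, rng)
    timestamps = np.concatenate([[0.0], np.cumsum(intervals)])
    u = timestamps / timestamps[-1]
    if config.time_warp > 0:
        a = np.clip(
            style.warp_bias + rng.uniform(-config.time_warp, config.time_warp),
            -0.6,
            0.6,
        )
        u = u + a * np.sin(2 * np.pi * u) / (2 * np.pi)
    yaw, pitch = shape_curve(label, u)
    amp = rng.uniform(1 - config.rec_amp_jitter, 1 + config.rec_amp_jitter)
    yaw = yaw * style.amp_yaw * amp
    pitch = pitch * style.amp_pitch * amp
    # subject-specific tilt of the gesture plane
    tilt = np.radians(style.tilt_deg)
    yaw, pitch = (
        np.cos(tilt) * yaw - np.sin(tilt) * pitch,
        np.sin(tilt) * yaw + np.cos(tilt) * pitch,
    )
    yaw = yaw + _smooth_noise(n, config.noise_angle_deg, config.noise_smooth_sigma, rng)
    pitch = pitch + _smooth_noise(n, config.noise_angle_deg, config.noise_smooth_sigma, rng)
    return yaw, pitch, timestamps


def generate_recording(
    label: str,
    style: SubjectStyle,
    config: SyntheticConfig,
    rng: np.random.Generator,
    subject: str | None = None,
) -> OrientationSequence:
    """One gesture performance: the class curve sampled at jittered times,
    scaled and tilted by the subject's style, perturbed by smooth angular
    noise, converted to quaternions and re-referenced to start at the
    identity."""
    yaw, pitch, timestamps = _gesture_angles(label, style, config, rng)
    return _angles_to_sequence(yaw, pitch, timestamps, subject, label)


def draw_style(config: SyntheticConfig, rng: np.random.Generator) -> SubjectStyle:
    """Draw one subject's style parameters."""
    return SubjectStyle(
        amp_yaw=rng.uniform(*config.amplitude_range),
        amp_pitch=rng.uniform(*config.amplitude_range),
        speed=rng.uniform(*config.speed_range),
        tilt_deg=rng.uniform(*config.tilt_range_deg),
        warp_bias=rng.uniform(-config.time_warp / 2, config.time_warp / 2),
    )


def generate_dataset(config: SyntheticConfig | None = None) -> list[OrientationSequence]:
    """Full labeled dataset: subjects × classes × repetitions recordings.

    Subject styles are drawn once per subject; everything is deterministic
    under ``config.seed``.
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    dataset: list[OrientationSequence] = []
    for s in range(config.subjects):
        subject = f"s{s + 1:02d}"
        style = draw_style(config, rng)
        for label in config.classes:
            for _ in range(config.reps_per_class):
                dataset.append(
                    generate_recording(label, style, config, rng, subject=subject)
                )
    return dataset


def generate_stream(
    config: SyntheticConfig,
    gestures: list[str],
    rest_samples: int = 100,
) -> tuple[OrientationSequence, list[Segment]]:
    """Continuous multi-gesture stream with ground-truth segment boundaries.

    Gestures are spliced between still periods (neutral orientation with
    ``still_noise_deg`` jitter, far below the segmentation threshold after
    filtering).  The performer makes brisk, full-amplitude gestures at a
    steady tempo (amplitude and tempo 1.25, no time warp), keeping every
    planted gesture's angular velocity near or above 2°/sample — the stream
    fixture exercises the segmenter, whose default thresholds assume
    deliberate gestures, not classifier robustness.  Returns the raw (not
    re-referenced) stream and the planted segments in stream sample indices.
    """
    if rest_samples < 1:
        raise ValueError("rest_samples must be >= 1")
    import dataclasses

    config = dataclasses.replace(config, time_warp=0.0)
    rng = np.random.default_rng(config.seed)
    style = SubjectStyle(amp_yaw=1.25, amp_pitch=1.25, speed=1.25)
    yaw_parts: list[np.ndarray] = []
    pitch_parts: list[np.ndarray] = []
    planted: list[Segment] = []

    def still(n: int) -> tuple[np.ndarray, np.ndarray]:
        return (
            _smooth_noise(n, config.still_noise_deg, config.noise_smooth_sigma, rng),
            _smooth_noise(n, config.still_noise_deg, config.noise_smooth_sigma, rng),
        )

    pos = 0
    y0, p0 = still(rest_samples)
    yaw_parts.append(y0)
    pitch_parts.append(p0)
    pos += rest_samples
    for label in gestures:
        yaw, pitch, _ = _gesture_angles(label, style, config, rng)
        planted.append(Segment(pos, pos + len(yaw)))
        yaw_parts.append(yaw)
        pitch_parts.append(pitch)
        pos += len(yaw)
        y, p = still(rest_samples)
        yaw_parts.append(y)
        pitch_parts.append(p)
        pos += rest_samples

    yaw = np.concatenate(yaw_parts)
    pitch = np.concatenate(pitch_parts)
    intervals = _sample_intervals(len(yaw), config, rng)
    timestamps = np.concatenate([[0.0], np.cumsum(intervals)])
    quats = direction_to_quaternion(yaw, np.clip(pitch, -85.0, 85.0))
    stream = OrientationSequence(quaternions=quats, timestamps_ms=timestamps)
    return stream, planted
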