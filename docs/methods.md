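# Methods

`headgest` implements a recognition stack for head gestures captured as
streams of unit quaternions from a head-mounted IMU. This note records the
models, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Orientation model and algebra

A sample is a unit quaternion `q = [x, y, z, w]` (vector part first). `q`
and `-q` encode the same rotation, so every comparison in the package is
sign-invariant. The product is implemented by the component formula given
in `quaternion.multiply`; its composition convention was fixed empirically
against a rotation-matrix oracle and is documented on the function:
`R(multiply(a, b)) = R(b) @ R(a)` ("apply a, then b").

The angle between two rotations is the geodesic angle
`α = 2·acos(w₃)` of `q₃ = U(q₁)·U(q₂)⁻¹`, folded into `[0, π]` (an angle
above π denotes the same rotation the short way round, `2π − α`; a signed
angle would be geometrically meaningless and would break the velocity
threshold in segmentation). Numerically the angle is evaluated as
`2·atan2(|vec(q₃)|, |w₃|)`, which is the same quantity but keeps full
precision near 0 and π, where `acos` loses half the significant digits —
the inter-sample velocities that segmentation thresholds live exactly in
that near-zero regime.

The *spatial representation* of a rotation is the image of the reference
direction `[0, 0, 1]` ("where the nose points"): `qr = (q*·qv)·q` with
`qv = [0, 0, 1, 0]`. Recordings are *re-referenced* by left-multiplying
with the inverse of their first sample, so every gesture starts at the
identity; this is an isometry of inter-sample angles.

Rotations are averaged with the Markley eigen-mean: the principal
eigenvector of `M = Σ wᵢ qᵢ qᵢᵀ`. Because `qqᵀ` is blind to sign, the mean
is well defined on rotations, and it never leaves the unit sphere (unlike
a renormalized arithmetic mean, which can degenerate for spread-out
inputs). The eigenvector sign is fixed deterministically (`w ≥ 0`, first
nonzero coordinate positive if `w = 0`) so results do not depend on
eigensolver internals.

## Segmentation

Continuous recordings contain several gestures separated by still periods.
The segmenter computes the inter-sample angular velocity series (degrees
per sample), median-filters it with an odd window `mk`, and keeps maximal
runs strictly above a threshold `t1` that last at least `t2` samples. A
surviving run `[i, j)` in velocity indices maps to stream samples
`[i, j+1)` (both endpoints of the last step). Defaults `mk = 15`,
`t1 = 1°/sample`, `t2 = 10` suit ~45 Hz acquisition; other rates need
retuning, which is why all three are exposed.

Numerical choices: boundary windows of the median filter are truncated
rather than padded (no data is invented at the edges); run detection uses
strict inequality; indices are 0-based half-open throughout. `t2` is a
*minimal run length* in samples — at ~45 Hz a 10-sample minimum (~0.22 s)
is the natural reading of a minimal-length parameter, whereas 10°/sample
would be an implausibly high second velocity threshold.

## DTW and template learning (DBA)

Two pointwise costs are used. Aligning recordings in quaternion space uses
`cost(q₁, q₂) = 1 − |q₁ ∘ q₂|` (the sign-invariant chordal dissimilarity;
0 iff the same rotation, at most 1). Classification uses plain Euclidean
distance between the 3-D spatial samples. The asymmetry is deliberate:
averaging happens in quaternion space, classification on the spatial
trajectory.

The DTW dynamic program uses steps {(1,0), (0,1), (1,1)}. "Normalized
distance" means accumulated path cost divided by warping-path length — the
convention that makes distances comparable across templates of different
lengths, which the nearest-template rule requires. Backtracking breaks
ties deterministically (diagonal, then the first-sequence step).

One template per class is learned by DTW barycenter averaging adapted to
quaternions: initialize with the *medoid* recording (minimal summed DTW
distance to the rest — the standard deterministic DBA initialization);
then repeatedly align every recording to the template, pool the
quaternions matched to each template position, and replace the position by
their Markley mean. The template keeps the medoid's length (DTW needs no
uniform length). Iteration stops after `max_iter = 10` or when the
relative objective improvement falls below `1e-4`. Because the descent
argument of classical DBA (arithmetic means under squared Euclidean cost)
does not carry over verbatim to eigen-means under the `1 − |dot|` cost, an
iteration that fails to lower the objective is rejected and ends the run;
the recorded objective trace is therefore non-increasing by construction.
In practice rejected iterations are rare and occur near convergence.

## Bagged per-subject voting

A single template per class averages away subject-specific styles. The
bagged variant trains one weak template classifier per training subject
(on that subject's recordings only) and classifies by plurality vote.
Every subject must cover every class — silently skipping a subject's
missing class would bias the vote, so it is a hard error. Voting ties are
broken by the smallest mean normalized DTW distance among the tied labels
over the members that voted for them (this reuses distances the members
already computed and is independent of member iteration order); an exact
distance tie falls back to lexicographic label order.

## PCA eigen-features

Spatial trajectories are resampled to a common length `m` (default 100,
the same order as typical recording lengths) by per-coordinate linear
interpolation on normalized *index* time, followed by renormalization to
the sphere. Index-based time is used rather than wall-clock time so that
resampling a uniformly sampled recording to its own length is exactly the
identity; acquisition jitter is small relative to gesture duration.

Each trajectory is flattened column-major (all x, then y, then z; length
`3m`) and projected onto the top-`k` eigenvectors of the training
covariance (`1/(N−1)` estimator): `s_k = X·(s − V)`. Eigenvector signs are
fixed (largest-magnitude component positive). Classification is exhaustive
1-nearest-neighbour by default — index structures would change speed, not
answers — and any `fit`/`predict` estimator can be plugged in instead
(neural networks, random forests, SVMs via scikit-learn).

The two-stage variant first reduces the three spatial channels to two with
a PCA fitted on the pooled per-sample point cloud of the training set,
then runs the same flatten/project/1-NN pipeline on the 2-channel series
with `k2 = 15`. Reducing *channels per sample* is the reading that leaves
a time series for the second stage; reducing whole flattened recordings to
2-D would leave nothing to build features from. On trajectories that lie
in a plane through the sphere the first stage is lossless, which the tests
exploit as an exact fixture.

## Evaluation protocol

Leave-one-subject-out (LOSO): one fold per subject, ordered by subject id;
the held-out subject's recordings touch nothing during training — DBA
templates, PCA means, eigenvectors and feature tables are all fitted per
fold. Per-class recognition is `diagonal / row sum` of the aggregated
confusion matrix; error is its complement; total recognition is
`trace / grand total`.

## Synthetic data: what it emulates, what it does not

The generator emulates the structure of a smartphone-VR head-gesture
study: 12 subjects × 7 classes × 10 repetitions, sampling intervals drawn
from a normal with mean 22.06 ms and sd 5.83 ms (floored at 1 ms — the
acquisition loop has no rate governor), recording lengths within
[50, 530] samples.

The seven class shapes are parametric yaw/pitch curves on the
semi-hemispherical motion range, all starting and ending at the neutral
direction: 30°-radius circles about a point 30° below neutral for
clockwise/counterclockwise (the circle must pass through the origin, which
pins the centre depth to the radius); ±60° piecewise-linear horizontal
sweeps for left/right; a −40° nod (at ~0.55× duration — nods are quick);
and two-lobed m-curves spanning ±30° yaw with 25° pitch dips. Waypoint
curves keep angular speed roughly constant within a gesture, as deliberate
gestures do, so the velocity-threshold segmenter sees one coherent run per
gesture. Direction-paired classes are exact time reversals tracing
identical point sets — indistinguishable without temporal information,
which is precisely why the classifiers under study are time-aware.

Subject style comprises independent yaw/pitch amplitude factors
(0.65–1.35), a tempo factor (0.8–1.25), a tilt of the gesture plane
(±20°), and a habitual tempo-asymmetry bias. Each performance additionally
draws a small amplitude/tempo jitter, smooth angular noise (sd 2°,
Gaussian-smoothed over ~5 samples), and a nonuniform within-gesture time
warp `u → u + a·sin(2πu)/2π` (|a| ≤ 0.6): people speed up and slow down
unevenly, which time-warping classifiers absorb and fixed-grid resampling
does not. These levels were calibrated once so that classes are separable
but genuinely overlapping — total LOSO errors land in the few-percent
range rather than at zero — and then frozen.

What the generator does *not* model: neck biomechanics, roll, sensor
drift and accelerometer noise spectra, fatigue or learning effects across
repetitions, and within-subject style drift. Passing benchmarks therefore
demonstrate the correctness and relative behaviour of the pipelines under
controlled variability, not field performance on real IMU data.

Continuous streams for segmentation tests splice gestures between still
periods (0.1° jitter at neutral). The stream performer keeps unit
amplitude and steady tempo: the stream fixture exercises the segmenter,
whose default thresholds assume gesture velocity above `t1`, not
classifier robustness.

All randomness flows through one `numpy` Generator seeded from the
configuration, so every dataset, template and report is bit-reproducible.

## Degenerate inputs and edge rules

Zero-norm quaternions are rejected with the offending index; non-unit
input to the spatial map is rejected with a pointer to `normalize`;
quaternion costs are clamped at 0 against rounding; `acos`-style arguments
are clamped to [−1, 1]; streams shorter than `t2` yield no segments (not
an error); a single-recording class yields that recording as its template
with objective 0; classification ties break by template order.

## Sizes used by the shipped benchmarks

The acceptance script and benchmark tests run the full 12 × 7 × 10 LOSO
study (840 recordings, ~100 samples each) for every classifier, 20
seeded four-gesture streams for segmentation, and 100–1000-instance
batches for the algebraic and oracle checks. These sizes match the study
conditions the generator emulates while keeping a complete run in the
minutes range on one core.
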