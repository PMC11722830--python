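# Methods

This note documents the models, the synthetic data, the numerical
choices, and what the test results do and do not demonstrate.

## Planar body chain

The body is a five-link chain in the sagittal plane: calf (ankle→knee),
thigh (knee→hip), back (hip→shoulder), upper arm (shoulder→elbow),
forearm (elbow→hand). Every angle is the signed inclination of a
segment's long axis from the gravity vertical, positive forward. Three
conventions matter:

* **Vertical calf.** The shank angle is not sensed by the models; the
  calf contributes its full length to V and nothing to H. This is a
  deliberate simplification — with bent knees the model overstates V by
  `L_calf·(1 − cos θ_calf)`.
* **Arms hang from the shoulder.** The arm cosine terms are subtracted
  from V, so hands above the shoulder need |θ| > π/2 for the arm
  segments. Such angles are allowed, never clamped.
* **Thigh sign.** A forward knee (positive thigh angle) moves the hip —
  and everything above it — backward relative to the ankles, which is
  why the thigh sine term is subtracted from H. The synthetic generator
  uses the same convention, so inverse and forward kinematics close.

V and H are even and odd, respectively, under simultaneous negation of
all angles; both are bounded by the summed segment lengths. These
invariants, and 1000-draw equivalence (≤ 1e-12 m) against an
independently coded joint-position chain, are asserted in the tests.

## Sensor model and fusion

Sensors are mounted with z along the segment, x anterior, y
medio-lateral, so a static reading gives inclination `atan2(a_x, a_z)`
and the sagittal rate is the y gyro. The complementary filter

    θ_k = α(θ_{k−1} + ω_k Δt) + (1 − α)·atan2(a_x, a_z)

uses α = 0.98 at Δt = 0.04 s (time constant ≈ 2 s): fast rotations are
tracked by the gyro while the accelerometer pins the low-frequency
gravity reference. For a static sensor with constant gyro bias *b* the
steady-state error is exactly `α·b·Δt/(1 − α)` (≈ 2 cm of hand height
per 0.01 rad/s of bias at typical segment lengths); the tests assert
this closed form to 1e-6 rad. Samples whose acceleration magnitude
leaves [2, 25] m/s² (free fall, impact) fall back to a gyro-only update
for that step. A per-segment mounting offset (default 0) is subtracted
after fusion. Pronation and any off-sagittal rotation are deliberately
out of scope: the estimate is a single planar angle.

## Lift detection

The smoothed (5-sample centred moving average) forearm angular speed
must stay above ω_on = 0.3 rad/s for ≥ 0.3 s to open an event; the
event extends outward to where speed drops below ω_off = 0.1 rad/s;
events separated by < 0.4 s of rest merge; events shorter than 0.5 s
are dropped. All thresholds sit in `DetectionParams`. Detection is
deterministic, shift-equivariant, and (on unimodal excursions)
monotone in ω_on.

**Where is the lift origin?** The risk zones assess the *origin* of the
lift. In the synthetic trials the recorded motion is the reach that
ends at the origin, so the pipeline samples the posture at the detected
event's **end** boundary by default. For recordings where the motion
starts at the origin (a lift-away), pass `sample_at="start"`. Which
convention real deployments need depends on how trials are cropped;
both are supported, the choice is logged in the results.

## Anthropometry

The ratio model scales one forearm measurement by population
segment-to-forearm ratios (default 1.27 upper arm, 1.99 back, 1.68
thigh, 1.69 calf — derived from the classical Drillis–Contini stature
proportions; configurable via JSON/YAML because better population
tables can be substituted). The ratio + length model uses five measured
lengths directly. Lengths are validated to (0, 1.5) m; the upper bound
exists purely to catch centimetre/metre unit mistakes.

## Zoning

Bands are lower-closed/upper-open with the top band closed, so shared
printed endpoints (e.g. 1.45 m) assign deterministically to the upper
band. Zones number row-major from the top-near cell; the default
grouping is low {4, 5}, medium {6–9}, high {1–3, 10–12}, with the
original Los Alamos grouping available as `LOS_ALAMOS_GROUPING`.
Estimates outside the 1.70 × 0.712 m envelope are clamped to the
nearest band and flagged rather than rejected, because out-of-envelope
estimates still need scoring. Partition totality over the envelope is
grid-tested.

## Evaluation

Trial scoring is all-or-nothing per zone. Precision is diagonal over
column total and recall diagonal over row total, both from raw counts;
row-normalized rates (each true-class row summing to 1) are reported
alongside because the two model variants produce very unbalanced
prediction columns. The F-score is the harmonic mean, defined as 0 when
both inputs are 0. Macro averages are unweighted over the three risk
classes; the class-size-weighted recall (= trace/total) is the overall
accuracy. Undetected trials are excluded from counts and reported as
missing, not imputed. The implementation is cross-checked against
scikit-learn's `precision_recall_fscore_support` in the tests but does
not depend on it.

## Synthetic experiments

The generator emulates the reference study design: 10 subjects
(alternating female/male, statures N(1.618, 0.06)/N(1.756, 0.07) m
truncated at ±2σ so the fixed zone envelope stays reachable), 12 zones,
3 repetitions — 360 trials, giving grouped-risk row totals 60/120/180.
Per-subject true segment lengths are the ratio-table values times a
multiplicative jitter (sd 4%, the order of anthropometric proportion
variability); this jitter is exactly what the ratio model cannot see,
and is the main driver of its penalty. Measured lengths are exact by
default (`measurement_error_sd` adds noise if wanted).

Each trial places a target at the jittered zone centre (uniform
±0.03 m); if the subject cannot reach it, the nearest reachable point
inside the zone rectangle is used — the analogue of the height-adjusted
rig in a laboratory study. The posture solver sets trunk/thigh angles
by a stoop heuristic (flexion ramps up as the target drops below hip,
then knee, height, to at most 1.2/1.0 rad), falls back to the nearest
feasible trunk–thigh pair on a fine grid when the heuristic leaves the
target outside the two-link arm annulus, and solves the arm exactly
(elbow-down branch), so forward kinematics reproduce the target to
≤ 1e-9 m. The solver optimizes closure and determinism, not
biofidelity: some solved arm postures are awkward (folded elbows) but
kinematically valid.

Trajectories are minimum-jerk: 1 s neutral standing, 1.5 s reach, 1 s
hold, at 25 Hz. The forearm additionally carries a 0.35 rad mid-reach
elbow-flexion transient with zero value and slope at both endpoints —
real reaches flex the elbow transiently even when the final forearm is
near vertical (a stoop), and without it a forearm-speed detector is
blind to precisely those lifts. Gyro = finite-difference rate + one
constant per-axis bias per trial (N(0, 0.02 rad/s)) + white noise
(sd 0.01 rad/s); accel = gravity through the segment angle + white
noise (sd 0.2 m/s²). Optional dropout masking (default off) replaces a
fraction of samples by the previous sample, mimicking proxy-filled
gaps. Identical seeds give bit-identical trials.

### What the synthetic results do and do not show

Noise-free, the full pipeline recovers 100% of the 360 zones — a
parameter-recovery check that the fusion, detection, kinematics and
binning compose without systematic error. Median |V error| grows
monotonically with injected gyro bias, matching the filter's
closed-form sensitivity. Under the default noise the ratio model is
directionally worse than the ratio + length model, for the right
structural reason (unobserved individual proportions). The *magnitudes*
do not transfer to real data: the generator has no arm pronation, no
3-D trunk motion, no soft-tissue artefact, no marker dropout, and its
accelerometer sees pure gravity (no linear acceleration corruption), so
synthetic accuracies (≳ 90%) sit far above what field hardware achieves
and the V errors are centimetres rather than tens of centimetres. The
generator validates the software, not the hardware's field accuracy.

## Numerical details and edge cases

* Angles wrap to (−π, π]; wrapping is sin/cos-invariant so kinematics
  are unaffected.
* `accel_inclination` rejects readings whose sagittal-plane magnitude
  is below 1e-9 m/s² (direction undefined).
* Zone classification rejects NaN; out-of-range values clamp + flag.
* Problem sizes in tests and the acceptance script (360-trial
  experiments, 4 bias levels × 10 single-subject experiments, 1000
  random kinematic draws, fine partition grids) run in seconds on one
  CPU; they are the full study design, not a reduced one.
* Empty streams, non-increasing timestamps, >3 repetitions per
  subject-zone, zero-column confusion matrices and empty results tables
  all raise or flag explicitly rather than propagating silently.

## Known limitations

Two-dimensional by construction; symmetric two-handed lifts only; no
TLV weight-limit lookup (the zones, not the allowable mass, are the
output); the lift-detection thresholds were chosen for 25 Hz reach
kinematics and will need retuning for other rates; the synthetic
cohort's anthropometry is a single population table plus jitter, not a
sex/age-stratified model.
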