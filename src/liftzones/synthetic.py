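"""Seeded synthetic lifting experiments with mocap-style ground truth.

No public dataset of instrumented lifting trials exists for this
problem, so the package ships a generator that stages the full study
design on a desk: 10 subjects (5 female, 5 male) x 12 lifting zones x 3
repetitions = 360 symmetric lifting trials.  For each trial a target
hand location is placed in the requested zone, an inverse-kinematics
solver finds a plausible sagittal posture reaching it, every segment
follows a minimum-jerk angle trajectory from neutral standing to that
posture, and per-segment gyro/accel streams are synthesized with
configurable bias and noise.  The noise-free forward kinematics of the
solved posture (the hand location at the end of the reach, i.e. the
lift origin) is the ground truth a laboratory motion-capture system
would report.

Everything is driven by a single integer seed: the same seed yields
bit-identical streams, truth, and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anthropometry import DEFAULT_RATIOS, SegmentLengths, SegmentRatios
from .kinematics import HandLocation, PostureAngles, hand_location
from .sensor_fusion import GRAVITY, NOMINAL_DT, ImuStream
from .zoning import DEFAULT_BOUNDARIES, Zone, ZoneBoundaries, zone_from_vh

__all__ = [
    "NoiseProfile",
    "SyntheticSubject",
    "TrialSpec",
    "SimulatedTrial",
    "Experiment",
    "InfeasibleTargetError",
    "default_subjects",
    "solve_posture",
    "min_jerk",
    "zone_target",
    "simulate_trial",
    "simulate_experiment",
]

KINEMATIC_SEGMENTS = ("forearm", "upper_arm", "back", "thigh")
ALL_SEGMENTS = KINEMATIC_SEGMENTS + ("calf",)


class InfeasibleTargetError(ValueError):
    """The target hand location cannot be reached by the subject's chain."""


@dataclass(frozen=True)
class NoiseProfile:
    """Sensor imperfection model for one experiment.

    gyro_bias_sd : rad/s -- each trial draws one constant bias per
        gyro axis per segment from N(0, gyro_bias_sd); this is the
        drift source the complementary filter must reject.
    gyro_noise_sd : rad/s -- white noise on every gyro sample.
    accel_noise_sd : m/s^2 -- white noise on every accel sample.
    target_jitter : m -- uniform +/- jitter of the target around the
        zone centre, emulating trial-to-trial placement variation.
    missing_fraction : fraction of samples masked and filled by
        previous-value carry-forward (proxy-filled dropouts); off by
        default.
    """

    gyro_bias_sd: float = 0.02
    gyro_noise_sd: float = 0.01
    accel_noise_sd: float = 0.2
    target_jitter: float = 0.03
    missing_fraction: float = 0.0


NOISE_FREE = NoiseProfile(gyro_bias_sd=0.0, gyro_noise_sd=0.0, accel_noise_sd=0.0,
                          missing_fraction=0.0)


@dataclass(frozen=True)
class SyntheticSubject:
    """A simulated lifter: stature plus true and measured segment lengths.

    True lengths deviate from the population ratio table by an
    individual multiplicative jitter; ``measured`` lengths are what the
    ratio + length model sees, and ``forearm_measured`` is the single
    input to the ratio model.
    """

    id: str
    stature: float
    sex: str
    true_lengths: SegmentLengths
    measured_lengths: SegmentLengths
    forearm_measured: float


@dataclass(frozen=True)
class TrialSpec:
    """Fully determined description of one trial; the seed fixes all
    randomness (target jitter, biases, noise, dropouts)."""

    subject_id: str
    zone: int
    repetition: int
    seed: int
    noise: NoiseProfile = NoiseProfile()


@dataclass
class SimulatedTrial:
    spec: TrialSpec
    streams: dict[str, ImuStream]
    posture: PostureAngles         # solved posture at the lift origin
    truth: HandLocation            # noise-free forward kinematics
    true_zone: Zone
    reach_end: float               # time (s) of the lift origin


@dataclass
class Experiment:
    subjects: list[SyntheticSubject]
    trials: list[SimulatedTrial]
    manifest: dict
    skipped: list[tuple[str, int, int]] = field(default_factory=list)


# --- subjects ---------------------------------------------------------------

#: Stature distributions (m): mean and sd for female and male adults.
STATURE_DIST = {"F": (1.618, 0.06), "M": (1.756, 0.07)}

#: Multiplicative sd of an individual's deviation from the population
#: segment proportions (anthropometric proportion CV is a few percent).
SEGMENT_JITTER_SD = 0.04

#: Drillis-Contini forearm fraction of stature, used to seed subjects.
FOREARM_STATURE_RATIO = 0.146


def default_subjects(
    n: int = 10,
    rng: np.random.Generator | None = None,
    ratios: SegmentRatios = DEFAULT_RATIOS,
    measurement_error_sd: float = 0.0,
) -> list[SyntheticSubject]:
    """Draw the study cohort: alternating female/male subjects whose true
    segment lengths are the ratio-table lengths with individual jitter."""
    rng = rng if rng is not None else np.random.default_rng(0)
    subjects = []
    for i in range(n):
        sex = "F" if i % 2 == 0 else "M"
        mu, sd = STATURE_DIST[sex]
        # truncate at +/-2 sd: the lifting rig accommodates a realistic
        # working-age stature range, not distribution tails
        stature = float(mu + sd * np.clip(rng.normal(), -2.0, 2.0))
        forearm = FOREARM_STATURE_RATIO * stature
        base = {
            "forearm": forearm,
            "upper_arm": forearm * ratios.upper_arm,
            "back": forearm * ratios.back,
            "thigh": forearm * ratios.thigh,
            "calf": forearm * ratios.calf,
        }
        jitter = rng.normal(1.0, SEGMENT_JITTER_SD, size=5)
        true = SegmentLengths(**{k: v * j for (k, v), j in zip(base.items(), jitter)})
        if measurement_error_sd > 0:
            err = rng.normal(0.0, measurement_error_sd, size=5)
            measured = SegmentLengths(
                **{k: getattr(true, k) + e for k, e in zip(base, err)}
            )
        else:
            measured = true
        subjects.append(
            SyntheticSubject(
                id=f"S{i + 1:02d}",
                stature=stature,
                sex=sex,
                true_lengths=true,
                measured_lengths=measured,
                forearm_measured=measured.forearm,
            )
        )
    return subjects


# --- posture solver ---------------------------------------------------------

#: Trunk/thigh heuristic: maximum stoop (rad) reached when the target is
#: at the floor, ramping linearly from zero at hip / knee height.
MAX_TRUNK_FLEXION = 1.2
MAX_THIGH_FLEXION = 1.0

_TRUNK_GRID = np.arange(-0.3, 1.5 + 1e-9, 0.005)
_THIGH_GRID = np.arange(0.0, 1.25 + 1e-9, 0.025)


def _shoulder(lengths: SegmentLengths, th_back, th_thigh):
    """Shoulder (x, y) over arrays of trunk/thigh angles (calf vertical)."""
    x = lengths.back * np.sin(th_back) - lengths.thigh * np.sin(th_thigh)
    y = lengths.calf + lengths.thigh * np.cos(th_thigh) + lengths.back * np.cos(th_back)
    return x, y


def solve_posture(target: HandLocation, lengths: SegmentLengths) -> PostureAngles:
    """Inverse kinematics: a sagittal posture whose hands reach ``target``.

    Trunk and thigh angles follow a stoop heuristic (flexion ramps up
    as the target drops below hip, then knee, height); if the heuristic
    shoulder leaves the target outside the two-link arm annulus, the
    nearest feasible trunk/thigh pair on a fine grid is used instead.
    The remaining shoulder-to-hand offset is solved exactly by two-link
    inverse kinematics with the elbow-down branch, so the round trip
    through the forward equations closes to ~1e-12 m.

    Raises
    ------
    InfeasibleTargetError
        If no trunk/thigh combination brings the target inside the arm's
        reach annulus.
    """
    l_ua, l_fa = lengths.upper_arm, lengths.forearm
    outer = (l_ua + l_fa) * 0.999
    inner = abs(l_ua - l_fa) * 1.001 + 1e-6

    hip_height = lengths.calf + lengths.thigh
    knee_height = lengths.calf
    th_back0 = MAX_TRUNK_FLEXION * min(max((hip_height - target.v) / hip_height, 0.0), 1.0)
    th_thigh0 = MAX_THIGH_FLEXION * min(max((knee_height - target.v) / knee_height, 0.0), 1.0)

    def arm_angles(th_back: float, th_thigh: float) -> PostureAngles | None:
        sx, sy = _shoulder(lengths, th_back, th_thigh)
        rx, ry = target.h - sx, target.v - sy
        d = math.hypot(rx, ry)
        if not inner <= d <= outer:
            return None
        # two-link IK, angles measured from the downward vertical
        cos_g = (d * d - l_ua * l_ua - l_fa * l_fa) / (2.0 * l_ua * l_fa)
        gamma = math.acos(min(1.0, max(-1.0, cos_g)))  # elbow-down branch
        beta = math.atan2(l_fa * math.sin(gamma), l_ua + l_fa * math.cos(gamma))
        phi = math.atan2(rx, -ry)
        th_ua = _wrap_pi(phi - beta)
        th_fa = _wrap_pi(th_ua + gamma)
        return PostureAngles(forearm=th_fa, upper_arm=th_ua,
                             back=_wrap_pi(th_back), thigh=_wrap_pi(th_thigh))

    angles = arm_angles(th_back0, th_thigh0)
    if angles is None:
        # grid-search the nearest feasible trunk/thigh pair
        tb, tt = np.meshgrid(_TRUNK_GRID, _THIGH_GRID, indexing="ij")
        sx, sy = _shoulder(lengths, tb, tt)
        d = np.hypot(target.h - sx, target.v - sy)
        feasible = (d >= inner) & (d <= outer)
        if not feasible.any():
            raise InfeasibleTargetError(
                f"target (V={target.v:.3f}, H={target.h:.3f}) m outside the arm "
                f"reach annulus [{inner:.3f}, {outer:.3f}] m for every trunk/thigh "
                f"posture (arm span {l_ua + l_fa:.3f} m)"
            )
        cost = (tb - th_back0) ** 2 + (tt - th_thigh0) ** 2
        cost[~feasible] = np.inf
        i, j = np.unravel_index(int(np.argmin(cost)), cost.shape)
        angles = arm_angles(float(tb[i, j]), float(tt[i, j]))
        assert angles is not None

    reached = hand_location(angles, lengths)
    if math.hypot(reached.v - target.v, reached.h - target.h) > 1e-9:
        raise InfeasibleTargetError("inverse kinematics failed to close the loop")
    return angles


def _wrap_pi(a: float) -> float:
    return float(-((-a + math.pi) % (2.0 * math.pi) - math.pi))


# --- trajectories and IMU synthesis -----------------------------------------

REST_BEFORE = 1.0   # s of neutral standing before the reach
REACH_DURATION = 1.5  # s, neutral -> lift-origin posture
REST_AFTER = 1.0    # s holding the origin posture

#: Mid-reach elbow-flexion transient (rad).  Human reaches flex the
#: elbow on the way even when the final forearm posture is near
#: vertical (e.g. a stoop with hanging arms); the transient is zero at
#: both endpoints so it never moves the lift-origin posture, but it
#: guarantees the forearm sensor actually sees the reach.
REACH_ARM_SWING = 0.35


def min_jerk(tau):
    """Minimum-jerk position profile s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5
    on tau in [0, 1] (clamped outside)."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def zone_target(
    zone: int,
    boundaries: ZoneBoundaries = DEFAULT_BOUNDARIES,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> HandLocation:
    """Centre of a zone's (V, H) rectangle, with optional uniform jitter."""
    z = Zone.from_index(zone)
    ve, he = boundaries.v_edges, boundaries.h_edges
    v_lo, v_hi = ve[4 - z.v_band], ve[5 - z.v_band]
    h_lo, h_hi = he[z.h_band - 1], he[z.h_band]
    v = 0.5 * (v_lo + v_hi)
    h = 0.5 * (h_lo + h_hi)
    if jitter > 0 and rng is not None:
        v += float(rng.uniform(-jitter, jitter))
        h += float(rng.uniform(-jitter, jitter))
    return HandLocation(v=v, h=h)


def _feasible_target(
    zone: int,
    subject: SyntheticSubject,
    boundaries: ZoneBoundaries,
    jitter: float,
    rng: np.random.Generator,
) -> tuple[HandLocation, PostureAngles]:
    """A reachable target inside the zone, plus its solved posture.

    The jittered zone centre is tried first; if the subject cannot reach
    it, points inside the zone rectangle are scanned in order of
    distance from the centre (the staging analogue of adjusting the
    lifting rig to the subject's stature)."""
    target = zone_target(zone, boundaries, jitter, rng)
    try:
        return target, solve_posture(target, subject.true_lengths)
    except InfeasibleTargetError:
        pass
    z = Zone.from_index(zone)
    ve, he = boundaries.v_edges, boundaries.h_edges
    v_lo, v_hi = ve[4 - z.v_band], ve[5 - z.v_band]
    h_lo, h_hi = he[z.h_band - 1], he[z.h_band]
    margin = 0.02
    vs = np.linspace(v_lo + margin, v_hi - margin, 9)
    hs = np.linspace(h_lo + margin, h_hi - margin, 9)
    centre = zone_target(zone, boundaries)
    candidates = sorted(
        ((v, h) for v in vs for h in hs),
        key=lambda p: (p[0] - centre.v) ** 2 + (p[1] - centre.h) ** 2,
    )
    for v, h in candidates:
        try:
            target = HandLocation(v=float(v), h=float(h))
            return target, solve_posture(target, subject.true_lengths)
        except InfeasibleTargetError:
            continue
    raise InfeasibleTargetError(
        f"zone {zone} unreachable for subject {subject.id} (stature {subject.stature:.2f} m)"
    )


def simulate_trial(
    spec: TrialSpec,
    subject: SyntheticSubject,
    boundaries: ZoneBoundaries = DEFAULT_BOUNDARIES,
) -> SimulatedTrial:
    """Synthesize one lifting trial's five IMU streams and ground truth.

    The subject stands neutral for 1 s, reaches the lift-origin posture
    along a 1.5 s minimum-jerk profile, and holds it for 1 s, all
    sampled at 25 Hz.  Gyro signals are the finite-difference angular
    rates plus a per-trial constant bias and white noise; accel signals
    are gravity projected through each segment's angle plus white noise
    (linear acceleration of the segment itself is not modelled).  The
    ground truth is the noise-free forward kinematics of the posture at
    the end of the reach -- the lift origin a motion-capture system
    would record.
    """
    rng = np.random.default_rng(spec.seed)
    noise = spec.noise
    target, posture = _feasible_target(
        spec.zone, subject, boundaries, noise.target_jitter, rng
    )
    truth = hand_location(posture, subject.true_lengths)
    true_zone = zone_from_vh(truth.v, truth.h, boundaries)

    dt = NOMINAL_DT
    n = int(round((REST_BEFORE + REACH_DURATION + REST_AFTER) / dt)) + 1
    t = np.arange(n) * dt
    tau = (t - REST_BEFORE) / REACH_DURATION
    profile = min_jerk(tau)
    reach_end = REST_BEFORE + REACH_DURATION

    end_angles = {
        "forearm": posture.forearm,
        "upper_arm": posture.upper_arm,
        "back": posture.back,
        "thigh": posture.thigh,
        "calf": 0.0,  # the shank is assumed vertical throughout
    }
    tau_c = np.clip(tau, 0.0, 1.0)
    swing = np.sin(np.pi * tau_c) ** 2  # zero value and slope at both ends

    streams: dict[str, ImuStream] = {}
    for segment in ALL_SEGMENTS:
        theta = end_angles[segment] * profile
        if segment == "forearm":
            theta = theta + REACH_ARM_SWING * swing
        rate = np.gradient(theta, t)
        bias = rng.normal(0.0, noise.gyro_bias_sd, size=3)
        gyro = rng.normal(0.0, noise.gyro_noise_sd, size=(n, 3)) + bias
        gyro[:, 1] += rate
        accel = rng.normal(0.0, noise.accel_noise_sd, size=(n, 3))
        accel[:, 0] += GRAVITY * np.sin(theta)
        accel[:, 2] += GRAVITY * np.cos(theta)
        if noise.missing_fraction > 0:
            k = int(round(noise.missing_fraction * (n - 1)))
            if k > 0:
                drop = rng.choice(np.arange(1, n), size=k, replace=False)
                for idx in np.sort(drop):  # previous-value carry-forward
                    gyro[idx] = gyro[idx - 1]
                    accel[idx] = accel[idx - 1]
        streams[segment] = ImuStream(segment=segment, t=t, gyro=gyro, accel=accel)

    return SimulatedTrial(
        spec=spec,
        streams=streams,
        posture=posture,
        truth=truth,
        true_zone=true_zone,
        reach_end=reach_end,
    )


def simulate_experiment(
    n_subjects: int = 10,
    reps: int = 3,
    zones: tuple[int, ...] = tuple(range(1, 13)),
    noise: NoiseProfile = NoiseProfile(),
    seed: int = 0,
    boundaries: ZoneBoundaries = DEFAULT_BOUNDARIES,
    measurement_error_sd: float = 0.0,
) -> Experiment:
    """Stage the full design: ``n_subjects x reps x len(zones)`` trials.

    All randomness flows from ``seed``: subject anthropometry, the
    randomized trial order, and every per-trial seed.  Zones a subject
    genuinely cannot reach are skipped with a record in
    ``Experiment.skipped`` (none occur for the default cohort).
    """
    master = np.random.default_rng(seed)
    subjects = default_subjects(n_subjects, master,
                                measurement_error_sd=measurement_error_sd)
    specs = [
        (s, zone, rep)
        for s in subjects
        for zone in zones
        for rep in range(1, reps + 1)
    ]
    order = master.permutation(len(specs))  # randomized presentation order
    trial_seeds = master.integers(0, 2**31 - 1, size=len(specs))

    trials: list[SimulatedTrial] = []
    skipped: list[tuple[str, int, int]] = []
    for k in order:
        subject, zone, rep = specs[k]
        spec = TrialSpec(subject_id=subject.id, zone=zone, repetition=rep,
                         seed=int(trial_seeds[k]), noise=noise)
        try:
            trials.append(simulate_trial(spec, subject, boundaries))
        except InfeasibleTargetError:
            skipped.append((subject.id, zone, rep))

    manifest = {
        "seed": int(seed),
        "n_subjects": int(n_subjects),
        "reps": int(reps),
        "zones": [int(z) for z in zones],
        "noise": {
            "gyro_bias_sd": noise.gyro_bias_sd,
            "gyro_noise_sd": noise.gyro_noise_sd,
            "accel_noise_sd": noise.accel_noise_sd,
            "target_jitter": noise.target_jitter,
            "missing_fraction": noise.missing_fraction,
        },
        "boundaries": {
            "v_edges": list(boundaries.v_edges),
            "h_edges": list(boundaries.h_edges),
        },
        "n_trials": len(trials),
        "n_skipped": len(skipped),
    }
    return Experiment(subjects=subjects, trials=trials, manifest=manifest,
                      skipped=skipped)
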