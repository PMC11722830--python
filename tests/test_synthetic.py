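import math

import numpy as np
import pytest

from liftzones.anthropometry import SegmentLengths, segments_from_forearm
from liftzones.kinematics import HandLocation, PostureAngles, estimate_h, estimate_v, hand_location
from liftzones.synthetic import (
    NOISE_FREE,
    InfeasibleTargetError,
    NoiseProfile,
    TrialSpec,
    default_subjects,
    min_jerk,
    simulate_experiment,
    simulate_trial,
    solve_posture,
    zone_target,
)
from liftzones.zoning import group_from_zone, zone_from_vh


@pytest.fixture(scope="module")
def subject():
    return default_subjects(1, np.random.default_rng(2))[0]


class TestSolvePosture:
    def test_round_trip_closure_on_reachable_targets(self, example_lengths):
        rng = np.random.default_rng(7)
        n_checked = 0
        for _ in range(200):
            # generate a target known to be reachable: forward kinematics
            # of a random plausible posture
            angles = PostureAngles(
                forearm=rng.uniform(-0.5, 2.0),
                upper_arm=rng.uniform(-0.5, 2.0),
                back=rng.uniform(-0.2, 1.3),
                thigh=rng.uniform(0.0, 1.0),
            )
            target = hand_location(angles, example_lengths)
            try:
                solved = solve_posture(target, example_lengths)
            except InfeasibleTargetError:
                continue  # annulus margins exclude near-singular targets
            reached = hand_location(solved, example_lengths)
            assert abs(reached.v - target.v) <= 1e-9
            assert abs(reached.h - target.h) <= 1e-9
            n_checked += 1
        assert n_checked > 150

    def test_unreachable_target_raises(self, example_lengths):
        too_high = sum(example_lengths.as_dict().values()) + 0.5
        with pytest.raises(InfeasibleTargetError, match="reach"):
            solve_posture(HandLocation(v=too_high, h=0.1), example_lengths)

    def test_zone5_centre_lands_in_zone5(self, subject):
        target = zone_target(5)
        angles = solve_posture(target, subject.true_lengths)
        loc = hand_location(angles, subject.true_lengths)
        assert zone_from_vh(loc.v, loc.h).index == 5

    def test_deterministic(self, subject):
        t = zone_target(9)
        a = solve_posture(t, subject.true_lengths)
        b = solve_posture(t, subject.true_lengths)
        assert a == b


class TestMinJerk:
    def test_endpoints_and_monotonicity(self):
        tau = np.linspace(0, 1, 101)
        s = min_jerk(tau)
        assert s[0] == 0.0 and s[-1] == 1.0
        assert (np.diff(s) >= 0).all()
        assert min_jerk(-0.5) == 0.0 and min_jerk(1.5) == 1.0


class TestSimulateTrial:
    def test_same_seed_bit_identical(self, subject):
        spec = TrialSpec(subject_id=subject.id, zone=8, repetition=1, seed=123)
        a = simulate_trial(spec, subject)
        b = simulate_trial(spec, subject)
        for seg in a.streams:
            np.testing.assert_array_equal(a.streams[seg].gyro, b.streams[seg].gyro)
            np.testing.assert_array_equal(a.streams[seg].accel, b.streams[seg].accel)
        assert a.truth == b.truth

    def test_noise_free_truth_matches_posture_kinematics(self, subject):
        spec = TrialSpec(subject_id=subject.id, zone=7, repetition=1, seed=5,
                         noise=NOISE_FREE)
        trial = simulate_trial(spec, subject)
        assert trial.truth.v == pytest.approx(
            estimate_v(trial.posture, subject.true_lengths), abs=1e-12)
        assert trial.truth.h == pytest.approx(
            estimate_h(trial.posture, subject.true_lengths), abs=1e-12)
        assert trial.true_zone.index == 7

    def test_calf_stream_stays_vertical(self, subject):
        spec = TrialSpec(subject_id=subject.id, zone=10, repetition=1, seed=9,
                         noise=NOISE_FREE)
        trial = simulate_trial(spec, subject)
        np.testing.assert_allclose(trial.streams["calf"].accel[:, 2], 9.81, atol=1e-9)

    def test_missing_data_carry_forward(self, subject):
        # with continuous accel noise, exact sample repeats can only come
        # from the carry-forward fill of masked samples
        noise = NoiseProfile(gyro_bias_sd=0.0, gyro_noise_sd=0.0,
                             accel_noise_sd=0.2, missing_fraction=0.3)
        spec = TrialSpec(subject_id=subject.id, zone=9, repetition=1, seed=21,
                         noise=noise)
        trial = simulate_trial(spec, subject)
        accel = trial.streams["forearm"].accel
        repeats = int((np.abs(np.diff(accel[:, 1])) == 0.0).sum())
        assert repeats == round(0.3 * (len(accel) - 1))


class TestSimulateExperiment:
    def test_design_counts(self):
        assert len(simulate_experiment(1, 1, zones=(5,), seed=3).trials) == 1
        exp = simulate_experiment(2, 2, zones=(4, 5), seed=3)
        assert len(exp.trials) == 8
        assert all(group_from_zone(t.true_zone) == "low" for t in exp.trials)

    def test_full_design_yields_360(self):
        exp = simulate_experiment(seed=4, noise=NOISE_FREE)
        assert len(exp.trials) == 360
        assert exp.skipped == []
        assert exp.manifest["n_trials"] == 360

    def test_manifest_records_conditions(self):
        exp = simulate_experiment(1, 1, zones=(5, 6), seed=42)
        m = exp.manifest
        assert m["seed"] == 42
        assert m["noise"]["gyro_bias_sd"] == pytest.approx(0.02)
        assert m["zones"] == [5, 6]


class TestRatioModelDegradationBound:
    def test_vh_change_bounded_by_length_perturbations(self, subject):
        # swapping true lengths for forearm-scaled estimates moves (V, H)
        # by at most the sum of absolute length changes (|sin|,|cos| <= 1)
        ratio_lengths = segments_from_forearm(subject.forearm_measured)
        true = subject.true_lengths
        deltas = {
            s: abs(getattr(ratio_lengths, s) - getattr(true, s))
            for s in true.as_dict()
        }
        rng = np.random.default_rng(13)
        for _ in range(100):
            angles = PostureAngles(*rng.uniform(-math.pi / 2, math.pi / 2, size=4))
            dv = abs(estimate_v(angles, ratio_lengths) - estimate_v(angles, true))
            dh = abs(estimate_h(angles, ratio_lengths) - estimate_h(angles, true))
            assert dv <= sum(deltas.values()) + 1e-12
            assert dh <= sum(v for s, v in deltas.items() if s != "calf") + 1e-12
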