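"""Event detection, angles and velocity estimators.

Hand-constructed trajectories with known constant velocities and rotations
serve as analytic oracles; generator studies provide ground-truth recovery
checks including the noise -> 0 consistency sweep.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from katyjump import (
    DegenerateGeometryError,
    EventDetectionError,
    JumpEvents,
    TrackedTrajectory,
    analyze_jump,
    body_angle,
    body_centroid,
    detect_contact,
    detect_takeoff,
    ftj_angle,
    local_velocity,
    secant_angular_velocity,
    secant_linear_velocity,
    total_rotation,
)
from katyjump.kinematics import body_angle_series, detect_stationary
from katyjump.synth import StudyConfig, simulate_study, study_variant
from katyjump.trackio import WIDE_COLUMNS


def make_traj(points, frame_rate=2000.0, target_height=0.1):
    """Build a trajectory from a dict label -> (n, 2) arrays."""
    n = len(next(iter(points.values())))
    data = {"frame": np.arange(n), "t": np.arange(n) / frame_rate}
    for label, arr in points.items():
        arr = np.asarray(arr, dtype=float)
        data[f"{label}_x"] = arr[:, 0]
        data[f"{label}_y"] = arr[:, 1]
    return TrackedTrajectory(
        jump_id="t",
        animal_id="a",
        sex="M",
        target_height=target_height,
        frame_rate=frame_rate,
        data=pd.DataFrame(data)[WIDE_COLUMNS],
    )


def constant_velocity_traj(v=(0.6, 0.8), omega=0.0, n=51, frame_rate=2000.0):
    t = np.arange(n) / frame_rate
    cent = np.column_stack([v[0] * t, v[1] * t + 0.01])
    theta = omega * t
    half = 0.007
    axis = np.column_stack([np.cos(theta), np.sin(theta)])
    head = cent + half * axis
    abdomen = cent - half * axis
    ftj = cent + [[0.0, -0.004]] * n
    tarsus = cent + [[0.003, -0.008]] * n
    return make_traj(
        {"head": head, "abdomen": abdomen, "ftj": ftj, "tarsus": tarsus},
        frame_rate=frame_rate,
    )


class TestGeometry:
    def test_centroid_is_midpoint(self):
        traj = make_traj(
            {
                "head": [[0.0, 0.0]],
                "abdomen": [[0.014, 0.0]],
                "ftj": [[0.0, -0.01]],
                "tarsus": [[0.0, -0.02]],
            }
        )
        assert body_centroid(traj, 0) == pytest.approx([0.007, 0.0])

    @pytest.mark.parametrize(
        "head, expected",
        [((1.0, 1.0), math.pi / 4), ((-1.0, 0.0), math.pi), ((0.0, 1.0), math.pi / 2)],
    )
    def test_body_angle_from_abdomen_to_head(self, head, expected):
        traj = make_traj(
            {
                "head": [list(head)],
                "abdomen": [[0.0, 0.0]],
                "ftj": [[0.0, -1.0]],
                "tarsus": [[1.0, -1.0]],
            }
        )
        assert body_angle(traj, 0) == pytest.approx(expected)

    def test_degenerate_body_axis(self):
        traj = make_traj(
            {
                "head": [[1.0, 1.0]],
                "abdomen": [[1.0, 1.0]],
                "ftj": [[0.0, 0.0]],
                "tarsus": [[0.5, 0.0]],
            }
        )
        with pytest.raises(DegenerateGeometryError):
            body_angle(traj, 0)

    def test_unwrapped_series_of_uniform_rotation(self):
        """A rotation of 0.05 rad/frame unwraps to a strictly increasing
        line of slope 0.05, with no 2-pi jumps."""
        n, step = 400, 0.05  # several full turns
        theta = step * np.arange(n)
        axis = np.column_stack([np.cos(theta), np.sin(theta)])
        cent = np.zeros((n, 2))
        traj = make_traj(
            {
                "head": cent + 0.007 * axis,
                "abdomen": cent - 0.007 * axis,
                "ftj": cent + [[0.0, -0.004]],
                "tarsus": cent + [[0.002, -0.008]],
            }
        )
        series = body_angle_series(traj)
        diffs = np.diff(series)
        np.testing.assert_allclose(diffs, step, atol=1e-12)
        assert np.all(np.abs(diffs) < np.pi)

    @pytest.mark.parametrize(
        "proximal, vertex, tarsus, expected",
        [
            ((0.0, 1.0), (0.0, 0.0), (1.0, 0.0), 90.0),  # right angle
            ((-1.0, 0.0), (0.0, 0.0), (1.0, 0.0), 180.0),  # collinear, ftj between
            ((1.0, 1.0), (0.0, 0.0), (1.0, 1.0), 0.0),  # fully folded
            ((0.0, 2.0), (0.0, 0.0), (3.0, 3.0), 45.0),
        ],
    )
    def test_ftj_interior_angle(self, proximal, vertex, tarsus, expected):
        traj = make_traj(
            {
                "head": [[5.0, 5.0]],
                "abdomen": [list(proximal)],
                "ftj": [list(vertex)],
                "tarsus": [list(tarsus)],
            }
        )
        assert ftj_angle(traj, 0) == pytest.approx(expected, abs=1e-5)

    def test_ftj_degenerate_joint(self):
        traj = make_traj(
            {
                "head": [[1.0, 1.0]],
                "abdomen": [[0.0, 0.0]],
                "ftj": [[0.0, 0.0]],
                "tarsus": [[1.0, 0.0]],
            }
        )
        with pytest.raises(DegenerateGeometryError):
            ftj_angle(traj, 0)

    @given(
        angle=st.floats(0.0, 2 * math.pi),
        dx=st.floats(-0.1, 0.1),
        dy=st.floats(-0.1, 0.1),
    )
    @settings(max_examples=50, deadline=None)
    def test_ftj_invariant_under_rigid_motion(self, angle, dx, dy):
        pts = {
            "head": np.array([[0.01, 0.012]]),
            "abdomen": np.array([[0.0, 0.003]]),
            "ftj": np.array([[0.004, -0.002]]),
            "tarsus": np.array([[0.009, -0.006]]),
        }
        base = ftj_angle(make_traj(pts), 0)
        c, s = math.cos(angle), math.sin(angle)
        R = np.array([[c, -s], [s, c]])
        moved = {k: v @ R.T + [dx, dy] for k, v in pts.items()}
        assert ftj_angle(make_traj(moved), 0) == pytest.approx(base, abs=1e-9)


class TestVelocities:
    def test_secant_linear_velocity_hand_value(self):
        """Centroid moving (0.03, 0.04) m over 50 frames at 2000 Hz:
        0.05 m over 0.025 s = 2 m/s."""
        traj = constant_velocity_traj(v=(1.2, 1.6), n=51)
        assert secant_linear_velocity(traj, 0, 50) == pytest.approx(2.0)

    def test_secant_zero_displacement(self):
        traj = constant_velocity_traj(v=(0.0, 0.0), n=11)
        assert secant_linear_velocity(traj, 0, 10) == 0.0

    def test_secant_requires_ordered_frames(self):
        traj = constant_velocity_traj(n=11)
        with pytest.raises(ValueError):
            secant_linear_velocity(traj, 5, 5)

    def test_secant_angular_velocity_constant_rotation(self):
        traj = constant_velocity_traj(omega=47.36, n=101)
        assert secant_angular_velocity(traj, 0, 100) == pytest.approx(47.36)

    def test_half_turn_over_air_time(self):
        """pi radians over 66.3 ms is 47.4 rad/s, the observed spin scale."""
        frame_rate = 2000.0
        n_frames = 133  # ~66.5 ms
        omega = math.pi / (132 / frame_rate)
        traj = constant_velocity_traj(omega=omega, n=n_frames)
        av = secant_angular_velocity(traj, 0, 132)
        assert av == pytest.approx(math.pi / 0.066, rel=0.01)

    def test_local_equals_secant_on_constant_motion(self):
        traj = constant_velocity_traj(v=(0.9, 1.2), omega=31.80, n=41)
        lv, av = local_velocity(traj, 20, window=5)
        assert lv == pytest.approx(secant_linear_velocity(traj, 0, 40), abs=1e-9)
        assert av == pytest.approx(31.80, abs=1e-9)

    def test_local_window_bounds(self):
        traj = constant_velocity_traj(n=11)
        with pytest.raises(ValueError, match="window"):
            local_velocity(traj, 0, window=5)
        with pytest.raises(ValueError):
            local_velocity(traj, 5, window=1)

    def test_local_ballistic_truncation_bound(self):
        """On a gravity-only flight the 2-frame local estimate at take-off is
        within g/frame_rate of the launch speed."""
        fr, g, v0 = 2000.0, 9.81, 1.79
        t = np.arange(40) / fr
        cent = np.column_stack([np.zeros_like(t), v0 * t - 0.5 * g * t**2])
        traj = make_traj(
            {
                "head": cent + [[0.007, 0.0]],
                "abdomen": cent - [[0.007, 0.0]],
                "ftj": cent + [[0.0, -0.004]],
                "tarsus": cent + [[0.002, -0.008]],
            },
            frame_rate=fr,
        )
        lv, _ = local_velocity(traj, 0, window=2)
        assert abs(lv - v0) <= g / fr


class TestEventDetection:
    def test_takeoff_matches_generator_truth(self, small_study):
        for traj, truth in zip(small_study.trajectories, small_study.truths):
            assert abs(detect_takeoff(traj) - truth.takeoff_frame) <= 1

    def test_no_takeoff_when_tarsus_grounded(self):
        traj = constant_velocity_traj(v=(0.0, 0.0), n=21)
        traj.data["tarsus_y"] = 0.0
        with pytest.raises(EventDetectionError, match="no take-off"):
            detect_takeoff(traj, substrate_y=0.0)

    def test_clearance_above_peak_fails(self, small_study):
        traj = small_study.trajectories[0]
        with pytest.raises(EventDetectionError):
            detect_takeoff(traj, clearance=10.0)

    def test_contact_matches_generator_truth(self, small_study):
        for traj, truth in zip(small_study.trajectories, small_study.truths):
            got = detect_contact(traj, traj.target_height)
            assert got <= truth.contact_frame
            assert truth.contact_frame - got <= 30  # slow near-apex approach

    def test_contact_unreachable_target(self, small_study):
        traj = small_study.trajectories[0]
        with pytest.raises(EventDetectionError, match="no contact"):
            detect_contact(traj, target_y=10.0)

    def test_huge_tolerance_returns_frame_zero(self, small_study):
        traj = small_study.trajectories[0]
        assert detect_contact(traj, traj.target_height, tolerance=1e9) == 0

    def test_stationary_requires_movement(self):
        traj = constant_velocity_traj(v=(0.0, 0.0), n=21)
        with pytest.raises(EventDetectionError, match="no movement"):
            detect_stationary(traj)

    def test_events_ordering_enforced(self):
        with pytest.raises(ValueError):
            JumpEvents(stationary_frame=5, takeoff_frame=5, contact_frame=9)


class TestTotalRotation:
    def test_constant_rotation_half_turn(self):
        n = 101
        omega = math.pi / (100 / 2000.0)
        traj = constant_velocity_traj(omega=omega, n=n)
        events = JumpEvents(0, 1, 100)
        rot = total_rotation(traj, events) + omega / 2000.0  # add back 1 frame
        assert rot == pytest.approx(math.pi, abs=1e-6)

    def test_zero_rotation(self):
        traj = constant_velocity_traj(omega=0.0, n=21)
        assert total_rotation(traj, JumpEvents(0, 5, 20)) == 0.0


class TestAnalyzeJump:
    def test_noise_free_recovery(self, noisefree_study):
        """Without tracking noise every estimator hits the generative truth
        up to frame-discretization bounds."""
        for traj, truth in zip(
            noisefree_study.trajectories, noisefree_study.truths
        ):
            morph = noisefree_study.morphometrics[traj.animal_id]
            kin = analyze_jump(traj, morph)
            assert kin.lv_secant == pytest.approx(truth.lv, abs=0.02)
            assert abs(kin.av_secant) == pytest.approx(truth.av, abs=0.5)
            assert kin.lv_takeoff == pytest.approx(truth.v0, abs=0.03)
            assert kin.ftj_takeoff == pytest.approx(truth.ftj_takeoff, abs=0.1)
            assert kin.ftj_rest == pytest.approx(truth.ftj_rest, abs=1.0)
            assert kin.air_time == pytest.approx(truth.air_time, abs=2e-3)

    def test_noise_consistency_sweep(self):
        """Estimates converge to generative parameters as tracking noise
        shrinks: RMSE decreases over SD = 0.2, 0.05, 0 mm."""
        rmses = []
        for sd in (2e-4, 5e-5, 0.0):
            cfg = study_variant(
                StudyConfig(seed=11),
                n_animals=3,
                n_males=2,
                jumps_per_height=(3, 3, 3),
                tracking_noise_sd=sd,
            )
            study = simulate_study(cfg)
            errs = []
            for traj, truth in zip(study.trajectories, study.truths):
                kin = analyze_jump(traj, study.morphometrics[traj.animal_id])
                errs.append(abs(kin.av_secant) - truth.av)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] > rmses[1] > rmses[2]
        assert rmses[2] < 0.5

    def test_missing_flight_phase_fails_contact(self, small_study):
        traj = small_study.trajectories[0]
        truncated = TrackedTrajectory(
            jump_id=traj.jump_id,
            animal_id=traj.animal_id,
            sex=traj.sex,
            target_height=traj.target_height,
            frame_rate=traj.frame_rate,
            data=traj.data.iloc[: traj.n_frames // 4],
        )
        morph = small_study.morphometrics[traj.animal_id]
        with pytest.raises(EventDetectionError):
            analyze_jump(truncated, morph)

    def test_batch_analysis_complete(self, small_study):
        from katyjump import analyze_study

        results, excluded = analyze_study(small_study)
        assert len(results) == len(small_study.trajectories)
        assert excluded == []
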