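"""Synthetic-study generator: structure, determinism, ground-truth fidelity."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from katyjump import (
    StudyConfig,
    generate_study,
    read_trajectory,
    sample_jump_parameters,
    sample_study,
    simulate_study,
)
from katyjump.synth import (
    _mean_preserving_loc,
    load_study,
    solve_takeoff_speed,
    study_variant,
)


class TestStudyConfig:
    def test_defaults_validate(self):
        StudyConfig().validate()

    def test_invalid_fields_listed(self):
        cfg = replace(StudyConfig(), n_animals=0, tracking_noise_sd=-1.0)
        with pytest.raises(ValueError, match="n_animals"):
            cfg.validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = study_variant(StudyConfig(), seed=99, jumps_per_height=(5, 6, 7))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = StudyConfig.from_yaml(path)
        assert back == cfg
        assert back.config_hash() == cfg.config_hash()

    def test_unknown_fields_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            StudyConfig.from_dict({"not_a_field": 1})


class TestSampleStudy:
    def test_study_structure(self, default_config, rng):
        """Default roster and jump counts: 7 animals (5 M, 2 F), 151 jumps
        split 47/53/51 across the three heights."""
        morphs, assign = sample_study(default_config, rng)
        assert len(morphs) == 7
        sexes = assign.drop_duplicates("animal_id")["sex"].value_counts()
        assert sexes["M"] == 5 and sexes["F"] == 2
        counts = assign["target_height"].value_counts()
        assert len(assign) == 151
        assert counts[0.050] == 47 and counts[0.075] == 53 and counts[0.100] == 51

    def test_masses_in_range_and_leg_ratio(self, default_config, rng):
        morphs, _ = sample_study(default_config, rng)
        for m in morphs.values():
            assert 6.78e-5 <= m.mass <= 8.22e-5
            assert m.leg_length / m.body_length == pytest.approx(1.37, rel=1e-12)

    def test_deterministic_given_seed(self, default_config):
        m1, a1 = sample_study(default_config, np.random.default_rng(5))
        m2, a2 = sample_study(default_config, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a1, a2)
        assert all(
            m1[k].body_length == m2[k].body_length for k in m1
        )

    def test_every_animal_jumps_at_every_height(self, default_config, rng):
        _, assign = sample_study(default_config, rng)
        per = assign.groupby("animal_id")["target_height"].nunique()
        assert (per == 3).all()


class TestSampleJumpParameters:
    def test_zero_variance_hits_means(self):
        cfg = study_variant(
            StudyConfig(),
            lv_se=(0.0, 0.0, 0.0),
            av_se=(0.0, 0.0, 0.0),
            ftj_takeoff_se=(0.0, 0.0, 0.0),
            ftj_rest_se=(0.0, 0.0, 0.0),
        )
        rng = np.random.default_rng(0)
        p = sample_jump_parameters(cfg, "a01", 0.050, rng)
        assert p["lv"] == 1.40
        assert p["av"] == 47.36
        assert p["ftj_takeoff"] == 129.0

    def test_monte_carlo_mean_recovery(self, default_config):
        """10k draws at the 100 mm condition: the sample mean of lv sits
        within 3 SEs of the mean of the generative 1.79 m/s despite the
        reachability truncation (mean-preserving location shift)."""
        rng = np.random.default_rng(123)
        draws = np.array(
            [
                sample_jump_parameters(default_config, "a01", 0.100, rng)["lv"]
                for _ in range(10_000)
            ]
        )
        sem = draws.std(ddof=1) / math.sqrt(len(draws))
        assert draws.mean() == pytest.approx(1.79, abs=3 * sem)
        # truncation floor respected
        assert draws.min() >= default_config.lv_lower_bound(0.100)

    def test_same_rng_state_same_draw(self, default_config):
        p1 = sample_jump_parameters(
            default_config, "a01", 0.075, np.random.default_rng(9)
        )
        p2 = sample_jump_parameters(
            default_config, "a01", 0.075, np.random.default_rng(9)
        )
        assert p1 == p2

    def test_mean_preserving_location(self):
        """The adjusted location makes the truncated-normal mean equal the
        target even under heavy truncation."""
        from scipy.stats import truncnorm

        mu, sd, lower = 1.79, 0.857, 1.0
        loc = _mean_preserving_loc(mu, sd, lower)
        a = (lower - loc) / sd
        assert truncnorm.mean(a, np.inf, loc=loc, scale=sd) == pytest.approx(
            mu, abs=1e-9
        )
        # negligible truncation: location untouched
        assert _mean_preserving_loc(10.0, 0.1, 0.0) == 10.0


class TestSynthesizeTrajectory:
    def test_rigid_body_axis(self, noisefree_study):
        """Head and abdomen tip are exactly one body length apart at every
        frame (noise-free)."""
        for traj in noisefree_study.trajectories:
            L = noisefree_study.morphometrics[traj.animal_id].body_length
            d = np.linalg.norm(traj.point("head") - traj.point("abdomen"), axis=1)
            np.testing.assert_allclose(d, L, atol=1e-12)

    def test_solver_realizes_secant(self, default_config):
        """The take-off speed solver produces a flight whose continuous
        secant velocity equals the requested value."""
        v0, T = solve_takeoff_speed(1.79, 31.80, default_config, 0.100, 0.0146)
        g = default_config.gravity
        secant = (1.79 * 0 + (v0 * T - 0.5 * g * T**2)) / T  # vertical jump
        assert secant == pytest.approx(1.79, abs=1e-6)
        assert v0 > 1.79  # gravity decelerates the ascent

    def test_constant_rotation_truth(self, noisefree_study):
        """total_rotation equals av * air_time for every generated jump."""
        for truth in noisefree_study.truths:
            assert truth.total_rotation == pytest.approx(
                truth.av * truth.air_time, rel=1e-12
            )

    def test_truth_table_sufficient(self, small_study):
        """Every quantity the analysis reports has a truth counterpart."""
        truth_cols = set(small_study.truth_frame().columns)
        assert {
            "lv", "av", "ftj_rest", "ftj_takeoff", "v0", "theta_takeoff",
            "air_time", "total_rotation", "stationary_frame", "takeoff_frame",
            "contact_frame",
        } <= truth_cols


class TestGenerateStudy:
    def test_file_tree_and_parseability(self, tmp_path):
        cfg = study_variant(
            StudyConfig(seed=21), n_animals=3, n_males=2, jumps_per_height=(2, 2, 2)
        )
        out = generate_study(cfg, tmp_path / "study")
        traj_files = sorted((out / "trajectories").glob("*.csv"))
        assert len(traj_files) == 6
        for name in ("morphometrics.csv", "assignments.csv", "truth.csv",
                     "manifest.yaml"):
            assert (out / name).exists()
        # every emitted trajectory parses with zero errors
        for f in traj_files:
            traj = read_trajectory(f, scale=1.0, frame_rate=cfg.frame_rate)
            assert traj.n_frames > cfg.rest_frames

    def test_regeneration_byte_identical(self, tmp_path):
        cfg = study_variant(
            StudyConfig(seed=22), n_animals=3, n_males=2, jumps_per_height=(2, 2, 2)
        )
        out1 = generate_study(cfg, tmp_path / "s1")
        out2 = generate_study(cfg, tmp_path / "s2")
        for f1 in sorted(out1.rglob("*.csv")):
            f2 = out2 / f1.relative_to(out1)
            assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_seed_changes_coordinates_not_counts(self, tmp_path):
        base = study_variant(
            StudyConfig(seed=23), n_animals=3, n_males=2, jumps_per_height=(2, 2, 2)
        )
        other = replace(base, seed=24)
        s1 = simulate_study(base)
        s2 = simulate_study(other)
        assert len(s1.trajectories) == len(s2.trajectories)
        n = min(s1.trajectories[0].n_frames, s2.trajectories[0].n_frames)
        assert not np.allclose(
            s1.trajectories[0].point("head")[:n],
            s2.trajectories[0].point("head")[:n],
        )

    def test_load_study_roundtrip(self, tmp_path):
        cfg = study_variant(
            StudyConfig(seed=25), n_animals=3, n_males=2, jumps_per_height=(2, 2, 2)
        )
        out = generate_study(cfg, tmp_path / "study")
        study = load_study(out)
        assert len(study.trajectories) == 6
        assert study.config == cfg

    def test_nontargeted_fraction_flags(self):
        cfg = study_variant(
            StudyConfig(seed=26),
            n_animals=3,
            n_males=2,
            jumps_per_height=(30, 30, 30),
            nontargeted_fraction=0.2,
        )
        rng = np.random.default_rng(26)
        _, assign = sample_study(cfg, rng)
        frac = 1.0 - assign["targeted"].mean()
        assert 0.05 < frac < 0.4
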