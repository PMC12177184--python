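"""End-to-end orchestration: simulate -> analyze -> summarize -> test -> report.

Each stage is a thin composition of the library modules; the pipeline adds
bookkeeping only (seeding, file layout, the run manifest and a structured
log of per-stage counts).  A single study seed fans out to per-stage child
seeds through ``numpy.random.SeedSequence``, so any stage can be re-run in
isolation and two runs with the same config produce identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import EventDetectionError
from .energetics import kinetic_energies
from .flight import SUCCESS_TOLERANCE, feasibility_map
from .kinematics import analyze_jump
from .beam import null_hypothesis_test, posture_arm
from .stats import (
    pairwise_height_tests,
    recovery_report,
    stratified_permutation_test,
    summarize,
)
from .synth import StudyConfig, SynthStudy, generate_study, load_study
from .trackio import RESULT_COLUMNS, write_results_table

log = logging.getLogger("katyjump")


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    version: str
    n_jumps: int
    n_analyzed: int
    n_excluded_nontargeted: int
    n_failed: int
    files: tuple[str, ...]


def analyze_study(study: SynthStudy) -> tuple[list[dict], list[dict]]:
    """Run the kinematic and energetic analysis on every targeted jump.

    Returns (result rows, excluded rows).  Non-targeted jumps (no
    motion-parallax swaying observed before the jump) are excluded up
    front, mirroring the study's inclusion rule; detection failures are
    recorded, not fatal.
    """
    results: list[dict] = []
    excluded: list[dict] = []
    for traj in study.trajectories:
        if not traj.targeted:
            excluded.append({"jump_id": traj.jump_id, "reason": "non-targeted"})
            continue
        morph = study.morphometrics[traj.animal_id]
        try:
            kin = analyze_jump(traj, morph)
        except EventDetectionError as exc:
            excluded.append({"jump_id": traj.jump_id, "reason": str(exc)})
            continue
        # energies from the whole-jump average velocities, as in the study
        budget = kinetic_energies(
            morph.mass, morph.body_length, kin.lv_secant, kin.av_secant
        )
        results.append(
            {
                "jump_id": kin.jump_id,
                "animal_id": kin.animal_id,
                "target_height": kin.target_height,
                "lv": kin.lv_secant,
                "av": kin.av_secant,
                "ftj_rest": kin.ftj_rest,
                "ftj_takeoff": kin.ftj_takeoff,
                "air_time": kin.air_time,
                "E_trans": budget.E_trans,
                "E_rot": budget.E_rot,
                "rot_fraction": budget.rot_fraction,
                "lv_takeoff": kin.lv_takeoff,
                "av_takeoff": kin.av_takeoff,
                "total_rotation": kin.total_rotation,
                "body_angle_takeoff": kin.body_angle_takeoff,
                "stationary_frame": kin.events.stationary_frame,
                "takeoff_frame": kin.events.takeoff_frame,
                "contact_frame": kin.events.contact_frame,
                "posture_arm": posture_arm(
                    kin.lv_secant, abs(kin.av_secant), morph.body_length
                ),
                "landed": True,
            }
        )
    return results, excluded


RECOVERY_RESPONSES = {
    "lv": ("lv", "lv"),
    "av": ("av", "av"),
    "ftj_rest": ("ftj_rest", "ftj_rest"),
    "ftj_takeoff": ("ftj_takeoff", "ftj_takeoff"),
    "air_time": ("air_time", "air_time"),
}


def recovery_bounds(config: StudyConfig) -> dict[str, float]:
    """Tracking-noise-propagated absolute error bounds (3 sigma scale).

    Rough first-order propagation of the coordinate noise through each
    estimator, floored by the frame-discretization error; used only for the
    coverage column of the recovery report.
    """
    sd = config.tracking_noise_sd
    L = config.body_length_mean
    t_min = 0.010  # s, conservative shortest flight
    lv_b = 3 * sd / t_min + 0.05  # secant noise + endpoint discretization
    av_b = 3 * (np.sqrt(2) * 2 * sd / L) / t_min + 1.0
    ftj_b = np.degrees(3 * np.sqrt(2) * sd / (0.25 * L)) + 1.0
    air_b = 3.0 / config.frame_rate
    return {
        "lv": float(lv_b),
        "av": float(av_b),
        "ftj_rest": float(ftj_b),
        "ftj_takeoff": float(ftj_b),
        "air_time": float(air_b),
    }


def run_pipeline(
    config: StudyConfig,
    out_dir,
    seed: int | None = None,
    n_permutations: int = 999,
) -> RunManifest:
    """Execute every stage and write all result tables under ``out_dir``."""
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    files: list[str] = []
    try:
        # stage 1: simulate
        study_dir = generate_study(config, out / "study")
        study = load_study(study_dir)
        log.info("simulate: %d jumps, %d animals", len(study.trajectories),
                 len(study.morphometrics))

        # stage 2: analyze
        results, excluded = analyze_study(study)
        n_failed = sum(1 for e in excluded if e["reason"] != "non-targeted")
        n_nontarg = len(excluded) - n_failed
        assert len(results) + len(excluded) == len(study.trajectories)
        write_results_table(results, out / "results.csv")
        files.append("results.csv")
        pd.DataFrame(excluded, columns=["jump_id", "reason"]).to_csv(
            out / "excluded.csv", index=False
        )
        files.append("excluded.csv")
        log.info(
            "analyze: %d in = %d analyzed + %d non-targeted + %d failed",
            len(study.trajectories), len(results), n_nontarg, n_failed,
        )

        res_df = pd.DataFrame(results)

        # stage 3: summarize
        ss = np.random.SeedSequence(config.seed).spawn(4)
        stat_seed = int(ss[3].generate_state(1)[0] % (2**31))
        summaries = []
        for resp in ("lv", "av", "ftj_rest", "ftj_takeoff", "air_time",
                     "rot_fraction"):
            s = summarize(res_df[resp].to_numpy(),
                          res_df["target_height"].to_numpy())
            s.insert(0, "response", resp)
            summaries.append(s)
        pd.concat(summaries, ignore_index=True).to_csv(
            out / "summary.csv", index=False
        )
        files.append("summary.csv")

        # stage 4: permutation tests for a height effect
        test_rows = []
        for resp in ("lv", "av", "ftj_rest", "ftj_takeoff"):
            res = stratified_permutation_test(
                res_df[resp].to_numpy(),
                res_df["target_height"].to_numpy(),
                res_df["animal_id"].to_numpy(),
                n_permutations=n_permutations,
                seed=stat_seed,
            )
            test_rows.append(
                {"response": resp, "statistic": res.observed_statistic,
                 "p": res.p, "n_permutations": res.n_permutations}
            )
            pw = pairwise_height_tests(
                res_df[resp].to_numpy(),
                res_df["target_height"].to_numpy(),
                res_df["animal_id"].to_numpy(),
                n_permutations=n_permutations,
                seed=stat_seed,
            )
            pw.insert(0, "response", resp)
            pw.to_csv(out / f"pairwise_{resp}.csv", index=False)
            files.append(f"pairwise_{resp}.csv")
        pd.DataFrame(test_rows).to_csv(out / "height_tests.csv", index=False)
        files.append("height_tests.csv")

        # stage 5: beam-model null-hypothesis test on (lv, av)
        corr = null_hypothesis_test(
            list(zip(res_df["lv"], res_df["av"].abs())),
            n_permutations=n_permutations,
            seed=stat_seed,
        )
        pd.DataFrame(
            [{"slope_sign": corr.slope_sign,
              "rank_correlation": corr.rank_correlation, "p": corr.p,
              "n_permutations": corr.n_permutations}]
        ).to_csv(out / "beam_null_test.csv", index=False)
        files.append("beam_null_test.csv")
        log.info("beam null test: sign %+d, rho %.3f, p %.4f",
                 corr.slope_sign, corr.rank_correlation, corr.p)

        # stage 6: recovery against generator truth (analyzed jumps only)
        truth_df = study.truth_frame()
        truth_df = truth_df[truth_df["jump_id"].isin(res_df["jump_id"])]
        rec = recovery_report(
            res_df, truth_df, RECOVERY_RESPONSES,
            recovery_bounds(config),
        )
        rec.to_csv(out / "recovery.csv", index=False)
        files.append("recovery.csv")

        # stage 7: feasibility map for the tallest target
        speeds = np.linspace(0.5, 3.0, 50)
        avs = np.linspace(0.0, 120.0, 50)
        grid = feasibility_map(
            max(config.heights), speeds, avs,
            elevation_angle=config.elevation_angle,
            y0=config.takeoff_height, g=config.gravity,
            success_tolerance=SUCCESS_TOLERANCE,
        )
        fm = pd.DataFrame(grid.astype(int),
                          index=np.round(speeds, 4), columns=np.round(avs, 3))
        fm.to_csv(out / "feasibility_map.csv")
        files.append("feasibility_map.csv")

        manifest = RunManifest(
            config_hash=config.config_hash(),
            seed=config.seed,
            version=__version__,
            n_jumps=len(study.trajectories),
            n_analyzed=len(results),
            n_excluded_nontargeted=n_nontarg,
            n_failed=n_failed,
            files=tuple(files),
        )
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(
                {**asdict(manifest), "files": list(manifest.files),
                 "config": config.to_dict()},
                fh, sort_keys=True,
            )
        log.info("pipeline complete: %s", out)
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
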