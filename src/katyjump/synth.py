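"""Synthetic targeted-jump study generator.

Emulates the full digitized dataset the analysis pipeline expects: a roster
of animals with morphometrics, a per-height jump assignment table, and one
tracked four-point trajectory per jump, with known ground truth stored
alongside.  The generative model mirrors the study design:

* 7 animals (5 male, 2 female), masses uniform on the studied range,
  hind-leg length a fixed 1.37 multiple of body length;
* 151 jumps split 47 / 53 / 51 across 50, 75 and 100 mm overhead targets,
  filmed at 2000 Hz;
* per-height fixed effects on whole-jump linear velocity, angular velocity
  and femorotibial (FTJ) joint angles equal to the study's reported means,
  with between-jump spread recovered from the reported standard errors
  (SD = SE * sqrt(n)) and split between an animal-level random intercept
  and a residual;
* each jump rendered as rest -> constant-acceleration stance -> ballistic
  flight with constant rotation, plus i.i.d. Gaussian tracking noise on
  every coordinate.

The sampled linear velocity is the *whole-jump secant* velocity (the
quantity the study reports); the generator solves for the take-off speed
that realizes it under the ballistic contact geometry.  Draws that cannot
reach the target are resampled above the reachability bound, and the
pre-truncation location is adjusted so the post-truncation mean still
equals the configured mean (mean-preserving truncation).

Ground truth is written next to the data but never read by the analysis
pipeline; it exists purely for parameter-recovery testing.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field, fields, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .trackio import (
    Morphometrics,
    TrackedTrajectory,
    WIDE_COLUMNS,
    write_morphometrics,
    write_trajectory,
)

RESPONSES = ("lv", "av", "ftj_rest", "ftj_takeoff")


@dataclass(frozen=True)
class StudyConfig:
    """Generative parameters of the synthetic study.

    Defaults reproduce the study conditions: animal roster, jump counts,
    per-height response means and standard errors, camera rate.  Parameters
    the study does not report (resting FTJ angle level, animal-intercept
    share of the variance, take-off height, tracking noise) are documented
    package choices; see docs/methods.md.
    """

    n_animals: int = 7
    n_males: int = 5
    mass_range: tuple[float, float] = (6.78e-5, 8.22e-5)  # kg
    body_length_mean: float = 0.0146  # m
    body_length_sd: float = 0.001  # m
    leg_body_ratio: float = 1.37  # hind leg length / body length
    heights: tuple[float, ...] = (0.050, 0.075, 0.100)  # m
    jumps_per_height: tuple[int, ...] = (47, 53, 51)
    frame_rate: float = 2000.0  # Hz

    # per-height fixed effects (means) and their standard errors
    lv_mean: tuple[float, ...] = (1.40, 1.55, 1.79)  # m/s, whole-jump secant
    lv_se: tuple[float, ...] = (0.07, 0.08, 0.12)
    av_mean: tuple[float, ...] = (47.36, 38.10, 31.80)  # rad/s
    av_se: tuple[float, ...] = (3.51, 2.43, 3.18)
    ftj_takeoff_mean: tuple[float, ...] = (129.0, 136.5, 144.0)  # deg
    ftj_takeoff_se: tuple[float, ...] = (4.39, 3.50, 2.65)
    ftj_rest_mean: tuple[float, ...] = (100.0, 100.0, 100.0)  # deg
    ftj_rest_se: tuple[float, ...] = (3.0, 3.0, 3.0)

    animal_sd_fraction: float = 0.5  # share of between-jump SD in the intercept
    tracking_noise_sd: float = 1e-4  # m, i.i.d. on every coordinate
    takeoff_height: float = 0.024  # m, centroid height at take-off (y0)
    rest_height: float = 0.008  # m, centroid height at rest
    rest_frames: int = 12
    elevation_angle: float = math.pi / 2  # rad; default vertical jumps
    gravity: float = 9.81  # m s^-2
    nontargeted_fraction: float = 0.0  # share of jumps flagged non-targeted
    leg_fold_angle: float = 60.0  # deg, FTJ angle once folded in flight
    leg_hold_s: float = 0.003  # s after take-off before folding begins
    leg_fold_s: float = 0.015  # s over which the leg folds
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_animals < 1 or not (0 <= self.n_males <= self.n_animals):
            problems.append("n_animals/n_males")
        if not (0 < self.mass_range[0] <= self.mass_range[1]):
            problems.append("mass_range")
        if self.body_length_mean <= 0 or self.body_length_sd < 0:
            problems.append("body_length")
        if self.leg_body_ratio <= 0:
            problems.append("leg_body_ratio")
        nh = len(self.heights)
        if nh == 0 or any(h <= self.takeoff_height for h in self.heights):
            problems.append("heights (must exceed takeoff_height)")
        if len(self.jumps_per_height) != nh or any(
            n < 1 for n in self.jumps_per_height
        ):
            problems.append("jumps_per_height")
        for name in ("lv", "av", "ftj_takeoff", "ftj_rest"):
            if len(getattr(self, f"{name}_mean")) != nh:
                problems.append(f"{name}_mean")
            if len(getattr(self, f"{name}_se")) != nh or any(
                s < 0 for s in getattr(self, f"{name}_se")
            ):
                problems.append(f"{name}_se")
        if not (0 <= self.animal_sd_fraction <= 1):
            problems.append("animal_sd_fraction")
        if self.tracking_noise_sd < 0:
            problems.append("tracking_noise_sd")
        if not (0 <= self.rest_height < self.takeoff_height):
            problems.append("rest_height/takeoff_height")
        if self.rest_frames < 1:
            problems.append("rest_frames")
        if not (0 < self.elevation_angle <= math.pi / 2):
            problems.append("elevation_angle")
        if self.frame_rate <= 0 or self.gravity <= 0:
            problems.append("frame_rate/gravity")
        if not (0 <= self.nontargeted_fraction < 1):
            problems.append("nontargeted_fraction")
        if problems:
            raise ValueError(f"invalid StudyConfig fields: {', '.join(problems)}")

    # -- serialization ------------------------------------------------------
    _TUPLE_FIELDS = (
        "mass_range",
        "heights",
        "jumps_per_height",
        "lv_mean",
        "lv_se",
        "av_mean",
        "av_se",
        "ftj_takeoff_mean",
        "ftj_takeoff_se",
        "ftj_rest_mean",
        "ftj_rest_se",
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (list(v) if k in self._TUPLE_FIELDS else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown StudyConfig fields: {sorted(unknown)}")
        kwargs = {
            k: (tuple(v) if k in cls._TUPLE_FIELDS else v) for k, v in d.items()
        }
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    # -- derived quantities -------------------------------------------------
    def between_jump_sd(self, response: str, height_index: int) -> float:
        """Between-jump SD recovered from the reported SE: SD = SE sqrt(n)."""
        se = getattr(self, f"{response}_se")[height_index]
        return se * math.sqrt(self.jumps_per_height[height_index])

    def response_mean(self, response: str, height_index: int) -> float:
        return getattr(self, f"{response}_mean")[height_index]

    def lv_lower_bound(self, height: float) -> float:
        """Reachability floor for the secant speed toward a given target.

        A whole-jump secant below roughly half the ballistic minimum speed
        sqrt(2 g (h - y0)) admits no take-off speed that reaches the target;
        0.6 of that minimum keeps a safety margin for the contact geometry.
        """
        return 0.6 * math.sqrt(
            2.0 * self.gravity * (height - self.takeoff_height)
        )

    def response_lower_bound(self, response: str, height: float) -> float:
        if response == "lv":
            return self.lv_lower_bound(height)
        if response == "av":
            return 0.5
        return 5.0  # FTJ angles, degrees


@dataclass
class JumpTruth:
    """Generative ground truth for one jump; never read by the pipeline."""

    jump_id: str
    animal_id: str
    sex: str
    target_height: float
    targeted: bool
    lv: float  # whole-jump secant linear velocity, m/s
    av: float  # constant angular velocity, rad/s
    ftj_rest: float  # deg
    ftj_takeoff: float  # deg
    # realized by synthesize_trajectory:
    v0: float = math.nan  # take-off speed, m/s
    theta_takeoff: float = math.nan  # body angle at take-off, rad
    stance_time: float = math.nan  # s
    air_time: float = math.nan  # s, continuous contact time
    total_rotation: float = math.nan  # rad, av * air_time
    stationary_frame: int = -1
    takeoff_frame: int = -1
    contact_frame: int = -1


@dataclass
class SynthStudy:
    """In-memory synthetic study: everything the pipeline consumes."""

    config: StudyConfig
    morphometrics: dict[str, Morphometrics]
    assignments: pd.DataFrame  # jump_id, animal_id, sex, target_height, targeted
    truths: list[JumpTruth]
    trajectories: list[TrackedTrajectory]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.truths])


# ---------------------------------------------------------------------------
# sampling


def _trunc_mean(loc: float, sd: float, lower: float) -> float:
    """Mean of N(loc, sd) truncated below at ``lower`` (closed form)."""
    a = (lower - loc) / sd
    z = 0.5 * math.erfc(a / math.sqrt(2.0))
    if z < 1e-300:
        return lower
    phi = math.exp(-0.5 * a * a) / math.sqrt(2.0 * math.pi)
    return loc + sd * phi / z


@lru_cache(maxsize=65536)
def _mean_preserving_loc(mu: float, sd: float, lower: float) -> float:
    """Location mu' such that a N(mu', sd) truncated below at ``lower`` has
    mean ``mu``.  Returns mu unchanged when truncation is negligible.
    Cached: repeated (animal, height, response) combinations recur."""
    if sd == 0.0 or (mu - lower) / sd > 6.0:
        return mu
    lo, hi = mu - 8.0 * sd, mu
    if _trunc_mean(lo, sd, lower) > mu:  # mean target too close to the bound
        return lo
    return float(
        brentq(lambda m: _trunc_mean(m, sd, lower) - mu, lo, hi, xtol=1e-12)
    )


def sample_study(
    config: StudyConfig, rng: np.random.Generator
) -> tuple[dict[str, Morphometrics], pd.DataFrame]:
    """Animal roster with morphometrics and the per-jump assignment table.

    Masses are uniform over the configured range; body lengths positive
    truncated-normal; hind-leg length exactly ``leg_body_ratio`` times body
    length, split evenly between femur and tibia.  Jumps are assigned
    round-robin over animals within each height.
    """
    config.validate()
    morphs: dict[str, Morphometrics] = {}
    sexes: dict[str, str] = {}
    for i in range(config.n_animals):
        aid = f"a{i + 1:02d}"
        mass = float(rng.uniform(*config.mass_range))
        bl = 0.0
        while bl <= 0.0:
            bl = float(rng.normal(config.body_length_mean, config.body_length_sd))
        leg = config.leg_body_ratio * bl
        morphs[aid] = Morphometrics(
            animal_id=aid,
            mass=mass,
            body_length=bl,
            femur_length=leg / 2.0,
            tibia_length=leg / 2.0,
        )
        sexes[aid] = "M" if i < config.n_males else "F"

    animal_ids = list(morphs)
    rows = []
    counter = 0
    for h, n in zip(config.heights, config.jumps_per_height):
        for k in range(n):
            aid = animal_ids[counter % len(animal_ids)]
            counter += 1
            rows.append(
                {
                    "jump_id": f"j{int(round(h * 1000)):03d}_{k + 1:03d}",
                    "animal_id": aid,
                    "sex": sexes[aid],
                    "target_height": h,
                    "targeted": bool(rng.random() >= config.nontargeted_fraction),
                }
            )
    return morphs, pd.DataFrame(rows)


def sample_animal_effects(
    config: StudyConfig, rng: np.random.Generator, animal_ids: list[str]
) -> dict[str, dict[str, float]]:
    """Standardized (N(0,1)) animal intercepts per response; the realized
    intercept at a height is z * animal_sd_fraction * between-jump SD."""
    return {
        aid: {resp: float(rng.standard_normal()) for resp in RESPONSES}
        for aid in animal_ids
    }


def sample_jump_parameters(
    config: StudyConfig,
    animal_id: str,
    target_height: float,
    rng: np.random.Generator,
    animal_z: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """One draw of (lv, av, ftj_rest, ftj_takeoff) for a jump.

    The intended conditional mean is height mean + z_animal * f * SD, with
    residual SD = SD * sqrt(1 - f^2) so the total between-jump SD is SD
    (f = animal_sd_fraction).  Draws below the physical floor for the
    response are resampled (bounded retries), and the residual location is
    pre-shifted so the post-truncation conditional mean still equals the
    intended one -- the marginal mean over animals therefore equals the
    configured height mean.
    """
    hi = config.heights.index(target_height)
    out: dict[str, float] = {}
    frac = config.animal_sd_fraction
    for resp in RESPONSES:
        mu = config.response_mean(resp, hi)
        sd = config.between_jump_sd(resp, hi)
        lower = config.response_lower_bound(resp, target_height)
        z = 0.0 if animal_z is None else animal_z.get(resp, 0.0)
        target_cond = mu + z * frac * sd  # intended conditional mean
        resid_sd = sd * math.sqrt(max(0.0, 1.0 - frac**2))
        if resid_sd == 0.0:
            value = max(target_cond, lower)
        else:
            base = _mean_preserving_loc(target_cond, resid_sd, lower)
            value = base + rng.normal(0.0, resid_sd)
            tries = 0
            while value < lower and tries < 1000:
                value = base + rng.normal(0.0, resid_sd)
                tries += 1
            if value < lower:
                value = lower
        if resp.startswith("ftj"):
            value = min(value, 175.0)
        out[resp] = value
    return out


# ---------------------------------------------------------------------------
# trajectory synthesis


def _contact_time(
    v0: float,
    av: float,
    theta_to: float,
    y0: float,
    target: float,
    half_body: float,
    elevation: float,
    g: float,
) -> float | None:
    """First time after take-off at which the head reaches the target, or
    None when it never does before returning to the ground."""
    vy = v0 * math.sin(elevation)
    vx = v0 * math.cos(elevation)
    if vy <= 0:
        return None
    t_ground = (vy + math.sqrt(vy**2 + 2.0 * g * y0)) / g
    tau = np.linspace(0.0, t_ground, 512)
    head_y = (
        y0
        + vy * tau
        - 0.5 * g * tau**2
        + half_body * np.sin(theta_to + av * tau)
    )
    above = head_y >= target
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return 0.0

    def f(t: float) -> float:
        return (
            y0
            + vy * t
            - 0.5 * g * t**2
            + half_body * math.sin(theta_to + av * t)
            - target
        )

    return float(brentq(f, tau[i - 1], tau[i], xtol=1e-12))


def solve_takeoff_speed(
    lv_secant: float,
    av: float,
    config: StudyConfig,
    target_height: float,
    body_length: float,
) -> tuple[float, float]:
    """Take-off speed whose ballistic flight realizes a given secant speed.

    Returns (v0, air_time).  The secant is the centroid displacement from
    take-off to head-target contact over the elapsed time; it increases
    with v0, so a bracketing bisection suffices.  Raises RuntimeError when
    no speed realizes the requested secant (a configuration bug: the draw
    should have been truncated above the reachability floor).
    """
    e = config.elevation_angle
    g = config.gravity
    y0 = config.takeoff_height
    d_st = (y0 - config.rest_height) / math.sin(e)
    half_body = body_length / 2.0

    def secant(v0: float) -> float | None:
        theta_to = av * d_st / v0  # av * t_st / 2 with t_st = 2 d_st / v0
        T = _contact_time(v0, av, theta_to, y0, target_height, half_body, e, g)
        if T is None or T <= 0:
            return None
        vy, vx = v0 * math.sin(e), v0 * math.cos(e)
        dx = vx * T
        dy = vy * T - 0.5 * g * T**2
        return math.hypot(dx, dy) / T

    hi = max(2.0 * lv_secant, 1.0)
    for _ in range(60):
        s = secant(hi)
        if s is not None and s >= lv_secant:
            break
        hi *= 1.3
    else:
        raise RuntimeError(
            f"no take-off speed realizes secant {lv_secant:.3f} m/s to "
            f"{target_height} m (internal generator error)"
        )
    lo = min(lv_secant, hi / 2.0)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        s = secant(mid)
        if s is None or s < lv_secant:
            lo = mid
        else:
            hi = mid
    v0 = hi
    theta_to = av * d_st / v0
    T = _contact_time(v0, av, theta_to, y0, target_height, half_body, e, g)
    return v0, float(T)


def _isoceles_knee(
    a: np.ndarray, t: np.ndarray, gamma_deg: float
) -> np.ndarray:
    """FTJ vertex realizing interior angle ``gamma_deg`` between rays to the
    abdomen point ``a`` and tarsus point ``t`` (isoceles construction)."""
    gamma = math.radians(gamma_deg)
    mid = 0.5 * (a + t)
    chord = t - a
    c = float(np.linalg.norm(chord))
    if c == 0.0:
        raise ValueError("abdomen and tarsus coincide; knee undefined")
    u = chord / c
    n = np.array([-u[1], u[0]])  # +90 deg perpendicular
    h = (c / 2.0) / math.tan(gamma / 2.0)
    return mid + n * h


def synthesize_trajectory(
    truth: JumpTruth,
    morph: Morphometrics,
    config: StudyConfig,
    rng: np.random.Generator,
) -> TrackedTrajectory:
    """Render one jump as a four-point tracked trajectory.

    Three phases at the camera rate: rest (body level, leg at the resting
    FTJ angle, tarsus on the substrate), stance (constant linear and angular
    acceleration to the take-off state, FTJ opening linearly with centroid
    displacement, tarsus planted), and ballistic flight with constant
    rotation (leg held briefly at the take-off angle, then folded).  The
    head and abdomen-tip lie exactly body_length apart on the rigid body
    axis; the leg points encode the FTJ angle, not anatomical segment
    lengths.  Gaussian tracking noise is added to every coordinate, and the
    realized event frames and air time are written back into ``truth``.
    """
    L = morph.body_length
    e = config.elevation_angle
    g = config.gravity
    fps = config.frame_rate
    y0 = config.takeoff_height
    target = truth.target_height

    v0, T = solve_takeoff_speed(truth.lv, truth.av, config, target, L)
    d_st = (y0 - config.rest_height) / math.sin(e)
    t_st = 2.0 * d_st / v0
    theta_to = truth.av * t_st / 2.0
    t_rest = config.rest_frames / fps
    t_takeoff = t_rest + t_st

    truth.v0 = v0
    truth.theta_takeoff = theta_to
    truth.stance_time = t_st
    truth.air_time = T
    truth.total_rotation = truth.av * T

    u_jump = np.array([math.cos(e), math.sin(e)])
    c_rest = np.array([0.0, config.rest_height])
    p0 = c_rest + u_jump * d_st  # centroid at take-off
    vx, vy = v0 * math.cos(e), v0 * math.sin(e)
    accel = v0 / t_st
    half = L / 2.0

    takeoff_frame = math.ceil(t_takeoff * fps - 1e-9)
    contact_frame = takeoff_frame + max(
        1, math.ceil((t_takeoff + T) * fps - 1e-9) - takeoff_frame
    )
    n_frames = contact_frame + 1

    times = np.arange(n_frames) / fps
    cent = np.empty((n_frames, 2))
    theta = np.empty(n_frames)
    gamma = np.empty(n_frames)

    for k, t in enumerate(times):
        if t < t_rest:  # rest
            cent[k] = c_rest
            theta[k] = 0.0
            gamma[k] = truth.ftj_rest
        elif t < t_takeoff:  # stance
            tau = t - t_rest
            dist = 0.5 * accel * tau**2
            cent[k] = c_rest + u_jump * dist
            theta[k] = 0.5 * (truth.av / t_st) * tau**2
            gamma[k] = truth.ftj_rest + (
                truth.ftj_takeoff - truth.ftj_rest
            ) * (dist / d_st)
        else:  # flight
            tau = t - t_takeoff
            cent[k] = p0 + np.array(
                [vx * tau, vy * tau - 0.5 * g * tau**2]
            )
            theta[k] = theta_to + truth.av * tau
            if tau <= config.leg_hold_s:
                gamma[k] = truth.ftj_takeoff
            else:
                frac = min(1.0, (tau - config.leg_hold_s) / config.leg_fold_s)
                gamma[k] = truth.ftj_takeoff + frac * (
                    config.leg_fold_angle - truth.ftj_takeoff
                )

    axis = np.column_stack([np.cos(theta), np.sin(theta)])
    head = cent + half * axis
    abdomen = cent - half * axis

    ftj = np.empty((n_frames, 2))
    tarsus = np.empty((n_frames, 2))
    tarsus_ground = np.array([abdomen[0, 0] - 0.2 * L, 0.0])
    for k, t in enumerate(times):
        if t < t_takeoff:
            tarsus[k] = tarsus_ground
        else:
            beta = theta[k] - 2.2  # folded leg direction in the body frame
            tarsus[k] = abdomen[k] + 0.75 * L * np.array(
                [math.cos(beta), math.sin(beta)]
            )
        ftj[k] = _isoceles_knee(abdomen[k], tarsus[k], gamma[k])

    coords = np.hstack([head, abdomen, ftj, tarsus])
    if config.tracking_noise_sd > 0:
        coords = coords + rng.normal(0.0, config.tracking_noise_sd, coords.shape)

    df = pd.DataFrame(
        np.column_stack([np.arange(n_frames), times, coords]),
        columns=WIDE_COLUMNS,
    )
    df["frame"] = df["frame"].astype(int)

    truth.stationary_frame = config.rest_frames - 1
    truth.takeoff_frame = takeoff_frame
    truth.contact_frame = contact_frame

    return TrackedTrajectory(
        jump_id=truth.jump_id,
        animal_id=truth.animal_id,
        sex=truth.sex,
        target_height=target,
        frame_rate=fps,
        data=df,
        targeted=truth.targeted,
    )


# ---------------------------------------------------------------------------
# whole-study generation


def simulate_study(config: StudyConfig) -> SynthStudy:
    """Generate the complete study in memory; deterministic given the seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_roster, s_effects, s_jumps = ss.spawn(3)
    rng_roster = np.random.default_rng(s_roster)
    morphs, assignments = sample_study(config, rng_roster)
    effects = sample_animal_effects(
        config, np.random.default_rng(s_effects), list(morphs)
    )
    jump_seeds = s_jumps.spawn(len(assignments))

    truths: list[JumpTruth] = []
    trajectories: list[TrackedTrajectory] = []
    for row, seed in zip(assignments.itertuples(), jump_seeds):
        rng = np.random.default_rng(seed)
        params = sample_jump_parameters(
            config, row.animal_id, row.target_height, rng,
            animal_z=effects[row.animal_id],
        )
        truth = JumpTruth(
            jump_id=row.jump_id,
            animal_id=row.animal_id,
            sex=row.sex,
            target_height=row.target_height,
            targeted=row.targeted,
            **params,
        )
        trajectories.append(synthesize_trajectory(truth, morphs[row.animal_id], config, rng))
        truths.append(truth)
    return SynthStudy(
        config=config,
        morphometrics=morphs,
        assignments=assignments,
        truths=truths,
        trajectories=trajectories,
    )


def generate_study(config: StudyConfig, out_dir) -> Path:
    """Write a full synthetic study to disk; re-running byte-reproduces it.

    Layout: ``trajectories/<jump_id>.csv`` (one per jump, wide CSV),
    ``morphometrics.csv``, ``assignments.csv``, ``truth.csv`` and
    ``manifest.yaml`` (config plus its hash).
    """
    out = Path(out_dir)
    (out / "trajectories").mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    for traj in study.trajectories:
        write_trajectory(traj, out / "trajectories" / f"{traj.jump_id}.csv")
    write_morphometrics(list(study.morphometrics.values()), out / "morphometrics.csv")
    study.assignments.to_csv(out / "assignments.csv", index=False)
    study.truth_frame().to_csv(out / "truth.csv", index=False)
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash()}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def load_study(study_dir) -> SynthStudy:
    """Read a generated study back from disk (trajectories lazily parsed)."""
    from .trackio import read_morphometrics, read_trajectory

    study_dir = Path(study_dir)
    with open(study_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    config = StudyConfig.from_dict(manifest["config"])
    morphs = read_morphometrics(study_dir / "morphometrics.csv")
    assignments = pd.read_csv(study_dir / "assignments.csv")
    truth_df = pd.read_csv(study_dir / "truth.csv")
    truths = [JumpTruth(**rec) for rec in truth_df.to_dict(orient="records")]
    trajectories = [
        read_trajectory(
            study_dir / "trajectories" / f"{row.jump_id}.csv",
            scale=1.0,
            frame_rate=config.frame_rate,
            jump_id=row.jump_id,
            animal_id=row.animal_id,
            sex=row.sex,
            target_height=row.target_height,
            targeted=bool(row.targeted),
        )
        for row in assignments.itertuples()
    ]
    return SynthStudy(
        config=config,
        morphometrics=morphs,
        assignments=assignments,
        truths=truths,
        trajectories=trajectories,
    )


def study_variant(config: StudyConfig, **changes) -> StudyConfig:
    """Convenience: a validated copy of a config with fields replaced."""
    cfg = replace(config, **changes)
    cfg.validate()
    return cfg
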