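"""Rigid-beam null model coupling linear and angular take-off velocity.

During leg extension the legs apply a force F at a distance l (the moment
arm) from the centre of mass of a uniform rod of mass m and length L.
Newton's second law gives the linear acceleration a = F/m, and the balance
of moments F l = (m L^2 / 12) alpha gives the angular acceleration, so

    a / alpha = v / w = L^2 / (12 l)

with the velocity ratio following because both accelerations act over the
same stance duration under a fixed posture.  The testable consequence: if
an animal modulates jump height by force alone (posture, hence l, held
fixed), linear and angular take-off velocity are proportional and hence
positively correlated.  A negative correlation across jumps falsifies the
force-only explanation and implies posture change.

The correlation test here is a rank (Spearman) correlation with a seeded
permutation p-value -- a deliberately assumption-light test of the sign
prediction, not a mixed-effects fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from ._errors import PureTranslationError


@dataclass(frozen=True)
class BeamModel:
    """Uniform rod of mass ``mass`` and length ``rod_length`` with the leg
    force applied ``moment_arm`` from the centre (all SI units)."""

    mass: float
    rod_length: float
    moment_arm: float

    def __post_init__(self) -> None:
        if not (self.mass > 0 and self.rod_length > 0):
            raise ValueError("mass and rod_length must be > 0")
        if self.moment_arm < 0:
            raise ValueError("moment_arm must be >= 0")
        if self.moment_arm > self.rod_length / 2:
            raise ValueError("moment_arm must not exceed rod_length / 2")


def coupling_ratio(model: BeamModel) -> float:
    """L^2 / (12 l): ratio of linear to angular acceleration (and velocity).

    Has units of length (m per rad).  A zero moment arm means the force
    passes through the centre of mass -- pure translation, infinite ratio --
    signalled distinctly.
    """
    if model.moment_arm == 0.0:
        raise PureTranslationError(
            "moment arm is zero: pure translation, coupling ratio infinite"
        )
    return model.rod_length**2 / (12.0 * model.moment_arm)


def predicted_av(lv: float, model: BeamModel) -> float:
    """Angular velocity the beam model predicts for a take-off speed lv.

    av = 12 l lv / L^2 -- linear in lv with positive slope.
    """
    if lv < 0:
        raise ValueError("lv must be >= 0")
    return 12.0 * model.moment_arm * lv / model.rod_length**2


def posture_arm(lv: float, av: float, rod_length: float) -> float:
    """Moment arm consistent with an observed (lv, av) pair: l = av L^2/(12 lv).

    The effective posture parameter of the beam model; inverse of
    :func:`predicted_av` at fixed rod length.
    """
    if not lv > 0:
        raise ValueError("lv must be > 0 (arm undefined at zero speed)")
    if av < 0:
        raise ValueError("av must be >= 0")
    if not rod_length > 0:
        raise ValueError("rod_length must be > 0")
    return av * rod_length**2 / (12.0 * lv)


@dataclass(frozen=True)
class CorrelationTest:
    slope_sign: int  # -1, 0 or +1: sign of the rank correlation
    rank_correlation: float  # Spearman rho of av on lv
    p: float  # two-sided permutation p-value (add-one rule)
    n_permutations: int
    seed: int


def null_hypothesis_test(
    pairs: Sequence[tuple[float, float]],
    n_permutations: int = 999,
    seed: int = 0,
) -> CorrelationTest:
    """Sign and significance of the lv-av correlation across jumps.

    Under the beam-model null (force-only modulation) the sign is +1.
    The p-value is a two-sided permutation test on |rho|: av values are
    randomly re-paired with lv values ``n_permutations`` times and the
    add-one rule (b + 1) / (m + 1) applied.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (lv, av) pairs")
    lv, av = arr[:, 0], arr[:, 1]
    if np.all(lv == lv[0]) or np.all(av == av[0]):
        raise ValueError("constant lv or av: rank correlation undefined")
    rho = float(sps.spearmanr(lv, av).statistic)

    rng = np.random.default_rng(seed)
    # rank once; permuting ranks is equivalent to permuting values
    r_lv = sps.rankdata(lv)
    r_av = sps.rankdata(av)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(r_av))
        rho_p = np.corrcoef(r_lv, r_av[perm])[0, 1]
        if abs(rho_p) >= abs(rho) - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return CorrelationTest(
        slope_sign=int(np.sign(rho)),
        rank_correlation=rho,
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
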