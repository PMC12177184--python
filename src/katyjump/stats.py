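"""Descriptive summaries and animal-stratified permutation inference.

The study design is repeated-measures: every animal jumps at every target
height, so naive between-height tests would confound animal identity with
height.  The test here removes each animal's own mean (within-animal
centering), uses the variance of the per-height means of the centered
values as the statistic, and builds the null by permuting height labels
*within* each animal -- the exchangeability that holds when height has no
effect for any animal.  P-values use the add-one rule (b + 1) / (m + 1),
so the smallest attainable p is 1 / (m + 1).

Pairwise post hoc contrasts are the same test restricted to two heights,
with Holm correction across the pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    n_permutations: int
    p: float
    seed: int
    n_used: int  # observations from animals with >= 2 heights


def summarize(
    values: np.ndarray, heights: np.ndarray, animals: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-height n, mean and standard error (SE = SD / sqrt(n)).

    Groups with a single observation get SE = NaN and are flagged.
    Row order of the inputs does not matter.
    """
    values = np.asarray(values, dtype=float)
    heights = np.asarray(heights)
    if values.size == 0:
        raise ValueError("empty input")
    df = pd.DataFrame({"height": heights, "value": values})
    rows = []
    for h, grp in df.groupby("height", sort=True):
        n = len(grp)
        mean = float(grp["value"].mean())
        se = float(grp["value"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(
            {"height": h, "n": n, "mean": mean, "se": se, "flagged": n < 2}
        )
    return pd.DataFrame(rows)


def _height_mean_variance(centered: np.ndarray, height_codes: np.ndarray,
                          n_heights: int) -> float:
    sums = np.bincount(height_codes, weights=centered, minlength=n_heights)
    counts = np.bincount(height_codes, minlength=n_heights)
    means = sums / counts
    return float(np.var(means))


def stratified_permutation_test(
    values: np.ndarray,
    heights: np.ndarray,
    animals: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """Upper-tail permutation test for a height effect, stratified by animal.

    Statistic: variance across heights of the per-height means of
    within-animal-centered values.  Null: height labels permuted within each
    animal.  Animals observed at fewer than two heights carry no information
    about the contrast and are excluded with a warning.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    values = np.asarray(values, dtype=float)
    heights = np.asarray(heights)
    animals = np.asarray(animals)
    if not (len(values) == len(heights) == len(animals)):
        raise ValueError("values, heights, animals must have equal length")
    if len(np.unique(heights)) < 2:
        raise ValueError("need at least 2 distinct heights")

    keep = np.ones(len(values), dtype=bool)
    for aid in np.unique(animals):
        mask = animals == aid
        if len(np.unique(heights[mask])) < 2:
            keep &= ~mask
            warnings.warn(
                f"animal {aid!r} observed at a single height; excluded",
                stacklevel=2,
            )
    values, heights, animals = values[keep], heights[keep], animals[keep]
    if len(values) == 0:
        raise ValueError("no animal observed at >= 2 heights")

    uniq_h, h_codes = np.unique(heights, return_inverse=True)
    n_h = len(uniq_h)

    centered = values.copy()
    groups: list[np.ndarray] = []
    for aid in np.unique(animals):
        idx = np.nonzero(animals == aid)[0]
        centered[idx] -= centered[idx].mean()
        groups.append(idx)

    obs = _height_mean_variance(centered, h_codes, n_h)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm_codes = h_codes.copy()
    for _ in range(n_permutations):
        for idx in groups:
            perm_codes[idx] = h_codes[idx][rng.permutation(len(idx))]
        stat = _height_mean_variance(centered, perm_codes, n_h)
        if stat >= obs - 1e-18:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermutationResult(
        observed_statistic=obs,
        n_permutations=n_permutations,
        p=float(p),
        seed=seed,
        n_used=len(values),
    )


def pairwise_height_tests(
    values: np.ndarray,
    heights: np.ndarray,
    animals: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise height contrasts with Holm-adjusted p-values."""
    heights = np.asarray(heights)
    uniq = np.unique(heights)
    rows = []
    for k, (h1, h2) in enumerate(itertools.combinations(uniq, 2)):
        mask = (heights == h1) | (heights == h2)
        res = stratified_permutation_test(
            np.asarray(values)[mask],
            heights[mask],
            np.asarray(animals)[mask],
            n_permutations=n_permutations,
            seed=seed + k,
        )
        rows.append({"height_1": h1, "height_2": h2, "p_raw": res.p,
                     "statistic": res.observed_statistic})
    df = pd.DataFrame(rows)
    # Holm step-down
    order = np.argsort(df["p_raw"].to_numpy())
    m = len(df)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * df["p_raw"].iloc[i])
        adj[i] = min(1.0, running)
    df["p_holm"] = adj
    return df


def recovery_report(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
    responses: dict[str, tuple[str, str]],
    bounds: dict[str, float],
) -> pd.DataFrame:
    """Bias, RMSE and bound-coverage of pipeline estimates vs ground truth.

    ``responses`` maps a report name to (estimate column, truth column);
    ``bounds`` gives the per-response absolute error bound used for the
    coverage column (fraction of jumps with |error| < bound).  Frames are
    matched on ``jump_id``; unmatched ids are an error.
    """
    est_ids = set(estimates["jump_id"])
    tru_ids = set(truth["jump_id"])
    if est_ids != tru_ids:
        missing = sorted(est_ids ^ tru_ids)
        raise ValueError(f"unmatched jump ids: {missing[:10]}")
    merged = estimates.merge(truth, on="jump_id", suffixes=("_est", "_tru"))
    height_col = (
        "target_height_est"
        if "target_height_est" in merged.columns
        else "target_height"
    )
    rows = []
    for name, (est_col, tru_col) in responses.items():
        ec = est_col if est_col in merged.columns else f"{est_col}_est"
        tc = tru_col if tru_col in merged.columns else f"{tru_col}_tru"
        err = merged[ec] - merged[tc]
        for h, grp in merged.assign(err=err).groupby(height_col):
            e = grp["err"].to_numpy()
            rows.append(
                {
                    "response": name,
                    "height": h,
                    "n": len(e),
                    "bias": float(np.mean(e)),
                    "rmse": float(np.sqrt(np.mean(e**2))),
                    "coverage": float(np.mean(np.abs(e) < bounds[name])),
                }
            )
    return pd.DataFrame(rows)
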