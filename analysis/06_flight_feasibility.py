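#!/usr/bin/env python
"""Map the (take-off speed, spin) combinations that land inverted.

For each overhead target height, ballistic flight plus constant rotation
defines a narrow feasible ridge: the spin must complete a half turn in
exactly the flight time the speed allows.  The required spin rises with
speed at fixed height (shorter flights) and falls with height at fixed
ascent margin (longer flights) -- the trade-off the animals navigate.
Also writes a sampled example flight path per height.
"""

import math
from pathlib import Path

import numpy as np
import pandas as pd

from katyjump import (
    TakeoffState,
    feasibility_map,
    required_av,
    simulate_flight,
    time_to_height,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

Y0 = 0.024  # m, take-off height of the centre of mass
HEIGHTS = (0.050, 0.075, 0.100)
MEAN_SPEEDS = (1.40, 1.55, 1.79)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    speeds = np.linspace(0.5, 3.0, 60)
    avs = np.linspace(0.0, 160.0, 60)
    frames = []
    for h in HEIGHTS:
        grid = feasibility_map(h, speeds, avs, y0=Y0)
        fm = pd.DataFrame(grid.astype(int), index=np.round(speeds, 4),
                          columns=np.round(avs, 2))
        fm.insert(0, "target_height", h)
        frames.append(fm)
        n_feasible = int(grid.sum())
        print(f"target {h:.3f} m: {n_feasible}/{grid.size} grid cells feasible")
    pd.concat(frames).to_csv(RESULTS / "feasibility_map.csv")

    rows = []
    for h, v in zip(HEIGHTS, MEAN_SPEEDS):
        t = time_to_height(v, math.pi / 2, Y0, h)
        av_star = required_av(t)
        res = simulate_flight(
            TakeoffState(speed=v, initial_height=Y0, angular_velocity=av_star),
            h,
        )
        rows.append(
            {
                "target_height": h,
                "takeoff_speed": v,
                "air_time_ms": res.air_time * 1e3,
                "required_av_rad_s": av_star,
                "rotation_at_contact_rad": res.rotation_at_contact,
                "success": res.success,
            }
        )
        pd.DataFrame(res.sampled_path, columns=["t", "x", "y", "theta"]).to_csv(
            SCRATCH / f"example_flight_{int(h * 1000)}mm.csv", index=False
        )
    req = pd.DataFrame(rows)
    req.to_csv(RESULTS / "required_spin.csv", index=False)
    for r in req.itertuples(index=False):
        print(
            f"  at the mean {r.takeoff_speed} m/s to {r.target_height:.3f} m: "
            f"air time {r.air_time_ms:.1f} ms -> inverted landing needs "
            f"{r.required_av_rad_s:.1f} rad/s (rotation {r.rotation_at_contact_rad:.2f} rad)"
        )
    print(f"tables -> {RESULTS}/feasibility_map.csv, required_spin.csv")


if __name__ == "__main__":
    main()
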