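"""Reading and writing digitized point-tracking data.

A jump is recorded as a time series of four labeled body points digitized
from lateral high-speed video: the head, the tip of the abdomen, the
femorotibial joint (FTJ) of a hind leg, and the hind tarsus (foot).  Files
are plain comma-separated text in one of two layouts:

* **wide** -- one row per frame with columns
  ``frame,t,head_x,head_y,abdomen_x,abdomen_y,ftj_x,ftj_y,tarsus_x,tarsus_y``
* **long** -- one row per (frame, point) with columns ``frame,t,point,x,y``

Coordinates are converted to metres on read via a ``scale`` factor
(metres per file unit), so files digitized in millimetres or in calibrated
pixel units are handled uniformly.  The y axis points upward (gravity acts
in -y); files in image coordinates must be flipped (``y_flip=True``).
Frame indices are 0-based; the time column is recomputed from the frame
rate and only checked for consistency.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import TrajectoryFormatError

POINT_LABELS = ("head", "abdomen", "ftj", "tarsus")
#: accepted aliases in long-layout ``point`` columns
_LABEL_ALIASES = {
    "head": "head",
    "abdomen": "abdomen",
    "abdomen_tip": "abdomen",
    "ftj": "ftj",
    "tarsus": "tarsus",
}

WIDE_COLUMNS = ["frame", "t"] + [
    f"{label}_{ax}" for label in POINT_LABELS for ax in ("x", "y")
]
LONG_COLUMNS = ["frame", "t", "point", "x", "y"]

STUDY_HEIGHTS = (0.050, 0.075, 0.100)


@dataclass
class Morphometrics:
    """Per-animal body measurements, SI units.

    ``body_length`` runs from the base of the antenna to the most distal
    point of the abdomen; hind-leg length is the sum of femur and tibia.
    """

    animal_id: str
    mass: float  # kg
    body_length: float  # m
    femur_length: float  # m
    tibia_length: float  # m

    def __post_init__(self) -> None:
        for name in ("mass", "body_length", "femur_length", "tibia_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"Morphometrics.{name} must be > 0")

    @property
    def leg_length(self) -> float:
        return self.femur_length + self.tibia_length


@dataclass
class TrackedTrajectory:
    """One digitized jump: four labeled points over consecutive frames.

    ``data`` is a wide-layout DataFrame with the columns of
    :data:`WIDE_COLUMNS`, sorted by frame, coordinates in metres.
    """

    jump_id: str
    animal_id: str
    sex: str
    target_height: float  # m, height of the overhead target above substrate
    frame_rate: float  # Hz
    data: pd.DataFrame
    targeted: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if not self.target_height > 0:
            raise ValueError("target_height must be > 0")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        self.data = self.data.reset_index(drop=True)
        frames = self.data["frame"].to_numpy()
        if len(frames) and np.any(np.diff(frames) <= 0):
            raise TrajectoryFormatError(
                f"{self.jump_id}: non-monotonic frame index"
            )

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy()

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, recomputed from the frame rate."""
        return self.frames / self.frame_rate

    def point(self, label: str) -> np.ndarray:
        """(n_frames, 2) array of x, y for one labeled point."""
        if label not in POINT_LABELS:
            raise KeyError(f"unknown point label {label!r}")
        return self.data[[f"{label}_x", f"{label}_y"]].to_numpy()

    def coords(self, label: str, frame: int) -> np.ndarray:
        """x, y of one point at one frame index position."""
        self._check_frame(frame)
        row = self.data.iloc[frame]
        return np.array([row[f"{label}_x"], row[f"{label}_y"]])

    def _check_frame(self, frame: int) -> None:
        if not (0 <= frame < self.n_frames):
            raise IndexError(
                f"{self.jump_id}: frame {frame} outside 0..{self.n_frames - 1}"
            )


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str], path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() & out[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise TrajectoryFormatError(
                f"{path}: unparseable numeric in column {col!r} at line {line}"
            )
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise TrajectoryFormatError(
                f"{path}: missing value in column {col!r} at line {line}"
            )
        out[col] = vals
    return out


def _long_to_wide(df: pd.DataFrame, path) -> pd.DataFrame:
    labels = df["point"].map(
        lambda s: _LABEL_ALIASES.get(str(s).strip().lower())
    )
    if labels.isna().any():
        bad = df["point"][labels.isna()].iloc[0]
        raise TrajectoryFormatError(f"{path}: unknown point label {bad!r}")
    df = df.assign(point=labels)
    wide_rows = []
    for frame, grp in df.groupby("frame", sort=True):
        row = {"frame": frame, "t": grp["t"].iloc[0]}
        present = set(grp["point"])
        for label in POINT_LABELS:
            if label not in present:
                raise TrajectoryFormatError(
                    f"{path}: frame {int(frame)} missing point {label!r}"
                )
            sub = grp[grp["point"] == label].iloc[0]
            row[f"{label}_x"] = sub["x"]
            row[f"{label}_y"] = sub["y"]
        wide_rows.append(row)
    return pd.DataFrame(wide_rows, columns=WIDE_COLUMNS)


def read_trajectory(
    path,
    scale: float = 1.0,
    frame_rate: float = 2000.0,
    *,
    jump_id: str | None = None,
    animal_id: str = "unknown",
    sex: str = "M",
    target_height: float = 0.100,
    targeted: bool = True,
    y_flip: bool = False,
) -> TrackedTrajectory:
    """Read a trajectory CSV (wide or long layout) into SI units.

    Parameters
    ----------
    scale
        Metres per file coordinate unit (0.001 for files in mm).
    frame_rate
        Camera frame rate in Hz; authoritative over the file's ``t`` column.
    y_flip
        Negate y on read, for files stored in image coordinates (y down).
    """
    if not scale > 0:
        raise ValueError("scale must be > 0")
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise TrajectoryFormatError(f"{path}: {exc}") from exc
    raw.columns = [c.strip() for c in raw.columns]

    if set(LONG_COLUMNS).issubset(raw.columns):
        raw = _coerce_numeric(raw, ["frame", "t", "x", "y"], path)
        wide = _long_to_wide(raw, path)
    elif set(WIDE_COLUMNS).issubset(raw.columns):
        wide = _coerce_numeric(raw[WIDE_COLUMNS], WIDE_COLUMNS, path)
    else:
        raise TrajectoryFormatError(
            f"{path}: header matches neither wide nor long layout"
        )

    frames = wide["frame"].to_numpy()
    if np.any(frames != np.round(frames)):
        raise TrajectoryFormatError(f"{path}: non-integer frame index")
    if len(frames) > 1 and np.any(np.diff(frames) <= 0):
        raise TrajectoryFormatError(f"{path}: non-monotonic frame index")
    wide["frame"] = frames.astype(int)

    coord_cols = [c for c in WIDE_COLUMNS if c not in ("frame", "t")]
    wide[coord_cols] = wide[coord_cols] * scale
    if y_flip:
        ycols = [c for c in coord_cols if c.endswith("_y")]
        wide[ycols] = -wide[ycols]
    wide["t"] = wide["frame"] / frame_rate

    if jump_id is None:
        jump_id = getattr(path, "stem", None) or str(path)
    return TrackedTrajectory(
        jump_id=str(jump_id),
        animal_id=animal_id,
        sex=sex,
        target_height=target_height,
        frame_rate=frame_rate,
        data=wide,
        targeted=targeted,
    )


def write_trajectory(traj: TrackedTrajectory, path) -> None:
    """Write a trajectory as wide-layout CSV in SI units, loss-free.

    Floats use shortest round-trip representation, so
    ``read_trajectory(write_trajectory(t)) == t`` to better than 1e-9 m.
    """
    df = traj.data[WIDE_COLUMNS]
    df.to_csv(path, index=False, float_format=None)


def write_results_table(records: Sequence[Mapping], path) -> None:
    """Write per-jump analysis rows to CSV.

    All records must share one key set; SI units throughout except
    ``rot_fraction`` which is a percentage.
    """
    records = list(records)
    if not records:
        pd.DataFrame(columns=RESULT_COLUMNS).to_csv(path, index=False)
        return
    keys = list(records[0].keys())
    for i, rec in enumerate(records):
        if list(rec.keys()) != keys:
            raise ValueError(
                f"record {i} has keys {sorted(rec.keys())}, "
                f"expected {sorted(keys)}"
            )
    pd.DataFrame.from_records(records, columns=keys).to_csv(path, index=False)


#: canonical column order of the per-jump results table
RESULT_COLUMNS = [
    "jump_id",
    "animal_id",
    "target_height",
    "lv",
    "av",
    "ftj_rest",
    "ftj_takeoff",
    "air_time",
    "E_trans",
    "E_rot",
    "rot_fraction",
]


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_morphometrics(morphs: Sequence[Morphometrics], path) -> None:
    pd.DataFrame(
        [
            {
                "animal_id": m.animal_id,
                "mass": m.mass,
                "body_length": m.body_length,
                "femur_length": m.femur_length,
                "tibia_length": m.tibia_length,
            }
            for m in morphs
        ]
    ).to_csv(path, index=False)


def read_morphometrics(path) -> dict[str, Morphometrics]:
    df = pd.read_csv(path)
    return {
        str(r.animal_id): Morphometrics(
            animal_id=str(r.animal_id),
            mass=float(r.mass),
            body_length=float(r.body_length),
            femur_length=float(r.femur_length),
            tibia_length=float(r.tibia_length),
        )
        for r in df.itertuples()
    }
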