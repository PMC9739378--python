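"""The 17-keypoint body model and 3D motion sequences.

World frame convention used throughout the package: right-handed, Y up,
millimetre units, gait progressing along +Z. The subject faces +Z, so the
right half of the body lies on the world +X side.

Keypoints: head (H), neck (N), shoulders (SR, SL), elbows (ER, EL),
wrists (WR, WL), pelvis centre (HC), hips (HR, HL), knees (KR, KL),
ankles (AR, AL) and feet (FR, FL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

KEYPOINT_NAMES: tuple[str, ...] = (
    "H", "N", "SR", "SL", "ER", "EL", "WR", "WL",
    "HC", "HR", "HL", "KR", "KL", "AR", "AL", "FR", "FL",
)
KEYPOINT_INDEX: dict[str, int] = {n: i for i, n in enumerate(KEYPOINT_NAMES)}
N_KEYPOINTS = len(KEYPOINT_NAMES)

#: Anatomical keypoint groups used for per-region error reporting.
KEYPOINT_GROUPS: dict[str, tuple[str, ...]] = {
    "feet": ("FR", "FL"),
    "ankles": ("AR", "AL"),
    "knees": ("KR", "KL"),
    "hips": ("HR", "HL"),
    "pelvis": ("HC",),
    "neck": ("N",),
    "head": ("H",),
    "wrists": ("WR", "WL"),
    "elbows": ("ER", "EL"),
    "shoulders": ("SR", "SL"),
}

#: Bone connectivity used for rendering stick figures.
SKELETON_EDGES: tuple[tuple[str, str], ...] = (
    ("H", "N"), ("N", "SR"), ("N", "SL"),
    ("SR", "ER"), ("ER", "WR"), ("SL", "EL"), ("EL", "WL"),
    ("N", "HC"), ("HC", "HR"), ("HC", "HL"),
    ("HR", "KR"), ("KR", "AR"), ("AR", "FR"),
    ("HL", "KL"), ("KL", "AL"), ("AL", "FL"),
)


@dataclass(frozen=True)
class KeypointSet:
    """One body pose: a (17, 3) array of world coordinates in mm."""

    xyz: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.xyz, dtype=float)
        if arr.shape != (N_KEYPOINTS, 3):
            raise InputError(
                f"KeypointSet requires shape ({N_KEYPOINTS}, 3), got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InputError("KeypointSet coordinates must be finite")
        object.__setattr__(self, "xyz", arr)

    def get(self, name: str) -> np.ndarray:
        """Return the 3-vector of the named keypoint."""
        try:
            return self.xyz[KEYPOINT_INDEX[name]]
        except KeyError:
            raise InputError(f"unknown keypoint name {name!r}") from None


@dataclass
class MotionSequence:
    """Time-ordered keypoint positions: (n_frames, 17, 3) in mm."""

    data: np.ndarray
    frame_rate: float
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3 or arr.shape[1:] != (N_KEYPOINTS, 3):
            raise InputError(
                f"MotionSequence requires shape (n, {N_KEYPOINTS}, 3), got {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise InputError("MotionSequence requires at least one frame")
        if not np.all(np.isfinite(arr)):
            raise InputError("MotionSequence coordinates must be finite")
        if not self.frame_rate > 0:
            raise InputError("frame_rate must be positive")
        self.data = arr

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def frame(self, i: int) -> KeypointSet:
        return KeypointSet(self.data[i])

    def keypoint(self, name: str) -> np.ndarray:
        """(n_frames, 3) trajectory of one keypoint."""
        return self.data[:, KEYPOINT_INDEX[name], :]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame_index, time_s, keypoint, x_mm, y_mm, z_mm."""
        n = self.n_frames
        idx = np.repeat(np.arange(n), N_KEYPOINTS)
        return pd.DataFrame(
            {
                "frame_index": idx,
                "time_s": idx / self.frame_rate,
                "keypoint": np.tile(np.array(KEYPOINT_NAMES), n),
                "x_mm": self.data[:, :, 0].ravel(),
                "y_mm": self.data[:, :, 1].ravel(),
                "z_mm": self.data[:, :, 2].ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float | None = None,
                 subject_id: str = "subject") -> "MotionSequence":
        """Read a trajectory CSV (columns as written by :meth:`to_csv`)."""
        df = pd.read_csv(path)
        required = {"frame_index", "keypoint", "x_mm", "y_mm", "z_mm"}
        if not required.issubset(df.columns):
            raise InputError(f"trajectory CSV must have columns {sorted(required)}")
        if frame_rate is None:
            if "time_s" in df.columns and df["frame_index"].max() > 0:
                sub = df.drop_duplicates("frame_index").sort_values("frame_index")
                dt = np.diff(sub["time_s"].to_numpy())
                if len(dt) == 0 or not np.all(dt > 0):
                    raise InputError("cannot infer frame rate from time_s column")
                frame_rate = 1.0 / float(np.mean(dt))
            else:
                frame_rate = 1.0
        frames = sorted(df["frame_index"].unique())
        if frames != list(range(len(frames))):
            raise InputError("frame_index must be contiguous from 0")
        wide = df.pivot_table(
            index="frame_index", columns="keypoint",
            values=["x_mm", "y_mm", "z_mm"], sort=False,
        )
        missing = set(KEYPOINT_NAMES) - set(df["keypoint"].unique())
        if missing:
            raise InputError(f"trajectory CSV is missing keypoints {sorted(missing)}")
        data = np.stack(
            [
                np.column_stack(
                    [wide[("x_mm", k)], wide[("y_mm", k)], wide[("z_mm", k)]]
                )
                for k in KEYPOINT_NAMES
            ],
            axis=1,
        )
        return cls(data=data, frame_rate=float(frame_rate), subject_id=subject_id)
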