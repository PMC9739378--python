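"""Joint-angle computation from the 17-keypoint body model.

Eleven clinically named angles are derived per frame:

* shoulder flexion / abduction — intrinsic Z-X'-Y'' Euler angles of the
  shoulder (humerus) frame relative to the trunk frame;
* elbow flexion — angle between upper arm and forearm (0° = straight);
* neck flexion / side bend — inclination of the neck vector N→H expressed
  in the trunk frame, projected onto the sagittal / frontal plane;
* hip abduction, knee flexion, femur flexion, femur abduction — thigh and
  shank segment angles relative to the trunk frame;
* pelvis abduction — obliquity of the hip line against the world
  horizontal plane;
* ankle flexion — shank-to-foot angle minus 90° (0° = neutral).

Trunk frame (origin at the pelvis centre HC): Y along HC→N, X perpendicular
to both Y and the hip line (anterior for an upright subject), Z = X x Y
(mediolateral, pointing to the subject's left... see sign conventions below).

Sign conventions: flexion is positive anteriorly (toward trunk +X),
abduction positive away from the midline, neck side bend positive toward
the subject's left. These choices are symmetric between the synthetic-gait
generator and this analyzer, which is what RMSE-based comparisons require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, InputError
from .keypoints import KeypointSet, MotionSequence

log = logging.getLogger(__name__)

#: Canonical names of the 11 reported joint angles.
ANGLE_NAMES: tuple[str, ...] = (
    "shoulder_flexion",
    "shoulder_abduction",
    "elbow_flexion",
    "neck_side_bend",
    "neck_flexion",
    "hip_abduction",
    "knee_flexion",
    "femur_flexion",
    "femur_abduction",
    "pelvis_abduction",
    "ankle_flexion",
)

#: Angles computed once per frame (no left/right variant).
UNSIDED_ANGLES: frozenset = frozenset({"neck_side_bend", "neck_flexion", "pelvis_abduction"})

_EPS = 1e-12


@dataclass(frozen=True)
class Frame3D:
    """A right-handed orthonormal coordinate frame embedded in world space."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "X", "Y", "Z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        M = self.basis
        if not np.allclose(M.T @ M, np.eye(3), atol=1e-9):
            raise GeometryError("Frame3D axes are not orthonormal")
        if np.linalg.det(M) < 0:
            raise GeometryError("Frame3D axes are not right-handed")

    @property
    def basis(self) -> np.ndarray:
        """3x3 matrix with X, Y, Z as columns."""
        return np.column_stack([self.X, self.Y, self.Z])

    def to_local(self, v: np.ndarray) -> np.ndarray:
        """Express a world-space direction in this frame's axes."""
        return self.basis.T @ np.asarray(v, float)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < _EPS:
        raise GeometryError(f"zero-length vector while constructing {what}")
    return v / n


def trunk_frame(kp: KeypointSet) -> Frame3D:
    """Trunk coordinate system: origin HC, Y = HC→N, X ⊥ (Y, hip line)."""
    hc, n = kp.get("HC"), kp.get("N")
    hr, hl = kp.get("HR"), kp.get("HL")
    Y = _unit(n - hc, "trunk frame (HC to N)")
    hip = hl - hr
    X = np.cross(Y, hip)
    nx = np.linalg.norm(X)
    if nx < _EPS * max(np.linalg.norm(hip), 1.0) or np.linalg.norm(hip) < _EPS:
        raise GeometryError("trunk frame degenerate: hip line parallel to HC->N")
    X = X / nx
    Z = np.cross(X, Y)
    return Frame3D(origin=hc, X=X, Y=Y, Z=Z)


def shoulder_frame(kp: KeypointSet, side: str, trunk: Frame3D | None = None) -> Frame3D:
    """Humerus coordinate system: origin S, Y along E→S, X ⊥ arm plane.

    A fully straight arm leaves the humerus-forearm plane undefined; in that
    case the trunk X axis resolves it (logged). Without a trunk frame the
    degenerate case raises :class:`GeometryError`.
    """
    s, e, w = (kp.get(k + _side_suffix(side)) for k in ("S", "E", "W"))
    Y = _unit(s - e, f"{side} shoulder frame (E to S)")
    X = np.cross(Y, w - e)
    nx = np.linalg.norm(X)
    if nx < 1e-9 * max(np.linalg.norm(w - e), 1.0):
        if trunk is None:
            raise GeometryError(
                f"{side} arm is straight; cannot orient the shoulder frame"
            )
        log.debug("straight %s arm: resolving shoulder frame with trunk X", side)
        X = trunk.X - np.dot(trunk.X, Y) * Y   # trunk X projected off the humerus
        X = _unit(X, f"{side} shoulder frame fallback")
    else:
        X = X / nx
    Z = np.cross(X, Y)
    return Frame3D(origin=s, X=X, Y=Y, Z=Z)


def _side_suffix(side: str) -> str:
    if side in ("right", "R"):
        return "R"
    if side in ("left", "L"):
        return "L"
    raise InputError(f"side must be 'left' or 'right', got {side!r}")


# ---------------------------------------------------------------------------
# Euler decomposition


def euler_zxy(Rrel: np.ndarray) -> tuple[float, float, float]:
    """Intrinsic Z-X'-Y'' Euler angles (degrees) of a rotation matrix.

    Returns (z, x, y) such that ``Rrel = Rz(z) @ Rx(x) @ Ry(y)`` with x in
    [-90°, 90°]. At gimbal lock (|x| = 90°) y is set to 0 and the residual
    rotation assigned to z.
    """
    R = np.asarray(Rrel, dtype=float).reshape(3, 3)
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
        raise GeometryError("euler_zxy input is not orthonormal")
    sx = np.clip(R[2, 1], -1.0, 1.0)
    x = np.arcsin(sx)
    if abs(sx) > 1.0 - 1e-12:
        # gimbal lock: only z +/- y observable
        z = np.arctan2(R[1, 0], R[0, 0])
        y = 0.0
    else:
        z = np.arctan2(-R[0, 1], R[1, 1])
        y = np.arctan2(-R[2, 0], R[2, 2])
    return float(np.degrees(z)), float(np.degrees(x)), float(np.degrees(y))


def compose_zxy(z_deg: float, x_deg: float, y_deg: float) -> np.ndarray:
    """Inverse of :func:`euler_zxy`: Rz(z) @ Rx(x) @ Ry(y), angles in degrees."""
    z, x, y = np.radians([z_deg, x_deg, y_deg])
    cz, sz, cx, sx, cy, sy = np.cos(z), np.sin(z), np.cos(x), np.sin(x), np.cos(y), np.sin(y)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    Rx = np.array([[1.0, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1.0, 0], [-sy, 0, cy]])
    return Rz @ Rx @ Ry


# ---------------------------------------------------------------------------
# Individual angles


def vector_angle_pair(u, v) -> float:
    """Unsigned angle between two 3-vectors in degrees, clamped to [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise GeometryError("vector_angle_pair requires non-zero vectors")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def shoulder_angles(trunk: Frame3D, shoulder: Frame3D) -> tuple[float, float]:
    """(flexion, abduction): Z and X of the ZXY-decomposed relative rotation."""
    Rrel = trunk.basis.T @ shoulder.basis
    z, x, _y = euler_zxy(Rrel)
    return z, x


def elbow_flexion(kp: KeypointSet, side: str) -> float:
    """Upper-arm to forearm angle; 0° = straight arm."""
    sfx = _side_suffix(side)
    s, e, w = kp.get("S" + sfx), kp.get("E" + sfx), kp.get("W" + sfx)
    return vector_angle_pair(e - s, w - e)


def neck_angles(kp: KeypointSet, trunk: Frame3D) -> tuple[float, float]:
    """(flexion, side_bend) of the neck vector N→H in trunk axes.

    Flexion: signed angle of the sagittal (X-Y) projection from +Y toward +X.
    Side bend: signed angle of the frontal (Z-Y) projection from +Y toward +Z.
    """
    h = trunk.to_local(kp.get("H") - kp.get("N"))
    if np.hypot(h[0], h[1]) < _EPS or np.hypot(h[2], h[1]) < _EPS:
        raise GeometryError("neck vector degenerate for plane projection")
    flexion = np.degrees(np.arctan2(h[0], h[1]))
    side_bend = np.degrees(np.arctan2(h[2], h[1]))
    return float(flexion), float(side_bend)


def lower_limb_angles(kp: KeypointSet, trunk: Frame3D, side: str) -> dict[str, float]:
    """Six lower-limb angles for one side (pelvis obliquity is side-free).

    knee flexion: thigh-shank angle; femur flexion/abduction: signed thigh
    inclination in the trunk sagittal/frontal plane from -Y; hip abduction:
    unsigned frontal-plane thigh angle from -Y; pelvis abduction: signed hip
    line elevation against the world horizontal; ankle flexion: shank-foot
    angle minus 90°.
    """
    sfx = _side_suffix(side)
    hip, k = kp.get("H" + sfx), kp.get("K" + sfx)
    a, f = kp.get("A" + sfx), kp.get("F" + sfx)
    hr, hl = kp.get("HR"), kp.get("HL")

    thigh = k - hip
    shank = a - k
    foot = f - a
    knee = vector_angle_pair(thigh, shank)

    t = trunk.to_local(thigh)
    if np.linalg.norm(t) < _EPS:
        raise GeometryError(f"{side} thigh segment degenerate")
    femur_flex = np.degrees(np.arctan2(t[0], -t[1]))
    # abduction: positive away from the midline (right side lies at trunk -Z)
    lat = -t[2] if sfx == "R" else t[2]
    femur_abd = np.degrees(np.arctan2(lat, -t[1]))
    hip_abd = abs(femur_abd)

    hip_line = hl - hr
    nh = np.linalg.norm(hip_line)
    if nh < _EPS:
        raise GeometryError("hip line degenerate")
    pelvis_abd = np.degrees(
        np.arctan2(hip_line[1], np.hypot(hip_line[0], hip_line[2]))
    )

    ankle = vector_angle_pair(shank, foot) - 90.0
    return {
        "hip_abduction": float(hip_abd),
        "knee_flexion": float(knee),
        "femur_flexion": float(femur_flex),
        "femur_abduction": float(femur_abd),
        "pelvis_abduction": float(pelvis_abd),
        "ankle_flexion": float(ankle),
    }


# ---------------------------------------------------------------------------
# Whole-sequence driver


@dataclass
class JointAngleSeries:
    """Per-frame values (degrees) of the 11 joint angles.

    ``values`` has one column per angle name and one row per frame; NaN marks
    frames where the geometry was degenerate. ``side_policy`` records whether
    sided angles come from the left, the right, or the per-frame mean.
    """

    values: pd.DataFrame
    side_policy: str = "mean"
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        if tuple(self.values.columns) != ANGLE_NAMES:
            raise InputError("JointAngleSeries requires exactly the 11 canonical angles")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        long = self.values.reset_index(names="frame_index").melt(
            id_vars="frame_index", var_name="angle_name", value_name="value_deg"
        )
        long["side"] = self.side_policy
        long.to_csv(path, index=False)


def compute_frame_angles(kp: KeypointSet, side: str) -> dict[str, float]:
    """All 11 angles for a single pose; `side` is 'left' or 'right'."""
    trunk = trunk_frame(kp)
    sh = shoulder_frame(kp, side, trunk=trunk)
    flex, abd = shoulder_angles(trunk, sh)
    nflex, nside = neck_angles(kp, trunk)
    out = {
        "shoulder_flexion": flex,
        "shoulder_abduction": abd,
        "elbow_flexion": elbow_flexion(kp, side),
        "neck_side_bend": nside,
        "neck_flexion": nflex,
    }
    out.update(lower_limb_angles(kp, trunk, side))
    return out


def compute_all_angles(seq: MotionSequence, side_policy: str = "mean") -> JointAngleSeries:
    """Apply every angle operation per frame.

    ``side_policy='mean'`` averages the left and right value of each sided
    angle per frame; degenerate frames yield NaN for the affected angles and
    are logged rather than aborting the sequence.
    """
    if side_policy not in ("left", "right", "mean"):
        raise InputError(f"side_policy must be left/right/mean, got {side_policy!r}")
    sides = ("left", "right") if side_policy == "mean" else (side_policy,)
    rows = np.full((seq.n_frames, len(ANGLE_NAMES)), np.nan)
    n_bad = 0
    for i in range(seq.n_frames):
        kp = seq.frame(i)
        per_side = []
        for side in sides:
            try:
                per_side.append(compute_frame_angles(kp, side))
            except GeometryError as exc:
                n_bad += 1
                log.warning("frame %d (%s): %s", i, side, exc)
        if not per_side:
            continue
        for j, name in enumerate(ANGLE_NAMES):
            vals = [d[name] for d in per_side]
            rows[i, j] = vals[0] if name in UNSIDED_ANGLES else float(np.mean(vals))
    if n_bad:
        log.info("%d degenerate side-frames recorded as missing", n_bad)
    df = pd.DataFrame(rows, columns=list(ANGLE_NAMES))
    return JointAngleSeries(values=df, side_policy=side_policy, subject_id=seq.subject_id)
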