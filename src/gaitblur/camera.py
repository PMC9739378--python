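"""Pinhole camera models, ring-rig construction and DLT triangulation.

A :class:`CameraModel` maps world coordinates (mm) to pixels through
``x = K (R X + t)`` followed by perspective division. ``R`` is the
world-to-camera rotation; the camera looks along its +Z axis with +X right
and +Y down (the usual computer-vision convention), so a camera at centre
``C`` has ``t = -R C``.

Lens distortion is deliberately not modelled; calibration files may carry a
``distortion`` field, and any non-zero coefficients raise
:class:`~gaitblur.errors.UnsupportedFeatureError`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError, ProjectionError, UnsupportedFeatureError

_ORTHO_TOL = 1e-8


@dataclass
class CameraModel:
    K: np.ndarray            # 3x3 intrinsics, upper triangular, px
    R: np.ndarray            # 3x3 world-to-camera rotation
    t: np.ndarray            # 3-vector translation, mm
    image_width: int
    image_height: int
    name: str = "camera"

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float).reshape(3, 3)
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(self.K, np.triu(self.K)):
            raise ConfigurationError(f"{self.name}: K must be upper triangular")
        if np.any(np.diag(self.K)[:2] <= 0) or self.K[2, 2] != 1.0:
            raise ConfigurationError(
                f"{self.name}: K needs positive focal lengths and K[2,2] == 1"
            )
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-6):
            raise ConfigurationError(f"{self.name}: R is not orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ConfigurationError(f"{self.name}: R must have det +1")
        if self.image_width < 1 or self.image_height < 1:
            raise ConfigurationError(f"{self.name}: image size must be positive")

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return -self.R.T @ self.t

    @property
    def P(self) -> np.ndarray:
        """3x4 projection matrix K [R | t]."""
        return self.K @ np.hstack([self.R, self.t[:, None]])

    @property
    def principal_point(self) -> np.ndarray:
        return self.K[:2, 2].copy()


def project_point(camera: CameraModel, point, name: str = "point") -> np.ndarray:
    """Project one world point (mm) to sub-pixel image coordinates.

    Raises :class:`ProjectionError` if the point has non-positive depth in
    the camera frame.
    """
    X = np.asarray(point, dtype=float).reshape(3)
    xc = camera.R @ X + camera.t
    if xc[2] <= 0:
        raise ProjectionError(
            f"{name} has non-positive depth ({xc[2]:.1f} mm) in camera {camera.name}"
        )
    uvw = camera.K @ xc
    return uvw[:2] / uvw[2]


def project_points(camera: CameraModel, points: np.ndarray) -> np.ndarray:
    """Vectorised projection of an (n, 3) array; all depths must be positive."""
    X = np.asarray(points, dtype=float).reshape(-1, 3)
    xc = X @ camera.R.T + camera.t
    bad = np.nonzero(xc[:, 2] <= 0)[0]
    if bad.size:
        raise ProjectionError(
            f"{bad.size} point(s) behind camera {camera.name} (first index {bad[0]})"
        )
    uvw = xc @ camera.K.T
    return uvw[:, :2] / uvw[:, 2:3]


def _look_at_rotation(center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World-to-camera rotation for a camera at `center` aimed at `target`."""
    fwd = target - center
    nrm = np.linalg.norm(fwd)
    if nrm == 0:
        raise ConfigurationError("camera centre coincides with its target")
    z = fwd / nrm
    up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    xn = np.linalg.norm(x)
    if xn < 1e-12:
        raise ConfigurationError("camera optical axis is vertical; rig is degenerate")
    x /= xn
    y = np.cross(z, x)
    return np.stack([x, y, z])


def generate_camera_rig(
    n_cameras: int = 4,
    radius: float = 3000.0,
    height: float = 1200.0,
    image_size: tuple[int, int] = (1920, 1080),
    focal_px: float = 1500.0,
    target: np.ndarray | None = None,
) -> list[CameraModel]:
    """Place cameras evenly on a horizontal circle, aimed at the volume centre.

    `target` is the capture-volume centre (defaults to (0, height, 0), i.e.
    the optical axes stay horizontal); principal point at the image centre.
    """
    if n_cameras < 1:
        raise ConfigurationError("n_cameras must be >= 1")
    if radius <= 0 or focal_px <= 0:
        raise ConfigurationError("radius and focal_px must be positive")
    w, h = image_size
    tgt = np.array([0.0, height, 0.0]) if target is None else np.asarray(target, float)
    K = np.array(
        [[focal_px, 0.0, (w - 1) / 2.0],
         [0.0, focal_px, (h - 1) / 2.0],
         [0.0, 0.0, 1.0]]
    )
    cams = []
    for i in range(n_cameras):
        theta = 2.0 * np.pi * i / n_cameras + np.pi / n_cameras
        C = np.array([radius * np.cos(theta), height, radius * np.sin(theta)])
        R = _look_at_rotation(C, tgt)
        cams.append(
            CameraModel(K=K, R=R, t=-R @ C, image_width=w, image_height=h,
                        name=f"cam{i}")
        )
    return cams


def triangulate_dlt(cameras: list[CameraModel], pixels) -> np.ndarray:
    """Linear (DLT) triangulation of one point from >= 2 views.

    `pixels` is an (n_cameras, 2) array of observed image coordinates.
    """
    px = np.asarray(pixels, dtype=float).reshape(-1, 2)
    if len(cameras) < 2 or px.shape[0] != len(cameras):
        raise InputError("triangulation needs >= 2 cameras with matching pixels")
    rows = []
    for cam, (u, v) in zip(cameras, px):
        P = cam.P
        rows.append(u * P[2] - P[0])
        rows.append(v * P[2] - P[1])
    A = np.stack(rows)
    _, _, vh = np.linalg.svd(A)
    X = vh[-1]
    if abs(X[3]) < 1e-15:
        raise InputError("triangulated point at infinity")
    return X[:3] / X[3]


# ---------------------------------------------------------------------------
# Calibration JSON I/O


def cameras_to_json(cameras: list[CameraModel], path) -> None:
    payload = [
        {
            "name": c.name,
            "width": c.image_width,
            "height": c.image_height,
            "K": c.K.ravel().tolist(),
            "R": c.R.ravel().tolist(),
            "t": c.t.tolist(),
        }
        for c in cameras
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def cameras_from_json(path) -> list[CameraModel]:
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    cams = []
    for entry in payload:
        dist = entry.get("distortion")
        if dist and any(abs(d) > 0 for d in dist):
            raise UnsupportedFeatureError(
                f"camera {entry.get('name', '?')}: non-zero lens distortion is not supported"
            )
        cams.append(
            CameraModel(
                K=np.array(entry["K"], float).reshape(3, 3),
                R=np.array(entry["R"], float).reshape(3, 3),
                t=np.array(entry["t"], float),
                image_width=int(entry["width"]),
                image_height=int(entry["height"]),
                name=str(entry.get("name", "camera")),
            )
        )
    return cams
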