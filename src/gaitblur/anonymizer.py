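"""Geometric face anonymization from calibrated cameras.

The reference head (H) and neck (N) annotations are projected into each
view; a circle centred on the projected head, with radius proportional to
the projected head-neck distance, delimits the face; pixels strictly inside
the circle are replaced by a Gaussian-blurred copy of the image. Pixels
outside the circle are left bit-identical — anonymization is strictly local.

The blur kernel is the separable truncated Gaussian of a given odd size.
When no standard deviation is supplied it follows the conventional
kernel-size rule sigma = 0.3 * ((k - 1) * 0.5 - 1) + 0.8, which gives 4.1
for the default 25x25 kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .camera import CameraModel, project_point
from .errors import ConfigurationError, GeometryError, InputError, ProjectionError
from .keypoints import MotionSequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FaceRegion:
    """Circular image region: sub-pixel centre (x, y) and radius in pixels."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise GeometryError("face region radius must be positive")


@dataclass(frozen=True)
class BlurSpec:
    """Gaussian blur parameters: odd kernel size and optional explicit sigma."""

    kernel_size: int = 25
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be odd and >= 3")
        if self.sigma is not None and not self.sigma > 0:
            raise ConfigurationError("sigma must be positive when given")

    @property
    def effective_sigma(self) -> float:
        return self.sigma if self.sigma is not None else auto_sigma(self.kernel_size)


def auto_sigma(kernel_size: int) -> float:
    """Standard deviation conventionally derived from an odd kernel size.

    ``0.3 * ((k - 1) * 0.5 - 1) + 0.8`` — e.g. 4.1 for k = 25.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ConfigurationError("kernel_size must be a positive odd integer")
    return 0.3 * ((kernel_size - 1) * 0.5 - 1.0) + 0.8


def compute_face_region(head_px, neck_px, scale: float = 1.0) -> FaceRegion:
    """Circle centred on the projected head, radius = scale * ||head - neck||."""
    head = np.asarray(head_px, dtype=float).reshape(2)
    neck = np.asarray(neck_px, dtype=float).reshape(2)
    dist = float(np.linalg.norm(head - neck))
    if dist == 0.0:
        raise GeometryError("head and neck project to the same pixel")
    if not scale > 0:
        raise ConfigurationError("face-region scale must be positive")
    return FaceRegion(center=(float(head[0]), float(head[1])), radius=scale * dist)


def _blur_full(image: np.ndarray, spec: BlurSpec) -> np.ndarray:
    """Separable truncated Gaussian over the whole image, reflective border."""
    radius = (spec.kernel_size - 1) // 2
    img = image.astype(np.float64, copy=False)
    axes = (0, 1)
    return ndimage.gaussian_filter(
        img, sigma=spec.effective_sigma, mode="reflect", radius=radius, axes=axes
    )


def gaussian_blur_disk(image: np.ndarray, region: FaceRegion, spec: BlurSpec) -> np.ndarray:
    """Blur the pixels whose centres lie strictly inside the face circle.

    The rest of the image is returned bit-identical. A region entirely
    outside the image bounds is a logged no-op.
    """
    img = np.asarray(image)
    if img.ndim not in (2, 3):
        raise InputError("image must be 2D grayscale or HxWxC")
    h, w = img.shape[:2]
    cx, cy = region.center
    if cx + region.radius < 0 or cx - region.radius >= w \
            or cy + region.radius < 0 or cy - region.radius >= h:
        log.warning("face region at (%.1f, %.1f) lies outside the image; no-op", cx, cy)
        return img.copy()

    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 < region.radius ** 2
    if not mask.any():
        return img.copy()

    blurred = _blur_full(img, spec)
    out = img.copy()
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        blurred = np.clip(np.rint(blurred), info.min, info.max).astype(img.dtype)
    out[mask] = blurred[mask]
    return out


def anonymize_frame(
    images: list[np.ndarray],
    cameras: list[CameraModel],
    head_mm,
    neck_mm,
    spec: BlurSpec,
    scale: float = 1.0,
) -> list[np.ndarray]:
    """Blur the face region of one frame in every camera view.

    Views where the head or neck has non-positive depth are returned
    unblurred and logged.
    """
    if len(images) != len(cameras):
        raise InputError("one image per camera is required")
    out = []
    for img, cam in zip(images, cameras):
        try:
            head_px = project_point(cam, head_mm, name="H")
            neck_px = project_point(cam, neck_mm, name="N")
            region = compute_face_region(head_px, neck_px, scale=scale)
        except (ProjectionError, GeometryError) as exc:
            log.warning("view %s left unblurred: %s", cam.name, exc)
            out.append(np.asarray(img).copy())
            continue
        out.append(gaussian_blur_disk(img, region, spec))
    return out


def anonymize_sequence(
    images: list[list[np.ndarray]],
    cameras: list[CameraModel],
    reference: MotionSequence,
    spec: BlurSpec = BlurSpec(),
    scale: float = 1.0,
) -> list[list[np.ndarray]]:
    """Anonymize a per-frame, per-camera image set using reference landmarks.

    ``images[i][j]`` is frame ``i`` seen by camera ``j``; the frame count
    must match the reference sequence.
    """
    if len(images) == 0:
        return []
    if len(images) != reference.n_frames:
        raise InputError(
            f"{len(images)} image frames vs {reference.n_frames} reference frames"
        )
    result = []
    for i, frame_images in enumerate(images):
        kp = reference.frame(i)
        result.append(
            anonymize_frame(frame_images, cameras, kp.get("H"), kp.get("N"),
                            spec=spec, scale=scale)
        )
    return result
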