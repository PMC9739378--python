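"""Deterministic stick-figure rendering of a pose through a camera.

Provides the imagery on which the face-blurring stage is exercised: bones as
dark line segments, a filled head disk at the projected head position, and a
uniform background. Rendering is pure rasterisation (scikit-image draw
primitives), so the same pose and camera always produce bit-identical
images.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk, line

from .camera import CameraModel, project_point
from .errors import ProjectionError, RenderError
from .keypoints import KEYPOINT_NAMES, SKELETON_EDGES, KeypointSet

BACKGROUND = (235, 235, 235)
BONE = (40, 40, 40)
HEAD = (90, 60, 50)


def render_subject_image(
    pose: KeypointSet,
    camera: CameraModel,
    canvas: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render one pose as an 8-bit RGB image of shape (height, width, 3).

    `canvas` overrides the camera's image size as (width, height). Raises
    :class:`RenderError` naming the first keypoint with non-positive depth.
    """
    if canvas is None:
        w, h = camera.image_width, camera.image_height
    else:
        w, h = canvas
    px = {}
    for name in KEYPOINT_NAMES:
        try:
            px[name] = project_point(camera, pose.get(name), name=name)
        except ProjectionError as exc:
            raise RenderError(f"cannot render keypoint {name}: {exc}") from exc

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = BACKGROUND

    def clip_rr_cc(rr, cc):
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        return rr[ok], cc[ok]

    for a, b in SKELETON_EDGES:
        r0, c0 = int(round(px[a][1])), int(round(px[a][0]))
        r1, c1 = int(round(px[b][1])), int(round(px[b][0]))
        rr, cc = line(r0, c0, r1, c1)
        rr, cc = clip_rr_cc(rr, cc)
        img[rr, cc] = BONE

    head_px = px["H"]
    neck_px = px["N"]
    radius = max(2.0, 0.6 * float(np.linalg.norm(head_px - neck_px)))
    rr, cc = disk((head_px[1], head_px[0]), radius, shape=(h, w))
    img[rr, cc] = HEAD
    return img
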