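"""Silhouette extraction: background subtraction, morphological cleanup, and
the moving bounding-cube optimisation.

Foreground is whatever differs from a per-camera reference background image.
Per-channel absolute differences are combined with luminance weights into an
intensity-difference image and thresholded (Otsu by default, with a
configurable floor so a frame with no animal does not threshold pure pixel
noise). Cleanup is morphological opening with a square element — 3x3 to keep
the whole animal, 7x7 to additionally strip the thin tail — followed by
removal of connected components whose bounding box fits strictly inside the
element.

The bounding cube tracks the animal so that subtraction and carving run on a
small region of interest instead of the full sensor; on the first frame the
cube is seeded by triangulating the per-camera silhouette centroid rays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .camera import CameraModel, CameraRig, project_points
from .errors import ConfigurationError

__all__ = [
    "BoundingCube",
    "subtract_background",
    "clean_mask",
    "update_bounding_cube",
    "restrict_to_cube",
    "initial_cube",
    "MORPH_WITH_TAIL",
    "MORPH_TAILLESS",
]

MORPH_WITH_TAIL = 3  # px; elements smaller than 3x3 are not animal
MORPH_TAILLESS = 7  # px; elements smaller than 7x7 are not animal body (tail removal)

LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class BoundingCube:
    """Axis-aligned cube tracking the animal: centre (mm) and half-extent (mm)."""

    center: np.ndarray  # (3,)
    half_extent: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if self.half_extent <= 0:
            raise ConfigurationError("bounding cube half-extent must be positive")

    def corners(self) -> np.ndarray:
        signs = np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
        )
        return self.center + self.half_extent * signs


def subtract_background(
    frame: np.ndarray,
    background: np.ndarray,
    threshold: float | str = "auto",
    weights=LUMA_WEIGHTS,
    floor: float = 0.05,
    ignore: np.ndarray | None = None,
) -> np.ndarray:
    """Binary foreground mask from a frame and its background image.

    Arrays may be 2-D grayscale or (H, W, 3) color, float in [0, 1] or
    integer; per-channel absolute differences are weighted and summed into
    an intensity image. ``threshold="auto"`` uses Otsu's method on that
    image with ``floor`` as a lower bound (intensity units of the input
    scale for float images; fractions of 255 are used for uint8 input).
    ``ignore`` is an optional static per-camera mask of pixels never
    counted as foreground (e.g. dark camera lenses visible in the scene).
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ConfigurationError(
            f"frame shape {frame.shape} != background shape {background.shape}"
        )
    diff = np.abs(frame.astype(np.float32) - background.astype(np.float32))
    if np.issubdtype(np.asarray(frame).dtype, np.integer):
        diff /= 255.0
    if diff.ndim == 3:
        w = np.asarray(weights, dtype=np.float32)
        w = w / w.sum()
        intensity = diff @ w
    else:
        intensity = diff
    if threshold == "auto":
        if intensity.max() <= floor:
            thr = floor
        else:
            thr = max(float(threshold_otsu(intensity)), floor)
    else:
        thr = float(threshold)
    out = intensity > thr
    if ignore is not None:
        if ignore.shape != out.shape:
            raise ConfigurationError("ignore mask shape does not match the frame")
        out &= ~np.asarray(ignore, dtype=bool)
    return out


def clean_mask(mask: np.ndarray, mode: str) -> np.ndarray:
    """Remove small isolated elements; ``tailless`` mode also strips the tail.

    Morphological opening with a square element (3x3 for ``with_tail``,
    7x7 for ``tailless``) then removal of connected components whose
    bounding box fits strictly inside the element. Idempotent.
    """
    if mode == "with_tail":
        k = MORPH_WITH_TAIL
    elif mode == "tailless":
        k = MORPH_TAILLESS
    else:
        raise ConfigurationError(f"unknown cleanup mode {mode!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    opened = ndimage.binary_opening(mask, structure=np.ones((k, k), dtype=bool))
    if not opened.any():
        return opened
    labels, n = ndimage.label(opened)
    if n:
        keep = opened.copy()
        for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
            if sl is None:
                continue
            if (sl[0].stop - sl[0].start) < k and (sl[1].stop - sl[1].start) < k:
                keep[sl][labels[sl] == idx] = False
        opened = keep
    return opened


def update_bounding_cube(
    body_half_extent: float,
    latest_cov,
    margin: float = 30.0,
) -> BoundingCube:
    """Re-centre the cube on the latest CoV, padded by ``margin`` beyond the
    tight body half-extent (so the animal cannot exit before the next frame)."""
    if margin <= 0:
        raise ConfigurationError("cube margin must be positive")
    return BoundingCube(center=latest_cov, half_extent=float(body_half_extent) + float(margin))


def restrict_to_cube(
    camera: CameraModel, cube: BoundingCube
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Pixel region of interest covering the cube in one camera.

    Returns ``((row0, row1), (col0, col1))`` half-open bounds clipped to the
    image, or None when the cube projects entirely outside the view. If any
    cube corner falls behind the camera the full image is returned
    (conservative fallback).
    """
    w, h = camera.image_size
    uv, in_front = project_points(camera, cube.corners())
    if not np.all(in_front):
        if not np.any(in_front):
            return None
        return (0, h), (0, w)
    c0 = int(np.floor(uv[:, 0].min()))
    c1 = int(np.ceil(uv[:, 0].max())) + 1
    r0 = int(np.floor(uv[:, 1].min()))
    r1 = int(np.ceil(uv[:, 1].max())) + 1
    r0, r1 = max(r0, 0), min(r1, h)
    c0, c1 = max(c0, 0), min(c1, w)
    if r0 >= r1 or c0 >= c1:
        return None
    return (r0, r1), (c0, c1)


def initial_cube(
    rig: CameraRig,
    masks: list[np.ndarray],
    half_extent: float = 100.0,
) -> BoundingCube:
    """Seed the bounding cube from full-frame first-frame silhouettes.

    Back-projects each camera's mask centroid as a ray and places the cube
    at the point minimising the summed squared distance to all rays.
    """
    A = np.zeros((3, 3))
    b = np.zeros(3)
    used = 0
    for cam, mask in zip(rig, masks):
        if mask is None or not mask.any():
            continue
        vs, us = np.nonzero(mask)
        uv = np.array([us.mean(), vs.mean()])
        d_cam = np.array(
            [
                (uv[0] - cam.principal_point[0]) / cam.focal[0],
                (uv[1] - cam.principal_point[1]) / cam.focal[1],
                1.0,
            ]
        )
        d = cam.rotation.T @ d_cam
        d = d / np.linalg.norm(d)
        o = cam.center
        P = np.eye(3) - np.outer(d, d)
        A += P
        b += P @ o
        used += 1
    if used < 2:
        raise ConfigurationError("initial cube needs silhouettes in at least two cameras")
    center = np.linalg.solve(A, b)
    return BoundingCube(center=center, half_extent=half_extent)
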