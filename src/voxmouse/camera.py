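"""Pinhole camera models, multi-camera rigs, and voxel-to-pixel correspondence.

World frame convention: origin at the arena center on the floor, z up,
millimetre units. Image convention: pixel (0, 0) is the centre of the
top-left pixel, x right, y down; pixel rounding is nearest integer with
ties toward +inf. Lens distortion is assumed to have been removed during
calibration, so the model is a pure pinhole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .errors import CalibrationError, ConfigurationError

__all__ = [
    "CameraModel",
    "CameraRig",
    "project_point",
    "project_points",
    "pixel_to_world",
    "voxel_in_silhouette",
    "voxels_in_silhouette",
    "build_virtual_rig",
    "save_calibration",
    "load_calibration",
]


@dataclass(frozen=True)
class CameraModel:
    """One calibrated pinhole view.

    ``rotation`` maps world to camera coordinates; ``translation`` is the
    world origin expressed in the camera frame (both in mm), so a world
    point ``X`` has camera coordinates ``R @ X + t``.
    """

    id: str
    rotation: np.ndarray
    translation: np.ndarray
    focal: np.ndarray
    principal_point: np.ndarray
    image_size: tuple[int, int]  # (width, height) pixels

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        f = np.asarray(self.focal, dtype=float).reshape(2)
        c = np.asarray(self.principal_point, dtype=float).reshape(2)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "focal", f)
        object.__setattr__(self, "principal_point", c)
        object.__setattr__(self, "image_size", (int(self.image_size[0]), int(self.image_size[1])))
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ConfigurationError(f"camera {self.id}: rotation is not orthonormal")
        if np.any(f <= 0):
            raise ConfigurationError(f"camera {self.id}: focal components must be > 0")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ConfigurationError(f"camera {self.id}: image size must be positive")

    @property
    def center(self) -> np.ndarray:
        """Camera optical centre in world coordinates."""
        return -self.rotation.T @ self.translation

    def projection_matrix(self) -> np.ndarray:
        """3x4 matrix K [R|t] mapping homogeneous world points to pixels."""
        K = np.array(
            [
                [self.focal[0], 0.0, self.principal_point[0]],
                [0.0, self.focal[1], self.principal_point[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        Rt = np.hstack([self.rotation, self.translation[:, None]])
        return K @ Rt


@dataclass(frozen=True)
class CameraRig:
    """Ordered collection of calibrated cameras covering the arena."""

    cameras: tuple[CameraModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cameras", tuple(self.cameras))
        if len(self.cameras) < 2:
            raise ConfigurationError("a rig needs at least two cameras")

    @property
    def n(self) -> int:
        return len(self.cameras)

    def __iter__(self):
        return iter(self.cameras)

    def __len__(self) -> int:
        return len(self.cameras)


def project_point(camera: CameraModel, point) -> np.ndarray | None:
    """Project one world point to pixel coordinates; None if behind the camera."""
    p = np.asarray(point, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    pc = camera.rotation @ p + camera.translation
    if pc[2] <= 0:
        return None
    return camera.focal * pc[:2] / pc[2] + camera.principal_point


def project_points(camera: CameraModel, points: np.ndarray):
    """Vectorised projection.

    Returns ``(uv, in_front)`` where ``uv`` is (n, 2) pixel coordinates
    (rows with non-positive depth hold NaN) and ``in_front`` is a boolean
    mask of points with positive depth.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    pc = pts @ camera.rotation.T + camera.translation
    z = pc[:, 2]
    in_front = z > 0
    uv = np.full((len(pts), 2), np.nan)
    safe = np.where(in_front, z, 1.0)
    uv[in_front] = (camera.focal * pc[:, :2] / safe[:, None] + camera.principal_point)[in_front]
    return uv, in_front


def pixel_to_world(camera: CameraModel, uv, depth: float) -> np.ndarray:
    """World point on the viewing ray of pixel ``uv`` at camera depth ``depth``."""
    uv = np.asarray(uv, dtype=float).reshape(2)
    xy = (uv - camera.principal_point) / camera.focal
    pc = np.array([xy[0] * depth, xy[1] * depth, depth])
    return camera.rotation.T @ (pc - camera.translation)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # nearest integer, ties toward +inf (np.round would round halves to even)
    return np.floor(x + 0.5).astype(np.int64)


def voxel_in_silhouette(camera: CameraModel, mask: np.ndarray, voxel_center) -> bool:
    """True iff the voxel centre projects onto a foreground pixel of ``mask``."""
    w, h = camera.image_size
    if mask.shape != (h, w):
        raise ConfigurationError(
            f"mask shape {mask.shape} does not match camera {camera.id} "
            f"image size (h={h}, w={w})"
        )
    uv = project_point(camera, voxel_center)
    if uv is None:
        return False
    ui, vi = _round_half_up(np.asarray(uv))
    if ui < 0 or ui >= w or vi < 0 or vi >= h:
        return False
    return bool(mask[vi, ui])


def voxels_in_silhouette(
    camera: CameraModel,
    mask: np.ndarray,
    centers: np.ndarray,
    mask_origin: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Vectorised silhouette test for many voxel centres.

    ``mask`` may be a crop of the full image whose top-left pixel sits at
    ``mask_origin = (row, col)`` in full-image coordinates; pixels outside
    the crop count as background.
    """
    uv, in_front = project_points(camera, centers)
    out = np.zeros(len(uv), dtype=bool)
    if not np.any(in_front):
        return out
    r0, c0 = mask_origin
    ui = _round_half_up(np.where(in_front[:, None], uv, 0.0)[:, 0]) - c0
    vi = _round_half_up(np.where(in_front[:, None], uv, 0.0)[:, 1]) - r0
    hh, ww = mask.shape
    inside = in_front & (ui >= 0) & (ui < ww) & (vi >= 0) & (vi < hh)
    out[inside] = mask[vi[inside], ui[inside]]
    return out


# ---------------------------------------------------------------------------
# Virtual rig construction


def _camera_from_pose(
    cam_id: str,
    center: np.ndarray,
    x_axis: np.ndarray,
    y_axis: np.ndarray,
    z_axis: np.ndarray,
    focal: float,
    image_size: tuple[int, int],
) -> CameraModel:
    R = np.vstack([x_axis, y_axis, z_axis])
    t = -R @ center
    w, h = image_size
    return CameraModel(
        id=cam_id,
        rotation=R,
        translation=t,
        focal=np.array([focal, focal]),
        principal_point=np.array([(w - 1) / 2.0, (h - 1) / 2.0]),
        image_size=(w, h),
    )


def _arena_sample_points(arena_radius: float, arena_height: float, spacing: float) -> np.ndarray:
    xs = np.arange(-arena_radius, arena_radius + spacing / 2, spacing)
    zs = np.arange(0.0, arena_height + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    keep = gx**2 + gy**2 <= arena_radius**2
    planar = np.column_stack([gx[keep], gy[keep]])
    pts = np.concatenate([np.column_stack([planar, np.full(len(planar), z)]) for z in zs])
    return pts


def build_virtual_rig(
    arena_radius: float = 457.0,
    n_below: int = 4,
    n_lateral: int = 6,
    image_size: tuple[int, int] = (1024, 1024),
    focal: float | None = None,
    arena_height: float = 120.0,
) -> CameraRig:
    """Construct the virtual capture rig: lateral cameras on a ring outside the
    arena with horizontal optical axes through the arena centre, and below
    cameras looking straight up through the transparent floor.

    ``focal`` defaults to the largest value (2-pixel margin) for which the
    whole arena interior (cylinder of ``arena_height``) fits inside every
    camera's frustum.
    """
    if n_below + n_lateral < 2:
        raise ConfigurationError("a rig needs at least two cameras")

    lat_distance = 2.6 * arena_radius
    lat_height = 0.65 * arena_height
    below_depth = 1.45 * arena_radius
    below_ring = 0.30 * arena_radius

    poses = []  # (id, center, x_axis, y_axis, z_axis)
    for i in range(n_lateral):
        phi = 2.0 * np.pi * i / n_lateral
        c = np.array([lat_distance * np.cos(phi), lat_distance * np.sin(phi), lat_height])
        z_axis = np.array([-np.cos(phi), -np.sin(phi), 0.0])
        x_axis = np.array([-np.sin(phi), np.cos(phi), 0.0])
        y_axis = np.cross(z_axis, x_axis)  # points to world -z: image y down
        poses.append((f"lat{i:02d}", c, x_axis, y_axis, z_axis))
    for j in range(n_below):
        phi = 2.0 * np.pi * j / max(n_below, 1) + np.pi / 4
        c = np.array([below_ring * np.cos(phi), below_ring * np.sin(phi), -below_depth])
        z_axis = np.array([0.0, 0.0, 1.0])
        x_axis = np.array([1.0, 0.0, 0.0])
        y_axis = np.cross(z_axis, x_axis)
        poses.append((f"bot{j:02d}", c, x_axis, y_axis, z_axis))

    samples = _arena_sample_points(arena_radius, arena_height, spacing=50.0)
    if focal is None:
        # largest focal keeping every sample point in every frustum
        limits = []
        w, h = image_size
        for _, c, xa, ya, za in poses:
            rel = samples - c
            depth = rel @ za
            if np.any(depth <= 0):
                raise ConfigurationError("arena extends behind a virtual camera")
            rx = np.max(np.abs(rel @ xa) / depth)
            ry = np.max(np.abs(rel @ ya) / depth)
            limits.append(min((w / 2 - 2) / rx, (h / 2 - 2) / ry))
        focal = float(min(limits))

    cams = [_camera_from_pose(cid, c, xa, ya, za, focal, image_size) for cid, c, xa, ya, za in poses]
    rig = CameraRig(tuple(cams))

    # coverage validation: every sample point must be visible to >= 2 cameras
    w, h = image_size
    seen = np.zeros(len(samples), dtype=int)
    for cam in rig:
        uv, in_front = project_points(cam, samples)
        ok = in_front & (uv[:, 0] >= -0.5) & (uv[:, 0] <= w - 0.5)
        ok &= (uv[:, 1] >= -0.5) & (uv[:, 1] <= h - 0.5)
        seen += ok
    if np.any(seen < 2):
        raise ConfigurationError("rig geometry leaves part of the arena seen by < 2 cameras")
    return rig


# ---------------------------------------------------------------------------
# Calibration file I/O (YAML)


def save_calibration(rig: CameraRig, path) -> None:
    data = {
        "cameras": [
            {
                "id": cam.id,
                "rotation": [[float(v) for v in row] for row in cam.rotation],
                "translation": [float(v) for v in cam.translation],
                "focal": [float(v) for v in cam.focal],
                "principal_point": [float(v) for v in cam.principal_point],
                "image_size": [int(v) for v in cam.image_size],
            }
            for cam in rig
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_calibration(path) -> CameraRig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "cameras" not in data:
        raise CalibrationError(f"{path}: missing 'cameras' section")
    cams = []
    for entry in data["cameras"]:
        try:
            cams.append(
                CameraModel(
                    id=str(entry["id"]),
                    rotation=np.array(entry["rotation"], dtype=float),
                    translation=np.array(entry["translation"], dtype=float),
                    focal=np.array(entry["focal"], dtype=float),
                    principal_point=np.array(entry["principal_point"], dtype=float),
                    image_size=tuple(entry["image_size"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise CalibrationError(f"{path}: malformed camera entry: {exc}") from exc
    return CameraRig(tuple(cams))
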