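"""Front/rear body segmentation by 2-means clustering of the tailless volume.

Lloyd's algorithm with deterministic initialisation: the previous frame's
cluster centres when available (warm start), otherwise the farthest voxel
pair. Anatomical labels are assigned from the whole-body motion direction —
the leading cluster along the planar velocity is the front — with
persistence while the animal is slow and hysteresis (contradictory evidence
must persist for several consecutive frames) so labels do not chatter
frame to frame or flip during turns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SegmentedBody", "SegmentationTracker", "split_two_clusters", "label_front_rear"]

SPEED_FOR_HEADING = 10.0  # mm/s; below this, labels persist
FLIP_PERSISTENCE = 5  # consecutive frames of contrary evidence needed to flip labels
MAX_ITER = 100


@dataclass
class SegmentedBody:
    front_voxels: np.ndarray  # (n1, 3)
    rear_voxels: np.ndarray  # (n2, 3)
    front_centroid: np.ndarray  # (3,)
    rear_centroid: np.ndarray  # (3,)
    heading: np.ndarray  # (2,) planar unit vector rear -> front


def _farthest_pair(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # O(n) approximation: farthest point from the centroid, then farthest from it
    c = points.mean(axis=0)
    a = points[np.argmax(np.sum((points - c) ** 2, axis=1))]
    b = points[np.argmax(np.sum((points - a) ** 2, axis=1))]
    return a, b


def split_two_clusters(
    points: np.ndarray,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-cluster Lloyd iteration on voxel centres.

    ``init`` is an optional (2, 3) array of starting centres (typically the
    previous frame's); the default start is the farthest voxel pair.
    Returns ``(assignment, centers, objective)`` where ``assignment`` is 0/1
    per point and ``objective`` the within-cluster sum of squared distances.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("need at least two voxels to split")
    if np.allclose(pts, pts[0]):
        warnings.warn("all voxels identical; degenerate one-vs-rest split", stacklevel=2)
        assign = np.zeros(len(pts), dtype=int)
        assign[0] = 1
        centers = np.vstack([pts[0], pts[0]])
        return assign, centers, 0.0

    if init is not None:
        centers = np.asarray(init, dtype=float).reshape(2, 3).copy()
    else:
        a, b = _farthest_pair(pts)
        centers = np.vstack([a, b])

    assign = np.zeros(len(pts), dtype=int)
    for _ in range(MAX_ITER):
        d0 = np.sum((pts - centers[0]) ** 2, axis=1)
        d1 = np.sum((pts - centers[1]) ** 2, axis=1)
        new_assign = (d1 < d0).astype(int)
        if np.all(new_assign == assign) and _ > 0:
            break
        assign = new_assign
        for k in (0, 1):
            sel = assign == k
            if sel.any():
                centers[k] = pts[sel].mean(axis=0)
            else:  # empty cluster: reseed at the point farthest from the other centre
                centers[k] = pts[np.argmax(np.sum((pts - centers[1 - k]) ** 2, axis=1))]
    d0 = np.sum((pts - centers[0]) ** 2, axis=1)
    d1 = np.sum((pts - centers[1]) ** 2, axis=1)
    obj = float(np.sum(np.minimum(d0, d1)))
    return assign, centers, obj


@dataclass
class SegmentationTracker:
    """Per-trial state for warm starts and front/rear label hysteresis."""

    head_hint: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    prev_centers: np.ndarray | None = None  # (2,3), index 0 = front
    _contrary: int = 0
    _motion_locked: bool = False  # labels have been confirmed by motion at least once

    def segment(self, points: np.ndarray, velocity_xy) -> SegmentedBody:
        assign, centers, _ = split_two_clusters(points, init=self.prev_centers)
        return self.label(points, assign, centers, velocity_xy)

    def label(self, points, assign, centers, velocity_xy) -> SegmentedBody:
        body = label_front_rear(
            points, assign, centers, velocity_xy, self.prev_centers, self.head_hint
        )
        # hysteresis protects an established (motion-confirmed) labeling;
        # before that, fresh motion evidence overrides the first-frame guess
        if self.prev_centers is not None and self._motion_locked:
            prev_front = self.prev_centers[0]
            keeps = np.linalg.norm(body.front_centroid - prev_front) <= np.linalg.norm(
                body.rear_centroid - prev_front
            )
            if keeps:
                self._contrary = 0
            else:
                self._contrary += 1
                if self._contrary < FLIP_PERSISTENCE:
                    body = SegmentedBody(
                        front_voxels=body.rear_voxels,
                        rear_voxels=body.front_voxels,
                        front_centroid=body.rear_centroid,
                        rear_centroid=body.front_centroid,
                        heading=-body.heading,
                    )
                else:
                    self._contrary = 0
        v = np.asarray(velocity_xy, dtype=float).reshape(2)
        if float(np.hypot(*v)) > SPEED_FOR_HEADING:
            self._motion_locked = True
        self.prev_centers = np.vstack([body.front_centroid, body.rear_centroid])
        return body


def label_front_rear(
    points: np.ndarray,
    assign: np.ndarray,
    centers: np.ndarray,
    velocity_xy,
    prev_centers: np.ndarray | None = None,
    head_hint=np.array([1.0, 0.0]),
) -> SegmentedBody:
    """Assign anatomical front/rear labels to the two clusters.

    Moving (planar speed > 10 mm/s): the front is the cluster whose centroid
    leads along the velocity direction. At rest: labels persist from
    ``prev_centers`` (front first) when given; on a first frame at rest the
    front is the cluster whose centroid lies further along ``head_hint``
    from the body centre.
    """
    pts = np.asarray(points, dtype=float)
    v = np.asarray(velocity_xy, dtype=float).reshape(2)
    speed = float(np.hypot(*v))
    axis = centers[1] - centers[0]

    if speed > SPEED_FOR_HEADING:
        front_idx = int(np.argmax(centers[:, :2] @ (v / speed)))
    elif prev_centers is not None:
        d_to_prev_front = np.linalg.norm(centers - prev_centers[0], axis=1)
        front_idx = int(np.argmin(d_to_prev_front))
    else:
        front_idx = int(np.argmax(centers[:, :2] @ np.asarray(head_hint, dtype=float)))

    rear_idx = 1 - front_idx
    fsel = assign == front_idx
    heading = centers[front_idx, :2] - centers[rear_idx, :2]
    nrm = np.linalg.norm(heading)
    heading = heading / nrm if nrm > 1e-12 else np.array([1.0, 0.0])
    return SegmentedBody(
        front_voxels=pts[fsel],
        rear_voxels=pts[~fsel],
        front_centroid=centers[front_idx].copy(),
        rear_centroid=centers[rear_idx].copy(),
        heading=heading,
    )
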