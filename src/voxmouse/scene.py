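"""Ground-truthed synthetic open-field trials.

A parametric mouse — three body ellipsoids (rear, front, head) plus a
cylindrical tail rendered as a chain of spheres — moves through scripted
behavior epochs on an arc inside a circular arena, viewed by a calibrated
virtual rig. The renderer produces photo-like grayscale frames (dark animal
on a white background, i.i.d. Gaussian pixel noise) together with the exact
analytic silhouette of the shape in every camera, so every downstream stage
of the pipeline can be tested against known ground truth.

Scripted locomotion carries a sinusoidal lateral offset of the rear centre
of volume (CoV) at the scripted step cadence — one left and one right
excursion per step cycle — mirrored at half amplitude and opposite phase on
the front CoV, emulating the lateral weight shift that accompanies stepping.
The default step-cadence law embeds a linear speed-to-step-cycle-distance
model (``cycle_mm = 0.25 * speed + 8``) so that the gait-regression stage
has a known generating model to recover.

All randomness flows from a single integer seed through counter-based
(Philox) generators keyed on (seed, frame, camera), so any frame can be
re-rendered independently and reproducibly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .camera import CameraModel, CameraRig, save_calibration
from .errors import RenderError, ScriptError

__all__ = [
    "Ellipsoid",
    "MouseShape",
    "Epoch",
    "TrialScript",
    "GroundTruth",
    "script_trajectory",
    "pose_mouse",
    "exact_mask",
    "render_views",
    "generate_trial",
    "SyntheticFrameSource",
    "cycle_distance",
    "cadence_for_speed",
    "default_cohort_script",
    "demo_script",
    "GAIT_SLOPE",
    "GAIT_INTERCEPT",
]

# --- mouse geometry (mm); tailless volume ~24,000 mm^3 (~24 cm^3, a 25-30 g mouse),
# body ~83 mm long and ~28 mm wide so that all parts stay thicker than the
# tail-removal element at the rig's pixel resolution, while the ~6 mm tail does not
REAR_SEMI = np.array([19.0, 14.0, 12.0])
FRONT_SEMI = np.array([15.0, 11.5, 9.5])
HEAD_SEMI = np.array([12.0, 11.0, 11.0])  # includes the ears: ~22 mm across
HEAD_OFFSET = 22.0  # head centre ahead of front-ellipsoid centre, mm
COV_SEPARATION = 38.0  # rear CoV to front-cluster CoV, mm (3D)
TAIL_RADIUS = 3.0
TAIL_LENGTH = 55.0

_VOL_REAR = 4.0 / 3.0 * np.pi * float(np.prod(REAR_SEMI))
_VOL_FRONT = 4.0 / 3.0 * np.pi * float(np.prod(FRONT_SEMI))
_VOL_HEAD = 4.0 / 3.0 * np.pi * float(np.prod(HEAD_SEMI))
_W_FRONT = (_VOL_FRONT + _VOL_HEAD) / (_VOL_REAR + _VOL_FRONT + _VOL_HEAD)

TAILLESS_VOLUME = _VOL_REAR + _VOL_FRONT + _VOL_HEAD  # ~10,013 mm^3

# --- generating gait model: distance per step cycle (mm) as a function of speed
GAIT_SLOPE = 0.25
GAIT_INTERCEPT = 8.0

BACKGROUND_INTENSITY = 1.0  # white environment around the open field
ANIMAL_INTENSITY = 0.1  # dark (black) mouse

PATH_ARC_RADIUS = 200.0  # mm; locomotion follows an arc well inside the arena

LABELS = (
    "directed_locomotion",
    "exploratory_locomotion",
    "meandering",
    "standing",
    "rearing",
)


def cycle_distance(speed: float) -> float:
    """Distance covered in one step cycle (mm) under the generating model."""
    return GAIT_SLOPE * speed + GAIT_INTERCEPT


def cadence_for_speed(speed: float) -> float:
    """Step-cycle rate (Hz) consistent with the generating model."""
    return speed / cycle_distance(speed) if speed > 0 else 0.0


# ---------------------------------------------------------------------------
# Shape


@dataclass(frozen=True)
class Ellipsoid:
    center: np.ndarray  # (3,) mm
    semi_axes: np.ndarray  # (3,) mm
    rotation: np.ndarray  # (3,3) body->world (columns are body axes)

    def contains(self, points: np.ndarray) -> np.ndarray:
        rel = (np.atleast_2d(points) - self.center) @ self.rotation
        return np.sum((rel / self.semi_axes) ** 2, axis=1) <= 1.0


@dataclass(frozen=True)
class MouseShape:
    """Rear + front + head ellipsoids, optional tail (chain of spheres)."""

    body: tuple[Ellipsoid, ...]
    tail_spheres: tuple[Ellipsoid, ...]
    present_tail: bool

    def components(self, tail: bool | None = None) -> tuple[Ellipsoid, ...]:
        if tail is None:
            tail = self.present_tail
        return self.body + (self.tail_spheres if tail and self.present_tail else ())

    def contains(self, points: np.ndarray, tail: bool | None = None) -> np.ndarray:
        pts = np.atleast_2d(points)
        out = np.zeros(len(pts), dtype=bool)
        for comp in self.components(tail):
            out |= comp.contains(pts)
        return out


def pose_mouse(
    rear_cov,
    front_cov,
    heading_xy,
    present_tail: bool = True,
) -> MouseShape:
    """Build the mouse shape for one frame.

    The rear ellipsoid is centred on the true rear CoV; the front ellipsoid
    and head are placed so that the volume-weighted centroid of the front
    cluster coincides with the true front CoV.
    """
    rear = np.asarray(rear_cov, dtype=float)
    front = np.asarray(front_cov, dtype=float)
    if not (np.all(np.isfinite(rear)) and np.all(np.isfinite(front))):
        raise ValueError("pose_mouse requires finite CoV positions")

    axis = front - rear
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        axis = np.array([1.0, 0.0, 0.0])
    else:
        axis = axis / norm

    # body frame: x along the rear->front axis, z as close to world-up as possible
    zb = np.array([0.0, 0.0, 1.0]) - axis[2] * axis
    zn = np.linalg.norm(zb)
    zb = zb / zn if zn > 1e-9 else np.array([1.0, 0.0, 0.0])
    yb = np.cross(zb, axis)
    R = np.column_stack([axis, yb, zb])

    v_h = _VOL_HEAD / (_VOL_FRONT + _VOL_HEAD)
    front_center = front - v_h * HEAD_OFFSET * axis
    head_center = front_center + HEAD_OFFSET * axis

    body = (
        Ellipsoid(rear, REAR_SEMI, R),
        Ellipsoid(front_center, FRONT_SEMI, R),
        Ellipsoid(head_center, HEAD_SEMI, R),
    )

    # tail: horizontal, trailing the rear ellipsoid opposite the planar heading
    h = np.asarray(heading_xy, dtype=float)
    hn = np.linalg.norm(h)
    h = h / hn if hn > 1e-9 else np.array([1.0, 0.0])
    base = rear - 14.0 * np.array([h[0], h[1], 0.0])
    base[2] = max(TAIL_RADIUS + 1.0, rear[2] - 6.0)
    step = 5.0
    n_sph = int(TAIL_LENGTH / step) + 1
    spheres = tuple(
        Ellipsoid(
            base - (k * step) * np.array([h[0], h[1], 0.0]),
            np.full(3, TAIL_RADIUS),
            np.eye(3),
        )
        for k in range(n_sph)
    )
    return MouseShape(body=body, tail_spheres=spheres, present_tail=present_tail)


# ---------------------------------------------------------------------------
# Scripts and ground truth


@dataclass(frozen=True)
class Epoch:
    """One scripted behavior interval."""

    label: str
    duration: float  # s
    speed: float = 0.0  # mm/s, planar
    cadence: float | None = None  # step cycles per second; default from gait model
    lateral_amplitude: float | None = None  # mm; default 3 during locomotion
    rear_height: float = 15.0  # mm
    front_height: float | None = None  # mm; default 20, or 45 when rearing

    def resolved(self) -> "Epoch":
        cad = self.cadence
        amp = self.lateral_amplitude
        fh = self.front_height
        moving = self.label in ("directed_locomotion", "exploratory_locomotion", "meandering")
        if cad is None:
            cad = cadence_for_speed(self.speed) if moving else 0.0
        if amp is None:
            amp = 3.0 if moving else 0.0
        if fh is None:
            fh = 45.0 if self.label == "rearing" else 20.0
        return replace(self, cadence=cad, lateral_amplitude=amp, front_height=fh)


@dataclass(frozen=True)
class TrialScript:
    epochs: tuple[Epoch, ...]
    frame_rate: float = 100.0
    arena_radius: float = 457.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(e.resolved() for e in self.epochs))
        self.validate()

    @property
    def duration(self) -> float:
        return sum(e.duration for e in self.epochs)

    def validate(self) -> None:
        if not self.epochs:
            raise ScriptError("script has no epochs")
        if self.frame_rate <= 0:
            raise ScriptError("frame rate must be positive")
        for e in self.epochs:
            if e.duration <= 0 or e.speed < 0:
                raise ScriptError(f"epoch {e.label}: non-positive duration or negative speed")
            if e.label not in LABELS:
                raise ScriptError(f"unknown behavior label {e.label!r}")
            if e.label in ("standing", "rearing") and e.speed >= 10.0:
                raise ScriptError(f"{e.label} epoch scripted at {e.speed} mm/s (must be < 10)")
            if e.label == "meandering" and not (10.0 <= e.speed < 60.0):
                raise ScriptError(f"meandering epoch at {e.speed} mm/s (must be in [10, 60))")
            if e.label in ("directed_locomotion", "exploratory_locomotion") and e.speed < 60.0:
                raise ScriptError(f"{e.label} epoch at {e.speed} mm/s (must be >= 60)")
            if e.label == "directed_locomotion" and e.speed * e.duration < 200.0:
                raise ScriptError(
                    f"directed_locomotion epoch covers {e.speed * e.duration:.0f} mm (< 200)"
                )
            if e.label == "exploratory_locomotion" and e.speed * e.duration >= 200.0:
                raise ScriptError("exploratory_locomotion epoch covers >= 200 mm; script as directed")
            if e.label == "rearing" and e.front_height < 34.0:
                raise ScriptError("rearing epoch with front CoV below 34 mm")
            if e.label != "rearing" and e.front_height >= 34.0:
                raise ScriptError(f"{e.label} epoch with front CoV >= 34 mm")


@dataclass
class GroundTruth:
    """Per-frame true kinematics and labels for one synthetic trial."""

    frame_rate: float
    t: np.ndarray  # (n,) s
    whole: np.ndarray  # (n,3) mm
    front: np.ndarray  # (n,3) mm
    rear: np.ndarray  # (n,3) mm
    heading: np.ndarray  # (n,2) unit planar heading
    label: np.ndarray  # (n,) str
    speed: np.ndarray  # (n,) scripted planar speed mm/s
    step_phase: np.ndarray  # (n,) rad, cumulative lateral-oscillation phase
    step_cycle_mm: np.ndarray  # (n,) scripted distance per step cycle (NaN when not stepping)
    step_times: np.ndarray  # (k,) s, true lateral-extremum times
    present_tail: bool = True

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def shape_at(self, i: int) -> MouseShape:
        return pose_mouse(self.rear[i], self.front[i], self.heading[i], self.present_tail)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"frame": np.arange(self.n_frames), "t_s": self.t})
        for name, arr in (("whole", self.whole), ("front", self.front), ("rear", self.rear)):
            for k, ax in enumerate("xyz"):
                df[f"{name}_{ax}_mm"] = arr[:, k]
        df["label"] = self.label
        df["speed_mm_s"] = self.speed
        df["step_phase_rad"] = self.step_phase
        return df


def script_trajectory(script: TrialScript, seed: int) -> GroundTruth:
    """Realise a script as per-frame ground-truth kinematics.

    The planar path follows a circular arc of radius ``PATH_ARC_RADIUS``
    centred on the arena centre; the start angle and oscillation phase are
    drawn from the seed. Speed is piecewise constant per epoch; the lateral
    oscillation phase only advances while the scripted cadence is non-zero.
    """
    rng = np.random.Generator(np.random.Philox(key=np.uint64(seed)))
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)

    dt = 1.0 / script.frame_rate
    frames_per_epoch = [int(round(e.duration * script.frame_rate)) for e in script.epochs]
    n = sum(frames_per_epoch)

    speed = np.empty(n)
    cad = np.empty(n)
    amp = np.empty(n)
    rear_h = np.empty(n)
    front_h = np.empty(n)
    label = np.empty(n, dtype=object)
    i0 = 0
    for e, ne in zip(script.epochs, frames_per_epoch):
        sl = slice(i0, i0 + ne)
        speed[sl] = e.speed
        cad[sl] = e.cadence
        amp[sl] = e.lateral_amplitude
        rear_h[sl] = e.rear_height
        front_h[sl] = e.front_height
        label[sl] = e.label
        i0 += ne

    t = np.arange(n) * dt
    arc = np.concatenate([[0.0], np.cumsum(speed[:-1] * dt)])  # arc length, mm
    theta = theta0 + arc / PATH_ARC_RADIUS
    center = PATH_ARC_RADIUS * np.column_stack([np.cos(theta), np.sin(theta)])
    heading = np.column_stack([-np.sin(theta), np.cos(theta)])  # CCW tangent
    normal = np.column_stack([-heading[:, 1], heading[:, 0]])  # left of travel

    phase = phi0 + np.concatenate([[0.0], np.cumsum(2.0 * np.pi * cad[:-1] * dt)])
    lat = amp * np.sin(phase)

    rear = np.empty((n, 3))
    rear[:, :2] = center + lat[:, None] * normal
    rear[:, 2] = rear_h

    dz = front_h - rear_h
    planar_sep = np.sqrt(np.maximum(COV_SEPARATION**2 - dz**2, 10.0**2))
    front = np.empty((n, 3))
    front[:, :2] = (
        center + planar_sep[:, None] * heading - 0.5 * lat[:, None] * normal
    )
    front[:, 2] = front_h

    whole = (1.0 - _W_FRONT) * rear + _W_FRONT * front

    # true step times: lateral extrema at phase = pi/2 + k*pi, during stepping only
    k_idx = np.floor((phase - np.pi / 2.0) / np.pi)
    crossings = np.nonzero((np.diff(k_idx) > 0) & (cad[:-1] > 0))[0]
    step_times = t[crossings + 1]

    cyc = np.where(cad > 0, np.divide(speed, cad, out=np.zeros_like(speed), where=cad > 0), np.nan)
    cyc[cad <= 0] = np.nan

    return GroundTruth(
        frame_rate=script.frame_rate,
        t=t,
        whole=whole,
        front=front,
        rear=rear,
        heading=heading,
        label=label.astype(str),
        speed=speed,
        step_phase=phase,
        step_cycle_mm=cyc,
        step_times=step_times,
    )


# ---------------------------------------------------------------------------
# Rendering


def _dual_quadric(e: Ellipsoid) -> np.ndarray:
    A = e.rotation @ np.diag(e.semi_axes**2) @ e.rotation.T
    c = e.center
    Q = np.empty((4, 4))
    Q[:3, :3] = A - np.outer(c, c)
    Q[:3, 3] = -c
    Q[3, :3] = -c
    Q[3, 3] = -1.0
    return Q


def _paint_component(mask: np.ndarray, cam: CameraModel, e: Ellipsoid) -> None:
    """Set to True the pixels whose centres fall inside the projected ellipsoid."""
    w, h = cam.image_size
    pc = cam.rotation @ e.center + cam.translation
    r = float(np.max(e.semi_axes))
    if pc[2] <= r:
        raise RenderError(f"shape too close to or behind camera {cam.id}")
    uvc = cam.focal * pc[:2] / pc[2] + cam.principal_point
    if not (0 <= uvc[0] <= w - 1 and 0 <= uvc[1] <= h - 1):
        raise RenderError(f"shape outside the frustum of camera {cam.id}")

    # conservative pixel bounding box from the bounding sphere
    rad_px = float(np.max(cam.focal)) * r / (pc[2] - r) * 1.25 + 2.0
    c0 = max(int(np.floor(uvc[0] - rad_px)), 0)
    c1 = min(int(np.ceil(uvc[0] + rad_px)), w - 1)
    r0 = max(int(np.floor(uvc[1] - rad_px)), 0)
    r1 = min(int(np.ceil(uvc[1] + rad_px)), h - 1)
    if c1 < c0 or r1 < r0:
        return

    P = cam.projection_matrix()
    Cstar = P @ _dual_quadric(e) @ P.T
    C = np.linalg.inv(Cstar)
    us = np.arange(c0, c1 + 1, dtype=float)
    vs = np.arange(r0, r1 + 1, dtype=float)
    U, V = np.meshgrid(us, vs)
    val = (
        C[0, 0] * U * U
        + 2.0 * C[0, 1] * U * V
        + C[1, 1] * V * V
        + 2.0 * C[0, 2] * U
        + 2.0 * C[1, 2] * V
        + C[2, 2]
    )
    s_center = (
        C[0, 0] * uvc[0] ** 2
        + 2.0 * C[0, 1] * uvc[0] * uvc[1]
        + C[1, 1] * uvc[1] ** 2
        + 2.0 * C[0, 2] * uvc[0]
        + 2.0 * C[1, 2] * uvc[1]
        + C[2, 2]
    )
    inside = val * np.sign(s_center) >= 0.0
    mask[r0 : r1 + 1, c0 : c1 + 1] |= inside


def exact_mask(shape: MouseShape, cam: CameraModel, tail: bool | None = None) -> np.ndarray:
    """Analytic silhouette: pixel centres inside any projected component."""
    w, h = cam.image_size
    mask = np.zeros((h, w), dtype=bool)
    for comp in shape.components(tail):
        _paint_component(mask, cam, comp)
    return mask


def _noise_rng(seed: int, frame: int, cam_idx: int) -> np.random.Generator:
    key = (np.uint64(seed) << np.uint64(26)) | np.uint64(frame * 64 + cam_idx)
    return np.random.Generator(np.random.Philox(key=key))


def render_views(
    shape: MouseShape,
    rig: CameraRig,
    background: float = BACKGROUND_INTENSITY,
    animal: float = ANIMAL_INTENSITY,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame: int = 0,
):
    """Render one frame in every camera.

    Returns a list of ``(background_image, composite_image, exact_mask)``
    triples (float32 in [0, 1], bool). The exact mask is the analytic
    silhouette, which equals silhouette extraction's output on noise-free
    images away from component boundaries.
    """
    out = []
    for k, cam in enumerate(rig):
        w, h = cam.image_size
        bg = np.full((h, w), background, dtype=np.float32)
        mask = exact_mask(shape, cam)
        comp = bg.copy()
        comp[mask] = animal
        if noise_sd > 0:
            rng = _noise_rng(seed, frame, k)
            comp = comp + rng.normal(0.0, noise_sd, size=comp.shape).astype(np.float32)
            np.clip(comp, 0.0, 1.0, out=comp)
        out.append((bg, comp, mask))
    return out


class SyntheticFrameSource:
    """In-memory trial: renders frames (or crops) on demand from ground truth.

    Noise inside a requested crop is drawn from the per-(frame, camera)
    counter-based stream, so repeated requests are reproducible; the noise
    realisation depends on the requested window, not on global pixel
    coordinates.
    """

    def __init__(
        self,
        ground_truth: GroundTruth,
        rig: CameraRig,
        noise_sd: float = 2.0 / 255.0,
        seed: int = 0,
        present_tail: bool | None = None,
    ):
        self.gt = ground_truth
        self.rig = rig
        self.noise_sd = float(noise_sd)
        self.seed = int(seed)
        if present_tail is not None:
            self.gt.present_tail = present_tail
        self._shape_cache: tuple[int, MouseShape] | None = None

    @property
    def n_frames(self) -> int:
        return self.gt.n_frames

    @property
    def frame_rate(self) -> float:
        return self.gt.frame_rate

    def _shape(self, i: int) -> MouseShape:
        if self._shape_cache is None or self._shape_cache[0] != i:
            self._shape_cache = (i, self.gt.shape_at(i))
        return self._shape_cache[1]

    def background_crop(self, cam_idx: int, roi) -> np.ndarray:
        (r0, r1), (c0, c1) = roi
        return np.full((r1 - r0, c1 - c0), BACKGROUND_INTENSITY, dtype=np.float32)

    def frame_crop(self, frame_idx: int, cam_idx: int, roi) -> np.ndarray:
        (r0, r1), (c0, c1) = roi
        cam = self.rig.cameras[cam_idx]
        mask = exact_mask(self._shape(frame_idx), cam)[r0:r1, c0:c1]
        img = np.full(mask.shape, BACKGROUND_INTENSITY, dtype=np.float32)
        img[mask] = ANIMAL_INTENSITY
        if self.noise_sd > 0:
            rng = _noise_rng(self.seed, frame_idx, cam_idx)
            img = img + rng.normal(0.0, self.noise_sd, size=img.shape).astype(np.float32)
            np.clip(img, 0.0, 1.0, out=img)
        return img


# ---------------------------------------------------------------------------
# On-disk trials


def generate_trial(
    script: TrialScript,
    rig: CameraRig,
    seed: int,
    outdir,
    noise_sd: float = 2.0 / 255.0,
    present_tail: bool = True,
) -> GroundTruth:
    """Write a complete trial in the layout the pipeline ingests.

    ``outdir/<camera_id>/frame_%06d.png`` and ``background.png`` per camera,
    plus ``calibration.yaml`` and ``ground_truth.csv``.
    """
    gt = script_trajectory(script, seed)
    gt.present_tail = present_tail
    os.makedirs(outdir, exist_ok=True)
    for cam in rig:
        os.makedirs(os.path.join(outdir, cam.id), exist_ok=True)
    save_calibration(rig, os.path.join(outdir, "calibration.yaml"))
    gt.to_dataframe().to_csv(os.path.join(outdir, "ground_truth.csv"), index=False)

    wrote_bg = False
    for i in range(gt.n_frames):
        views = render_views(
            gt.shape_at(i), rig, noise_sd=noise_sd, seed=seed, frame=i
        )
        for cam, (bg, comp, _mask) in zip(rig, views):
            if not wrote_bg:
                iio.imwrite(
                    os.path.join(outdir, cam.id, "background.png"),
                    (bg * 255).astype(np.uint8),
                )
            iio.imwrite(
                os.path.join(outdir, cam.id, f"frame_{i:06d}.png"),
                (comp * 255).astype(np.uint8),
            )
        wrote_bg = True
    return gt


# ---------------------------------------------------------------------------
# Canonical scripts


def default_cohort_script(index: int, duration: float = 2.0) -> TrialScript:
    """Trial script ``index`` (0-11) of the default synthetic cohort.

    Locomotion speeds span 60-250 mm/s with cadences from the generating
    gait model (2.6-3.6 Hz). Even-index trials are pure locomotion; odd
    trials end with a 0.6 s standing or rearing epoch to exercise the
    posture classes.
    """
    speeds = np.linspace(60.0, 250.0, 12)
    s = float(speeds[index % 12])
    if index % 2 == 0:
        loco_dur = duration
        tail_epochs: tuple[Epoch, ...] = ()
    else:
        loco_dur = duration - 0.6
        pause = "rearing" if index % 4 == 1 else "standing"
        tail_epochs = (Epoch(label=pause, duration=0.6, speed=0.0),)
    loco_label = "directed_locomotion" if s * loco_dur >= 200.0 else "exploratory_locomotion"
    return TrialScript(epochs=(Epoch(label=loco_label, duration=loco_dur, speed=s),) + tail_epochs)


def demo_script() -> TrialScript:
    """Short mixed-behavior script used by the CLI demo and smoke tests."""
    return TrialScript(
        epochs=(
            Epoch(label="directed_locomotion", duration=1.4, speed=180.0),
            Epoch(label="standing", duration=0.4, speed=0.0),
            Epoch(label="rearing", duration=0.4, speed=0.0),
            Epoch(label="meandering", duration=0.4, speed=35.0),
        )
    )
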