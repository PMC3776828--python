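"""Step detection and gait statistics from rear-CoV lateral deviation.

The rear CoV oscillates laterally once per step cycle (one step with each
hindlimb). Its deviation from a speed-adaptive averaged trajectory — a
central moving average whose window spans exactly one step cycle — is a
signed series whose local maxima and minima mark individual steps. Because
the window size itself depends on a linear speed-to-step-cycle-distance
regression fitted from the detected steps, the whole procedure iterates
from a fixed 31-point window until the regression coefficients change by
less than 1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from scipy.signal import find_peaks

__all__ = [
    "StepLengthModel",
    "StepEvent",
    "GaitBoutStats",
    "BoutTrace",
    "TrialGait",
    "window_frames",
    "averaged_trajectory",
    "lateral_deviation",
    "detect_steps",
    "bout_stats",
    "fit_step_model",
    "iterate_to_convergence",
    "validity_correlations",
    "INITIAL_WINDOW",
    "MAX_WINDOW",
    "MIN_WINDOW",
]

INITIAL_WINDOW = 31  # frames: first regression pass (15 before and after)
MAX_WINDOW = 61  # frames: slowest-animal clamp (30 before and after)
MIN_WINDOW = 5  # frames: guard against degenerate averages at high speed
PROMINENCE_MM = 0.5  # extremum prominence noise guard
MIN_SEPARATION_S = 0.05  # minimum time between step extrema
FALLBACK_SLOPE = 0.3
FALLBACK_INTERCEPT = 10.0
CONVERGENCE_REL = 0.01
MAX_ITERATIONS = 20


@dataclass(frozen=True)
class StepLengthModel:
    """Linear speed -> distance-per-step-cycle regression (mm vs mm/s)."""

    slope: float
    intercept: float
    r2: float = np.nan
    iterations: int = 0
    n_points: int = 0

    def cycle_distance(self, speed) -> np.ndarray:
        return self.slope * np.asarray(speed, dtype=float) + self.intercept


FALLBACK_MODEL = StepLengthModel(slope=FALLBACK_SLOPE, intercept=FALLBACK_INTERCEPT)


@dataclass(frozen=True)
class StepEvent:
    frame: int
    time_s: float
    kind: str  # "max" | "min"
    deviation_mm: float


@dataclass(frozen=True)
class GaitBoutStats:
    avg_speed_mm_s: float
    n_steps: int
    distance_per_step_mm: float
    cadence_steps_s: float
    mean_abs_dev_front_mm: float
    mean_abs_dev_rear_mm: float
    path_mm: float
    duration_s: float
    is_gait_bout: bool = True


@dataclass
class BoutTrace:
    """Filtered planar positions and speeds of one directed-locomotion bout."""

    rear_xy: np.ndarray  # (n, 2) mm
    front_xy: np.ndarray  # (n, 2) mm
    speeds: np.ndarray  # (n,) mm/s, whole-body planar
    frame_rate: float
    trial_id: str = ""
    start_frame: int = 0

    @property
    def path_mm(self) -> float:
        d = np.diff(self.rear_xy, axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


@dataclass
class TrialGait:
    """Full-trial planar traces with the directed-locomotion bout windows.

    The averaged trajectory is computed over the whole recording, as frames
    neighbouring a bout still inform the moving average; steps and bout
    statistics are then taken on the per-bout windows. This avoids the
    edge attenuation a bout-local moving average would introduce.
    """

    rear_xy: np.ndarray  # (n, 2) mm
    front_xy: np.ndarray  # (n, 2) mm
    speeds: np.ndarray  # (n,) mm/s
    frame_rate: float
    bouts: list  # [(start, end), ...) frame windows of directed bouts
    trial_id: str = ""


def window_frames(
    speed: float,
    model: StepLengthModel,
    frame_rate: float = 100.0,
) -> int:
    """Frames in the speed-adaptive central moving-average window.

    One step cycle's worth of frames: round(d(speed) / speed * rate),
    forced odd (+1 on even rounds) and clamped to [5, 61]; speeds below
    1 mm/s (and non-positive predicted distances) take the 61-frame clamp.
    """
    if speed < 1.0:
        return MAX_WINDOW
    d = float(model.cycle_distance(speed))
    if d <= 0:
        return MAX_WINDOW
    w = int(round(d / speed * frame_rate))
    if w % 2 == 0:
        w += 1
    return int(np.clip(w, MIN_WINDOW, MAX_WINDOW))


def averaged_trajectory(
    xy: np.ndarray,
    speeds: np.ndarray,
    model: StepLengthModel | None = None,
    frame_rate: float = 100.0,
    fixed_window: int | None = None,
) -> np.ndarray:
    """Central moving average of planar positions with per-frame windows.

    ``fixed_window`` (e.g. the 31-point initial pass) overrides the
    speed-adaptive window. Near the ends the window shrinks symmetrically.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if fixed_window is not None:
        wins = np.full(n, int(fixed_window))
    else:
        if model is None:
            raise ValueError("averaged_trajectory needs a model or a fixed window")
        wins = np.array([window_frames(s, model, frame_rate) for s in np.asarray(speeds)])
    halves = (wins - 1) // 2
    cs = np.concatenate([np.zeros((1, 2)), np.cumsum(xy, axis=0)])
    out = np.empty_like(xy)
    for i in range(n):
        half = min(halves[i], i, n - 1 - i)
        lo, hi = i - half, i + half + 1
        out[i] = (cs[hi] - cs[lo]) / (hi - lo)
    return out


def lateral_deviation(xy: np.ndarray, averaged: np.ndarray) -> np.ndarray:
    """Signed perpendicular offset from the averaged path (left of travel > 0).

    The local travel direction is the gradient of the averaged path;
    stationary samples (zero tangent) get deviation 0.
    """
    xy = np.asarray(xy, dtype=float)
    avg = np.asarray(averaged, dtype=float)
    if xy.shape != avg.shape:
        raise ValueError("positions and averaged path must have equal shapes")
    if len(xy) < 2:
        return np.zeros(len(xy))
    tang = np.gradient(avg, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    ok = norm > 1e-9
    nx = np.where(ok, -tang[:, 1] / np.where(ok, norm, 1.0), 0.0)
    ny = np.where(ok, tang[:, 0] / np.where(ok, norm, 1.0), 0.0)
    rel = xy - avg
    return rel[:, 0] * nx + rel[:, 1] * ny


def detect_steps(
    deviation: np.ndarray,
    frame_rate: float = 100.0,
    prominence: float = PROMINENCE_MM,
    min_separation_s: float = MIN_SEPARATION_S,
) -> list[StepEvent]:
    """Step events: alternating local extrema of the lateral deviation.

    Extrema need ``prominence`` (mm) and ``min_separation_s`` spacing;
    where two same-kind extrema are adjacent the more prominent survives,
    so kinds strictly alternate. Each extremum is one step; a max+min pair
    is one step cycle.
    """
    dev = np.asarray(deviation, dtype=float)
    dist = max(int(round(min_separation_s * frame_rate)), 1)
    imax, pmax = find_peaks(dev, prominence=prominence, distance=dist)
    imin, pmin = find_peaks(-dev, prominence=prominence, distance=dist)
    events = [(i, "max", pmax["prominences"][k]) for k, i in enumerate(imax)]
    events += [(i, "min", pmin["prominences"][k]) for k, i in enumerate(imin)]
    events.sort(key=lambda e: e[0])

    # enforce alternation: among consecutive same-kind events keep the most prominent
    cleaned: list[tuple[int, str, float]] = []
    for ev in events:
        if cleaned and cleaned[-1][1] == ev[1]:
            if ev[2] > cleaned[-1][2]:
                cleaned[-1] = ev
        else:
            cleaned.append(ev)
    return [
        StepEvent(frame=int(i), time_s=i / frame_rate, kind=kind, deviation_mm=float(dev[i]))
        for i, kind, _ in cleaned
    ]


def bout_stats(
    bout: BoutTrace,
    steps: list[StepEvent],
    dev_front: np.ndarray | None = None,
    dev_rear: np.ndarray | None = None,
) -> GaitBoutStats:
    """Per-bout gait summary; bouts with < 2 steps are flagged non-gait."""
    path = bout.path_mm
    dur = len(bout.speeds) / bout.frame_rate
    n_steps = len(steps)
    ok = n_steps >= 2
    return GaitBoutStats(
        avg_speed_mm_s=float(np.mean(bout.speeds)),
        n_steps=n_steps,
        distance_per_step_mm=path / n_steps if ok else np.nan,
        cadence_steps_s=n_steps / dur if ok else np.nan,
        mean_abs_dev_front_mm=float(np.mean(np.abs(dev_front))) if dev_front is not None else np.nan,
        mean_abs_dev_rear_mm=float(np.mean(np.abs(dev_rear))) if dev_rear is not None else np.nan,
        path_mm=path,
        duration_s=dur,
        is_gait_bout=ok,
    )


def fit_step_model(stats_list: list[GaitBoutStats], iterations: int = 0) -> StepLengthModel:
    """OLS of distance per step cycle (2 x distance per step) on bout speed.

    Each directed-locomotion bout contributes one point. Fewer than 3 valid
    points, or a degenerate single-speed design, fall back to the
    configured default model with a warning.
    """
    pts = [
        (s.avg_speed_mm_s, 2.0 * s.distance_per_step_mm)
        for s in stats_list
        if s.is_gait_bout and np.isfinite(s.distance_per_step_mm)
    ]
    if len(pts) < 3:
        warnings.warn("fewer than 3 gait bouts; using fallback step-length model", stacklevel=2)
        return StepLengthModel(
            FALLBACK_SLOPE, FALLBACK_INTERCEPT, iterations=iterations, n_points=len(pts)
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) < 1e-9:
        warnings.warn("single-speed degenerate design; using fallback model", stacklevel=2)
        return StepLengthModel(
            FALLBACK_SLOPE, FALLBACK_INTERCEPT, iterations=iterations, n_points=len(pts)
        )
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StepLengthModel(float(slope), float(intercept), r2, iterations, len(pts))


def _analyse_bouts(
    items: list,
    model: StepLengthModel | None,
    fixed_window: int | None,
):
    """Per-bout gait statistics for BoutTrace or TrialGait inputs."""
    stats_list = []
    for it in items:
        if isinstance(it, TrialGait):
            avg_rear = averaged_trajectory(
                it.rear_xy, it.speeds, model, it.frame_rate, fixed_window=fixed_window
            )
            avg_front = averaged_trajectory(
                it.front_xy, it.speeds, model, it.frame_rate, fixed_window=fixed_window
            )
            dev_rear = lateral_deviation(it.rear_xy, avg_rear)
            dev_front = lateral_deviation(it.front_xy, avg_front)
            for s, e in it.bouts:
                bt = BoutTrace(
                    it.rear_xy[s:e], it.front_xy[s:e], it.speeds[s:e],
                    it.frame_rate, it.trial_id, s,
                )
                steps = detect_steps(dev_rear[s:e], it.frame_rate)
                stats_list.append(
                    bout_stats(bt, steps, dev_front=dev_front[s:e], dev_rear=dev_rear[s:e])
                )
            continue
        bt = it
        avg_rear = averaged_trajectory(
            bt.rear_xy, bt.speeds, model, bt.frame_rate, fixed_window=fixed_window
        )
        avg_front = averaged_trajectory(
            bt.front_xy, bt.speeds, model, bt.frame_rate, fixed_window=fixed_window
        )
        dev_rear = lateral_deviation(bt.rear_xy, avg_rear)
        dev_front = lateral_deviation(bt.front_xy, avg_front)
        steps = detect_steps(dev_rear, bt.frame_rate)
        stats_list.append(bout_stats(bt, steps, dev_front=dev_front, dev_rear=dev_rear))
    return stats_list


def iterate_to_convergence(bouts: list) -> tuple[StepLengthModel, list[GaitBoutStats]]:
    """Iterate moving average -> step detection -> regression to a fixed point.

    ``bouts`` is a list of BoutTrace (isolated bouts) and/or TrialGait
    (full-trial traces with bout windows). The first pass uses the fixed
    31-point window; subsequent passes use the fitted model's
    speed-adaptive windows. Convergence: both the slope (relative) and the
    intercept (relative to the predicted cycle distance at the mean
    observed speed) change by less than 1%. Returns the final model and
    the final per-bout statistics.
    """
    if not bouts or all(isinstance(b, TrialGait) and not b.bouts for b in bouts):
        return FALLBACK_MODEL, []
    speed_chunks = []
    for b in bouts:
        if isinstance(b, TrialGait):
            speed_chunks.extend(b.speeds[s:e] for s, e in b.bouts)
        else:
            speed_chunks.append(b.speeds)
    mean_speed = float(np.mean(np.concatenate(speed_chunks)))
    stats_list = _analyse_bouts(bouts, model=None, fixed_window=INITIAL_WINDOW)
    model = fit_step_model(stats_list, iterations=1)
    for it in range(2, MAX_ITERATIONS + 1):
        stats_list = _analyse_bouts(bouts, model=model, fixed_window=None)
        new = fit_step_model(stats_list, iterations=it)
        scale = max(abs(float(model.cycle_distance(mean_speed))), 1e-9)
        d_slope = abs(new.slope - model.slope) / max(abs(model.slope), 1e-9)
        d_icept = abs(new.intercept - model.intercept) / scale
        model = new
        if d_slope < CONVERGENCE_REL and d_icept < CONVERGENCE_REL:
            return model, stats_list
    warnings.warn("step-length regression did not converge; returning last iterate", stacklevel=2)
    return model, stats_list


def validity_correlations(metrics: dict, scores: dict) -> dict:
    """Pearson r and two-sided p for every metric/score pairing.

    ``metrics`` and ``scores`` map column names to equal-length per-animal
    value sequences (>= 3 animals, no missing values). Zero-variance
    columns yield NaN r with a flag.
    """
    out = {}
    for mname, mvals in metrics.items():
        mv = np.asarray(mvals, dtype=float)
        for sname, svals in scores.items():
            sv = np.asarray(svals, dtype=float)
            if len(mv) != len(sv) or len(mv) < 3:
                raise ValueError("correlations need >= 3 paired, complete observations")
            key = f"{mname}_vs_{sname}"
            if np.ptp(mv) < 1e-12 or np.ptp(sv) < 1e-12:
                out[key] = {"r": np.nan, "p": np.nan, "zero_variance": True}
                continue
            r, p = sstats.pearsonr(mv, sv)
            out[key] = {"r": float(r), "p": float(p), "zero_variance": False}
    return out
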