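"""Centre-of-volume traces: filtering, differentiation, and planar speed.

Raw per-frame CoV positions are low-pass filtered with a zero-phase
(forward-backward) Butterworth filter designed at 20 Hz for the trial frame
rate, then differentiated analytically through smoothing quintic splines.
Speed is the planar (x, y) velocity magnitude; the vertical component is
excluded. Missing frames (empty reconstructions) are bridged by cubic
interpolation when shorter than 0.5 s; longer gaps split the trial into
independently analysed segments.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import UnivariateSpline, interp1d

__all__ = [
    "center_of_volume",
    "filter_trace",
    "differentiate",
    "interpolate_gaps",
    "build_trace",
]

FILTER_CUTOFF_HZ = 20.0
FILTER_ORDER = 4
MAX_GAP_S = 0.5
EDGE_FRAMES = 5  # spline derivatives this close to the ends are low-confidence


def center_of_volume(voxel_centers: np.ndarray) -> np.ndarray | None:
    """Arithmetic mean of occupied voxel centres; None for an empty set."""
    pts = np.asarray(voxel_centers, dtype=float)
    if pts.size == 0:
        return None
    return pts.reshape(-1, 3).mean(axis=0)


def butterworth_sos(frame_rate: float, cutoff: float = FILTER_CUTOFF_HZ, order: int = FILTER_ORDER):
    """Single-pass Butterworth design used (twice) by the zero-phase filter."""
    return signal.butter(order, cutoff, btype="low", fs=frame_rate, output="sos")


def filter_trace(
    positions: np.ndarray,
    frame_rate: float,
    cutoff: float = FILTER_CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase low-pass filtering, applied per coordinate.

    Falls back to the unfiltered input (with a warning) when the trace is
    shorter than the filter's minimum padding length.
    """
    x = np.asarray(positions, dtype=float)
    one_d = x.ndim == 1
    x2 = x[:, None] if one_d else x
    sos = butterworth_sos(frame_rate, cutoff, order)
    # sosfiltfilt padlen default depends on sections; reflective (even) padding
    ntaps = 3 * (2 * sos.shape[0] + 1)
    if len(x2) <= ntaps:
        warnings.warn("trace too short for zero-phase filtering; returning input", stacklevel=2)
        return x.copy()
    out = np.column_stack(
        [signal.sosfiltfilt(sos, x2[:, k], padtype="even") for k in range(x2.shape[1])]
    )
    return out[:, 0] if one_d else out


def _spline_smoothing(x: np.ndarray) -> float:
    # noise variance estimated from second differences: var(d2) = 6 sigma^2
    if len(x) < 4:
        return 0.0
    d2 = np.diff(x, n=2)
    sigma2 = float(np.mean(d2**2) / 6.0)
    return len(x) * sigma2


def differentiate(positions: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Velocity from smoothing quintic splines fit per coordinate.

    The smoothing level is set from the residual noise variance estimated
    via second differences, so noise-free traces are interpolated nearly
    exactly. Fewer than 6 samples fall back to finite differences.
    """
    x = np.asarray(positions, dtype=float)
    t = np.asarray(t, dtype=float)
    one_d = x.ndim == 1
    x2 = x[:, None] if one_d else x
    if len(t) < 6:
        warnings.warn("too few samples for quintic splines; finite-difference fallback", stacklevel=2)
        v = np.gradient(x2, t, axis=0)
        return v[:, 0] if one_d else v
    v = np.empty_like(x2)
    for k in range(x2.shape[1]):
        s = _spline_smoothing(x2[:, k])
        with warnings.catch_warnings():
            # near-interpolating fits trip FITPACK's "s too small" notice
            warnings.filterwarnings("ignore", message=".*s too small.*")
            spl = UnivariateSpline(t, x2[:, k], k=5, s=s)
        v[:, k] = spl.derivative()(t)
    return v[:, 0] if one_d else v


def interpolate_gaps(
    positions: np.ndarray,
    frame_rate: float,
    max_gap_s: float = MAX_GAP_S,
) -> list[tuple[int, np.ndarray]]:
    """Fill short gaps (NaN rows) by cubic interpolation; split at long ones.

    Returns a list of ``(start_frame, filled_positions)`` segments covering
    the valid portion of the trace. Gaps of ``max_gap_s`` or longer, and
    leading/trailing missing frames, delimit segments.
    """
    x = np.asarray(positions, dtype=float)
    valid = np.all(np.isfinite(x), axis=1)
    if valid.all():
        return [(0, x.copy())]
    max_gap = int(round(max_gap_s * frame_rate))

    # segment boundaries: runs of invalid frames with length >= max_gap
    segments: list[tuple[int, int]] = []  # [start, end) of frames to keep together
    n = len(x)
    i = 0
    cur_start = None
    while i < n:
        if valid[i]:
            if cur_start is None:
                cur_start = i
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        gap = j - i
        if cur_start is not None and (gap >= max_gap or j == n):
            segments.append((cur_start, i))
            cur_start = None
        i = j
    if cur_start is not None:
        segments.append((cur_start, n))

    out = []
    for s0, s1 in segments:
        seg = x[s0:s1].copy()
        segvalid = np.all(np.isfinite(seg), axis=1)
        if not segvalid.all():
            tt = np.arange(len(seg), dtype=float)
            for k in range(seg.shape[1]):
                f = interp1d(tt[segvalid], seg[segvalid, k], kind="cubic", assume_sorted=True)
                seg[~segvalid, k] = f(tt[~segvalid])
        out.append((s0, seg))
    return out


def build_trace(
    t: np.ndarray,
    whole_raw: np.ndarray,
    front_raw: np.ndarray,
    rear_raw: np.ndarray,
    frame_rate: float,
    cutoff: float = FILTER_CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> pd.DataFrame:
    """Assemble the CoV trace table: raw/filtered positions, velocity, speed.

    Whole-body velocity and planar speed come from the filtered whole-body
    CoV; front/rear filtered positions are carried for segment analyses.
    The first/last ``EDGE_FRAMES`` samples are flagged low-confidence.
    """
    n = len(t)
    df = pd.DataFrame({"frame": np.arange(n), "t_s": t})
    filtered = {}
    for name, arr in (("whole", whole_raw), ("front", front_raw), ("rear", rear_raw)):
        arrf = filter_trace(arr, frame_rate, cutoff, order)
        filtered[name] = arrf
        for k, ax in enumerate("xyz"):
            df[f"{name}_{ax}_mm"] = arr[:, k]
            df[f"{name}_{ax}_filt_mm"] = arrf[:, k]
    vel = differentiate(filtered["whole"], t)
    df["vx_mm_s"] = vel[:, 0]
    df["vy_mm_s"] = vel[:, 1]
    df["vz_mm_s"] = vel[:, 2]
    df["speed_mm_s"] = np.hypot(vel[:, 0], vel[:, 1])
    conf = np.ones(n, dtype=bool)
    conf[:EDGE_FRAMES] = False
    conf[n - EDGE_FRAMES :] = False
    df["confident"] = conf
    return df
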