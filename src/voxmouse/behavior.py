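"""Rule-based open-field behavior classification.

Per-frame rules on whole-body CoV planar speed and front CoV height:
rearing whenever the front CoV is at or above 34 mm (speed ignored);
otherwise fast ambulation at >= 60 mm/s, meandering in [10, 60) mm/s and
standing below 10 mm/s. Fast-ambulation runs are merged across sub-60 mm/s
interruptions no longer than 0.17 s; a merged run whose cumulative planar
CoV path reaches 200 mm is a directed-locomotion bout, shorter fast runs
are exploratory locomotion. Interruption frames inside a merged directed
bout inherit the bout label and count toward its path and duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BehaviorThresholds",
    "BehaviorBout",
    "BehaviorSummary",
    "classify_frame",
    "classify_frames",
    "extract_bouts",
    "summarize",
]


@dataclass(frozen=True)
class BehaviorThresholds:
    """Printed classification constants (all positive)."""

    speed_fast: float = 60.0  # mm/s
    speed_stand: float = 10.0  # mm/s
    rear_height: float = 34.0  # mm, front CoV
    directed_distance: float = 200.0  # mm
    slowing_tolerance: float = 0.17  # s

    def __post_init__(self) -> None:
        for name in ("speed_fast", "speed_stand", "rear_height", "directed_distance", "slowing_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass(frozen=True)
class BehaviorBout:
    label: str
    start: int  # frame, inclusive
    end: int  # frame, exclusive
    duration_s: float
    path_mm: float


@dataclass(frozen=True)
class BehaviorSummary:
    percent: dict  # label -> % of trial
    total_distance_mm: float
    percent_first_half: dict
    percent_second_half: dict


def classify_frame(
    speed: float, front_height: float, thresholds: BehaviorThresholds = BehaviorThresholds()
) -> str:
    """Provisional per-frame label; fast ambulation is resolved into
    directed/exploratory at the bout level."""
    if front_height >= thresholds.rear_height:
        return "rearing"
    if speed >= thresholds.speed_fast:
        return "ambulation_fast"
    if speed >= thresholds.speed_stand:
        return "meandering"
    return "standing"


def classify_frames(
    speeds: np.ndarray,
    front_heights: np.ndarray,
    thresholds: BehaviorThresholds = BehaviorThresholds(),
) -> np.ndarray:
    speeds = np.asarray(speeds, dtype=float)
    h = np.asarray(front_heights, dtype=float)
    out = np.where(
        h >= thresholds.rear_height,
        "rearing",
        np.where(
            speeds >= thresholds.speed_fast,
            "ambulation_fast",
            np.where(speeds >= thresholds.speed_stand, "meandering", "standing"),
        ),
    )
    return out.astype(object)


def _path_length(xy: np.ndarray, start: int, end: int) -> float:
    seg = xy[start:end]
    if len(seg) < 2:
        return 0.0
    return float(np.sum(np.hypot(np.diff(seg[:, 0]), np.diff(seg[:, 1]))))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def extract_bouts(
    labels: np.ndarray,
    speeds: np.ndarray,
    xy: np.ndarray,
    frame_rate: float,
    thresholds: BehaviorThresholds = BehaviorThresholds(),
) -> list[BehaviorBout]:
    """Tile the trial into behavior bouts from provisional frame labels.

    ``xy`` is the filtered whole-body planar CoV used for path lengths.
    The slowing tolerance is ``round(0.17 * frame_rate)`` frames (17 at
    100 Hz); only interruptions free of rearing frames are merged.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if n == 0:
        return []
    tol = int(round(thresholds.slowing_tolerance * frame_rate))

    fast = labels == "ambulation_fast"
    runs = _runs(fast)
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= tol and not np.any(
            labels[merged[-1][1] : s] == "rearing"
        ):
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    final = np.array(labels, dtype=object)
    for s, e in merged:
        path = _path_length(xy, s, e)
        lab = (
            "directed_locomotion"
            if path >= thresholds.directed_distance
            else "exploratory_locomotion"
        )
        final[s:e] = lab

    bouts: list[BehaviorBout] = []
    s = 0
    for i in range(1, n + 1):
        if i == n or final[i] != final[s]:
            bouts.append(
                BehaviorBout(
                    label=str(final[s]),
                    start=s,
                    end=i,
                    duration_s=(i - s) / frame_rate,
                    path_mm=_path_length(xy, s, i),
                )
            )
            s = i
    return bouts


def summarize(
    bouts: list[BehaviorBout],
    n_frames: int,
    frame_rate: float,
    xy: np.ndarray,
) -> BehaviorSummary:
    """Per-label time percentages, total planar path, and half-trial split."""
    labels = (
        "directed_locomotion",
        "exploratory_locomotion",
        "meandering",
        "standing",
        "rearing",
    )
    counts = {lab: 0 for lab in labels}
    half = n_frames // 2
    counts1 = {lab: 0 for lab in labels}
    counts2 = {lab: 0 for lab in labels}
    for b in bouts:
        counts[b.label] += b.end - b.start
        counts1[b.label] += max(0, min(b.end, half) - b.start)
        counts2[b.label] += max(0, b.end - max(b.start, half))
    pct = {lab: 100.0 * c / n_frames for lab, c in counts.items()}
    pct1 = {lab: (100.0 * c / half if half else 0.0) for lab, c in counts1.items()}
    n2 = n_frames - half
    pct2 = {lab: (100.0 * c / n2 if n2 else 0.0) for lab, c in counts2.items()}
    total = _path_length(np.asarray(xy, dtype=float), 0, n_frames)
    return BehaviorSummary(
        percent=pct,
        total_distance_mm=total,
        percent_first_half=pct1,
        percent_second_half=pct2,
    )
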