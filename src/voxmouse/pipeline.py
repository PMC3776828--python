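"""Trial configuration, orchestration, and file I/O for the full pipeline.

A trial is processed stage by stage for every frame: background subtraction
inside the tracked bounding cube, morphological cleanup (with-tail and
tailless), voxel carving with the likelihood-index volume filter, 2-means
front/rear segmentation, CoV trace assembly, behavior classification, and
gait analysis of the directed-locomotion bouts.

Outputs: trace CSV (per frame), bout JSON, gait CSV (per directed bout),
and a one-row summary CSV. Re-running on identical inputs is
byte-identical: the pipeline itself draws no random numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import re
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import gait as gt
from . import kinematics as km
from . import reconstruct as rc
from . import silhouette as sil
from .camera import CameraRig, load_calibration
from .errors import ConfigurationError, TrialLayoutError
from .scene import TAILLESS_VOLUME

log = logging.getLogger("voxmouse")

__all__ = [
    "TrialConfig",
    "PipelineResult",
    "DiskFrameSource",
    "reconstruct_frames",
    "analyse_trace",
    "process_source",
    "run_pipeline",
    "aggregate_report",
]


@dataclass(frozen=True)
class TrialConfig:
    """Every tunable constant of the pipeline; defaults are the printed values."""

    frame_rate: float = 100.0  # Hz
    voxel_edge_mm: float = 2.0
    filter_cutoff_hz: float = 20.0
    filter_order: int = 4
    speed_fast_mm_s: float = 60.0
    speed_stand_mm_s: float = 10.0
    rear_height_mm: float = 34.0
    directed_distance_mm: float = 200.0
    slowing_tolerance_s: float = 0.17
    morph_with_tail_px: int = 3
    morph_tailless_px: int = 7
    volume_band_sigma: float = 3.0
    window_clamp_frames: int = 61
    cube_margin_mm: float = 30.0
    subtract_threshold: float | str = "auto"
    subtract_floor: float = 0.05
    volume_prior_mm3: float = TAILLESS_VOLUME
    volume_prior_sigma_frac: float = 0.05
    tail_volume_extra_mm3: float = 1700.0  # prior bump for the with-tail reconstruction
    min_stats_frames: int = 10
    arena_floor_mm: float = 0.0
    arena_height_mm: float = 120.0
    head_hint: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        positive = (
            "frame_rate",
            "voxel_edge_mm",
            "filter_cutoff_hz",
            "speed_fast_mm_s",
            "speed_stand_mm_s",
            "rear_height_mm",
            "directed_distance_mm",
            "slowing_tolerance_s",
            "morph_with_tail_px",
            "morph_tailless_px",
            "volume_band_sigma",
            "window_clamp_frames",
            "cube_margin_mm",
            "volume_prior_mm3",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"config field {name} must be positive")
        if self.filter_cutoff_hz >= self.frame_rate / 2:
            raise ConfigurationError("filter cutoff must be below the Nyquist frequency")

    def thresholds(self) -> bh.BehaviorThresholds:
        return bh.BehaviorThresholds(
            speed_fast=self.speed_fast_mm_s,
            speed_stand=self.speed_stand_mm_s,
            rear_height=self.rear_height_mm,
            directed_distance=self.directed_distance_mm,
            slowing_tolerance=self.slowing_tolerance_s,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["head_hint"] = list(self.head_hint)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        d = dict(d)
        if "head_hint" in d:
            d["head_hint"] = tuple(d["head_hint"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "TrialConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Frame sources


class DiskFrameSource:
    """Reads a trial directory written by the simulator (or frame extraction).

    Layout: ``<trial>/<camera_id>/frame_%06d.png`` plus ``background.png``
    per camera and ``calibration.yaml`` at the top level.
    """

    def __init__(self, trial_dir: str):
        self.trial_dir = str(trial_dir)
        calib = os.path.join(trial_dir, "calibration.yaml")
        if not os.path.exists(calib):
            raise TrialLayoutError(f"missing calibration file {calib}")
        self.rig: CameraRig = load_calibration(calib)
        self._frames: list[list[str]] = []
        self._bg: list[np.ndarray] = []
        self._ignore: list[np.ndarray | None] = []
        pat = re.compile(r"frame_(\d+)\.png$")
        counts = []
        for cam in self.rig:
            d = os.path.join(trial_dir, cam.id)
            if not os.path.isdir(d):
                raise TrialLayoutError(f"missing camera directory {d}")
            frames = sorted(f for f in os.listdir(d) if pat.search(f))
            if not frames:
                raise TrialLayoutError(f"no frames in {d}")
            bgp = os.path.join(d, "background.png")
            if not os.path.exists(bgp):
                raise TrialLayoutError(f"missing background image {bgp}")
            self._bg.append(_load_image(bgp))
            igp = os.path.join(d, "ignore.png")
            self._ignore.append(_load_image(igp) > 0.5 if os.path.exists(igp) else None)
            self._frames.append([os.path.join(d, f) for f in frames])
            counts.append(len(frames))
        if len(set(counts)) != 1:
            raise TrialLayoutError(f"cameras disagree on frame count: {counts}")
        self.n_frames = counts[0]

    def background_crop(self, cam_idx: int, roi) -> np.ndarray:
        (r0, r1), (c0, c1) = roi
        return self._bg[cam_idx][r0:r1, c0:c1]

    def frame_crop(self, frame_idx: int, cam_idx: int, roi) -> np.ndarray:
        (r0, r1), (c0, c1) = roi
        img = _load_image(self._frames[cam_idx][frame_idx])
        return img[r0:r1, c0:c1]

    def ignore_crop(self, cam_idx: int, roi) -> np.ndarray | None:
        ig = self._ignore[cam_idx]
        if ig is None:
            return None
        (r0, r1), (c0, c1) = roi
        return ig[r0:r1, c0:c1]


def _load_image(path: str) -> np.ndarray:
    img = iio.imread(path)
    if img.dtype == np.uint8:
        return img.astype(np.float32) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float32) / 65535.0
    return img.astype(np.float32)


# ---------------------------------------------------------------------------
# Stage 1: frames -> raw CoV positions


@dataclass
class ReconstructionTrace:
    """Raw per-frame reconstruction output, before filtering."""

    t: np.ndarray
    whole: np.ndarray  # (n,3), NaN where reconstruction failed
    front: np.ndarray
    rear: np.ndarray
    volume_tailless: np.ndarray  # (n,) mm^3, final filtered volume
    volume_with_tail: np.ndarray
    threshold: np.ndarray  # (n,) final likelihood threshold tau (tailless)


def reconstruct_frames(source, rig: CameraRig, config: TrialConfig) -> ReconstructionTrace:
    """Silhouette -> carve -> likelihood filter -> segment, for every frame."""
    n = source.n_frames
    edge = config.voxel_edge_mm
    whole = np.full((n, 3), np.nan)
    front = np.full((n, 3), np.nan)
    rear = np.full((n, 3), np.nan)
    vol_tl = np.full(n, np.nan)
    vol_wt = np.full(n, np.nan)
    taus = np.full(n, np.nan)

    prior_tl = rc.VolumeStats(
        config.volume_prior_mm3, config.volume_prior_sigma_frac * config.volume_prior_mm3
    )
    prior_wt = rc.VolumeStats(
        config.volume_prior_mm3 + config.tail_volume_extra_mm3,
        config.volume_prior_sigma_frac * (config.volume_prior_mm3 + config.tail_volume_extra_mm3),
    )
    raw_history_tl: list[float] = []
    raw_history_wt: list[float] = []

    cube: sil.BoundingCube | None = None
    tracker = None
    prev_whole: np.ndarray | None = None
    dt = 1.0 / config.frame_rate
    n_missing = 0

    from .segment import SegmentationTracker

    tracker = SegmentationTracker(head_hint=np.asarray(config.head_hint, dtype=float))

    for i in range(n):
        if cube is None:
            rois = [((0, cam.image_size[1]), (0, cam.image_size[0])) for cam in rig]
        else:
            rois = [sil.restrict_to_cube(cam, cube) for cam in rig]

        masks_wt, masks_tl, origins = [], [], []
        for k, cam in enumerate(rig):
            roi = rois[k]
            if roi is None:
                masks_wt.append(None)
                masks_tl.append(None)
                origins.append((0, 0))
                continue
            frame = source.frame_crop(i, k, roi)
            bg = source.background_crop(k, roi)
            ign = source.ignore_crop(k, roi) if hasattr(source, "ignore_crop") else None
            raw = sil.subtract_background(
                frame,
                bg,
                threshold=config.subtract_threshold,
                floor=config.subtract_floor,
                ignore=ign,
            )
            masks_wt.append(sil.clean_mask(raw, "with_tail"))
            masks_tl.append(sil.clean_mask(raw, "tailless"))
            origins.append((roi[0][0], roi[1][0]))

        if cube is None:
            cube = sil.initial_cube(rig, masks_wt)

        grid = rc.VoxelGrid.from_cube(
            cube, edge, z_range=(config.arena_floor_mm, config.arena_height_mm)
        )
        C_tl, C_wt = rc.carve_multi([masks_tl, masks_wt], rig, grid, origins)

        raw_v_tl = float(np.count_nonzero(C_tl == rig.n)) * edge**3
        raw_v_wt = float(np.count_nonzero(C_wt == rig.n)) * edge**3
        if raw_v_tl > 0:
            raw_history_tl.append(raw_v_tl)
        if raw_v_wt > 0:
            raw_history_wt.append(raw_v_wt)

        stats_tl = (
            rc.estimate_volume_stats(raw_history_tl)
            if len(raw_history_tl) >= config.min_stats_frames
            else prior_tl
        )
        stats_wt = (
            rc.estimate_volume_stats(raw_history_wt)
            if len(raw_history_wt) >= config.min_stats_frames
            else prior_wt
        )

        body_tl = rc.threshold_volume(
            rc.likelihood_index(C_tl), stats_tl, grid, "tailless", config.volume_band_sigma
        )
        body_wt = rc.threshold_volume(
            rc.likelihood_index(C_wt), stats_wt, grid, "with_tail", config.volume_band_sigma
        )
        vol_tl[i] = body_tl.volume
        vol_wt[i] = body_wt.volume
        taus[i] = body_tl.threshold

        if body_tl.count == 0:
            n_missing += 1
            continue

        cov = body_tl.centroid()
        whole[i] = cov
        if body_tl.count >= 2:
            if prev_whole is not None and np.all(np.isfinite(prev_whole)):
                vel_xy = (cov[:2] - prev_whole[:2]) / dt
            else:
                vel_xy = np.zeros(2)
            seg = tracker.segment(body_tl.voxel_centers, vel_xy)
            front[i] = seg.front_centroid
            rear[i] = seg.rear_centroid
        else:
            front[i] = cov
            rear[i] = cov
        prev_whole = cov

        # track with the with-tail volume so the tail stays inside the cube
        track_pts = body_wt.voxel_centers if body_wt.count else body_tl.voxel_centers
        half = float(np.max(track_pts.max(axis=0) - track_pts.min(axis=0)) / 2.0)
        cube = sil.update_bounding_cube(half, cov, config.cube_margin_mm)

    if n_missing:
        log.warning("reconstruction produced %d empty frames of %d", n_missing, n)
    return ReconstructionTrace(
        t=np.arange(n) * dt,
        whole=whole,
        front=front,
        rear=rear,
        volume_tailless=vol_tl,
        volume_with_tail=vol_wt,
        threshold=taus,
    )


# ---------------------------------------------------------------------------
# Stage 2: raw positions -> trace, bouts, gait


@dataclass
class PipelineResult:
    trace: pd.DataFrame
    bouts: list[bh.BehaviorBout]
    summary: bh.BehaviorSummary
    gait: pd.DataFrame
    step_model: gt.StepLengthModel
    config: TrialConfig
    reconstruction: ReconstructionTrace | None = None
    trial_gait: gt.TrialGait | None = None


def analyse_trace(recon: ReconstructionTrace, config: TrialConfig, trial_id: str = "") -> PipelineResult:
    """Filter, differentiate, classify and run gait analysis on raw CoVs.

    Gaps >= 0.5 s split the trial into independently filtered segments;
    frames inside unfilled gaps keep NaN kinematics and are labelled
    ``standing`` for tiling purposes.
    """
    n = len(recon.t)
    whole_f = np.full((n, 3), np.nan)
    front_f = np.full((n, 3), np.nan)
    rear_f = np.full((n, 3), np.nan)
    speed = np.full(n, np.nan)
    vel = np.full((n, 3), np.nan)

    segs = km.interpolate_gaps(recon.whole, config.frame_rate)
    seg_front = km.interpolate_gaps(recon.front, config.frame_rate)
    seg_rear = km.interpolate_gaps(recon.rear, config.frame_rate)
    frames_df_parts = []
    for (s0, w), (_, f), (_, r) in zip(segs, seg_front, seg_rear):
        m = len(w)
        tt = recon.t[s0 : s0 + m]
        df = km.build_trace(
            tt, w, f, r, config.frame_rate, config.filter_cutoff_hz, config.filter_order
        )
        df["frame"] = np.arange(s0, s0 + m)
        frames_df_parts.append(df)
        for name, arr in (("whole", whole_f), ("front", front_f), ("rear", rear_f)):
            arr[s0 : s0 + m] = df[[f"{name}_{a}_filt_mm" for a in "xyz"]].to_numpy()
        vel[s0 : s0 + m] = df[["vx_mm_s", "vy_mm_s", "vz_mm_s"]].to_numpy()
        speed[s0 : s0 + m] = df["speed_mm_s"].to_numpy()

    trace = pd.DataFrame({"frame": np.arange(n), "t_s": recon.t})
    for name, raw, filt in (
        ("whole", recon.whole, whole_f),
        ("front", recon.front, front_f),
        ("rear", recon.rear, rear_f),
    ):
        for k, ax in enumerate("xyz"):
            trace[f"{name}_{ax}_mm"] = raw[:, k]
            trace[f"{name}_{ax}_filt_mm"] = filt[:, k]
    trace["vx_mm_s"] = vel[:, 0]
    trace["vy_mm_s"] = vel[:, 1]
    trace["speed_mm_s"] = speed
    trace["volume_tailless_mm3"] = recon.volume_tailless
    trace["volume_with_tail_mm3"] = recon.volume_with_tail
    conf = np.zeros(n, dtype=bool)
    for s0, w in segs:
        m = len(w)
        if m > 2 * km.EDGE_FRAMES:
            conf[s0 + km.EDGE_FRAMES : s0 + m - km.EDGE_FRAMES] = True
    trace["confident"] = conf

    # behavior classification on filtered whole-body speed and front CoV height
    thr = config.thresholds()
    speed_c = np.where(np.isfinite(speed), speed, 0.0)
    height_c = np.where(np.isfinite(front_f[:, 2]), front_f[:, 2], 0.0)
    labels = bh.classify_frames(speed_c, height_c, thr)
    xy = np.where(
        np.isfinite(whole_f[:, :2]), whole_f[:, :2], np.nan
    )
    # path lengths ignore NaN gaps: forward-fill for distance accumulation
    xy_filled = pd.DataFrame(xy).ffill().bfill().to_numpy()
    bouts = bh.extract_bouts(labels, speed_c, xy_filled, config.frame_rate, thr)
    summary = bh.summarize(bouts, n, config.frame_rate, xy_filled)

    # gait analysis on directed-locomotion bouts; the moving average runs
    # over the whole recording so bout edges keep full windows
    rear_filled = pd.DataFrame(rear_f[:, :2]).ffill().bfill().to_numpy()
    front_filled = pd.DataFrame(front_f[:, :2]).ffill().bfill().to_numpy()
    windows = []
    for b in bouts:
        if b.label != "directed_locomotion":
            continue
        # low-confidence filter/spline edge frames are excluded from bout stats
        s0, e0 = b.start, b.end
        while s0 < e0 and not conf[s0]:
            s0 += 1
        while e0 > s0 and not conf[e0 - 1]:
            e0 -= 1
        if e0 - s0 < gt.MIN_WINDOW or np.any(~np.isfinite(rear_f[s0:e0, :2])):
            continue
        windows.append((s0, e0))
    trial_gait = gt.TrialGait(
        rear_xy=rear_filled,
        front_xy=front_filled,
        speeds=speed_c,
        frame_rate=config.frame_rate,
        bouts=windows,
        trial_id=trial_id,
    )
    model, stats_list = gt.iterate_to_convergence([trial_gait] if windows else [])
    gait_rows = []
    for (s0, e0), st in zip(windows, stats_list):
        gait_rows.append(
            {
                "trial_id": trial_id,
                "start_s": s0 / config.frame_rate,
                "duration_s": st.duration_s,
                "avg_speed_mm_s": st.avg_speed_mm_s,
                "n_steps": st.n_steps,
                "distance_per_step_mm": st.distance_per_step_mm,
                "cadence_steps_s": st.cadence_steps_s,
                "mean_abs_dev_front_mm": st.mean_abs_dev_front_mm,
                "mean_abs_dev_rear_mm": st.mean_abs_dev_rear_mm,
                "is_gait_bout": st.is_gait_bout,
            }
        )
    gait_df = pd.DataFrame(
        gait_rows,
        columns=[
            "trial_id",
            "start_s",
            "duration_s",
            "avg_speed_mm_s",
            "n_steps",
            "distance_per_step_mm",
            "cadence_steps_s",
            "mean_abs_dev_front_mm",
            "mean_abs_dev_rear_mm",
            "is_gait_bout",
        ],
    )
    return PipelineResult(
        trace=trace,
        bouts=bouts,
        summary=summary,
        gait=gait_df,
        step_model=model,
        config=config,
        reconstruction=recon,
        trial_gait=trial_gait,
    )


def process_source(source, rig: CameraRig, config: TrialConfig, trial_id: str = "") -> PipelineResult:
    """Full in-memory pipeline on any frame source."""
    recon = reconstruct_frames(source, rig, config)
    return analyse_trace(recon, config, trial_id)


# ---------------------------------------------------------------------------
# On-disk entry points


def write_outputs(result: PipelineResult, out_dir: str, trial_id: str = "") -> dict:
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "trace": os.path.join(out_dir, "trace.csv"),
        "bouts": os.path.join(out_dir, "bouts.json"),
        "gait": os.path.join(out_dir, "gait.csv"),
        "summary": os.path.join(out_dir, "summary.csv"),
        "step_model": os.path.join(out_dir, "step_model.json"),
    }
    result.trace.to_csv(paths["trace"], index=False, float_format="%.6f")
    with open(paths["bouts"], "w") as fh:
        json.dump(
            [
                {
                    "label": b.label,
                    "start_s": b.start / result.config.frame_rate,
                    "end_s": b.end / result.config.frame_rate,
                    "path_mm": round(b.path_mm, 3),
                }
                for b in result.bouts
            ],
            fh,
            indent=1,
        )
    result.gait.to_csv(paths["gait"], index=False, float_format="%.6f")
    srow = {"trial_id": trial_id, "total_distance_mm": round(result.summary.total_distance_mm, 3)}
    for lab, v in result.summary.percent.items():
        srow[f"pct_{lab}"] = round(v, 4)
    for lab, v in result.summary.percent_first_half.items():
        srow[f"pct_h1_{lab}"] = round(v, 4)
    for lab, v in result.summary.percent_second_half.items():
        srow[f"pct_h2_{lab}"] = round(v, 4)
    pd.DataFrame([srow]).to_csv(paths["summary"], index=False)
    with open(paths["step_model"], "w") as fh:
        json.dump(
            {
                "slope": result.step_model.slope,
                "intercept": result.step_model.intercept,
                "r2": result.step_model.r2,
                "iterations": result.step_model.iterations,
                "n_points": result.step_model.n_points,
            },
            fh,
            indent=1,
        )
    return paths


def run_pipeline(trial_dir: str, config: TrialConfig | None = None, out_dir: str | None = None) -> PipelineResult:
    """Process an on-disk trial directory end to end and write all outputs."""
    config = config or TrialConfig()
    source = DiskFrameSource(trial_dir)
    trial_id = os.path.basename(os.path.normpath(trial_dir))
    log.info("processing trial %s: %d cameras, %d frames", trial_id, source.rig.n, source.n_frames)
    result = process_source(source, source.rig, config, trial_id)
    if out_dir is None:
        out_dir = os.path.join(trial_dir, "output")
    write_outputs(result, out_dir, trial_id)
    log.info(
        "trial %s: %d bouts, %.0f mm total path",
        trial_id,
        len(result.bouts),
        result.summary.total_distance_mm,
    )
    return result


def aggregate_report(summary_csvs: list[str], scores_csv: str | None = None) -> dict:
    """Cohort report: per-group means/SDs of the summary metrics, plus
    validity correlations when a score table (trial_id, score columns) is given."""
    if not summary_csvs:
        raise ConfigurationError("report needs at least one trial summary")
    df = pd.concat([pd.read_csv(p) for p in summary_csvs], ignore_index=True)
    numeric = df.select_dtypes("number")
    report = {
        "n_trials": int(len(df)),
        "mean": {c: float(numeric[c].mean()) for c in numeric.columns},
        "sd": {c: float(numeric[c].std(ddof=1)) if len(df) > 1 else 0.0 for c in numeric.columns},
    }
    if scores_csv is not None:
        scores = pd.read_csv(scores_csv)
        if "trial_id" not in scores.columns:
            raise ConfigurationError("score table must have a trial_id column")
        merged = df.merge(scores, on="trial_id", how="inner", validate="one_to_one")
        if len(merged) != len(df):
            raise ConfigurationError("score table does not match the trial ids")
        metric_cols = [c for c in numeric.columns]
        score_cols = [c for c in scores.columns if c != "trial_id"]
        corr = gt.validity_correlations(
            {c: merged[c].to_numpy() for c in metric_cols},
            {c: merged[c].to_numpy() for c in score_cols},
        )
        report["correlations"] = corr
    return report
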