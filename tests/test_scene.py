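"""Synthetic trials: scripted trajectories, the parametric mouse, rendering."""

import numpy as np
import pandas as pd
import pytest

from voxmouse import behavior as bh
from voxmouse import scene
from voxmouse.errors import RenderError, ScriptError


def loco_script(speed=150.0, duration=3.0, cadence=4.0, amplitude=3.0):
    return scene.TrialScript(
        epochs=(
            scene.Epoch(
                label="directed_locomotion",
                duration=duration,
                speed=speed,
                cadence=cadence,
                lateral_amplitude=amplitude,
            ),
        )
    )


class TestScriptTrajectory:
    def test_path_length_and_cycle_count(self):
        """3 s at 150 mm/s, 4 Hz cadence: ~450 mm path, 12 lateral cycles."""
        gt = scene.script_trajectory(loco_script(), seed=1)
        d = np.diff(gt.whole[:, :2], axis=0)
        path = np.sum(np.hypot(d[:, 0], d[:, 1]))
        assert abs(path - 450.0) < 450.0 * 0.02
        total_phase = gt.step_phase[-1] - gt.step_phase[0]
        assert abs(total_phase / (2 * np.pi) - 12.0) < 0.1
        # extrema count: 2 per cycle
        assert abs(len(gt.step_times) - 24) <= 1

    def test_standing_epoch_is_stationary(self):
        script = scene.TrialScript(epochs=(scene.Epoch(label="standing", duration=2.0),))
        gt = scene.script_trajectory(script, seed=0)
        disp = np.linalg.norm(gt.whole[-1, :2] - gt.whole[0, :2])
        assert disp < 1.0

    def test_determinism(self):
        a = scene.script_trajectory(loco_script(), seed=7)
        b = scene.script_trajectory(loco_script(), seed=7)
        assert np.array_equal(a.whole, b.whole)
        assert np.array_equal(a.step_times, b.step_times)
        c = scene.script_trajectory(loco_script(), seed=8)
        assert not np.allclose(a.whole, c.whole)

    def test_rearing_raises_front_cov(self):
        script = scene.TrialScript(epochs=(scene.Epoch(label="rearing", duration=1.0),))
        gt = scene.script_trajectory(script, seed=0)
        assert np.all(gt.front[:, 2] >= 34.0 * 1.2)
        assert np.all(np.hypot(*np.diff(gt.whole[:, :2], axis=0).T) * 100.0 < 10.0)

    def test_step_count_conservation(self):
        """Scripted cadence x duration equals the lateral cycle count exactly."""
        script = loco_script(speed=120.0, duration=2.0, cadence=3.0)
        gt = scene.script_trajectory(script, seed=3)
        cycles = (gt.step_phase[-1] - gt.step_phase[0]) / (2 * np.pi)
        # phase accumulates over n-1 inter-frame intervals of the 2 s epoch
        expected = 3.0 * (gt.n_frames - 1) / gt.frame_rate
        assert abs(cycles - expected) < 1e-9

    @pytest.mark.parametrize(
        "label,speed",
        [("standing", 50.0), ("meandering", 80.0), ("directed_locomotion", 30.0)],
    )
    def test_forbidden_speed_bands(self, label, speed):
        with pytest.raises(ScriptError):
            scene.TrialScript(epochs=(scene.Epoch(label=label, duration=2.0, speed=speed),))

    def test_labels_follow_script(self):
        script = scene.demo_script()
        gt = scene.script_trajectory(script, seed=0)
        assert set(gt.label) == {e.label for e in script.epochs}


class TestLabelConsistency:
    def test_classifier_on_ground_truth_kinematics(self):
        """Frame labels recomputed from true kinematics alone match the script
        on >= 95% of frames when epochs sit >= 20% from every threshold."""
        script = scene.TrialScript(
            epochs=(
                scene.Epoch(label="directed_locomotion", duration=2.0, speed=150.0),
                scene.Epoch(label="standing", duration=1.0),
                scene.Epoch(label="rearing", duration=1.0),
                scene.Epoch(label="meandering", duration=1.0, speed=35.0),
            )
        )
        gt = scene.script_trajectory(script, seed=5)
        labels = bh.classify_frames(gt.speed, gt.front[:, 2])
        labels = np.where(labels == "ambulation_fast", "directed_locomotion", labels)
        assert np.mean(labels == gt.label) >= 0.95


class TestPoseMouse:
    def test_front_cluster_centroid_matches_front_cov(self):
        gt = scene.script_trajectory(loco_script(), seed=2)
        for i in (0, 50, 100):
            shape = gt.shape_at(i)
            vols = np.array(
                [4.0 / 3.0 * np.pi * np.prod(e.semi_axes) for e in shape.body[1:]]
            )
            cents = np.array([e.center for e in shape.body[1:]])
            front_centroid = (vols[:, None] * cents).sum(axis=0) / vols.sum()
            assert np.linalg.norm(front_centroid - gt.front[i]) < 1.0
            assert np.allclose(shape.body[0].center, gt.rear[i])

    def test_rearing_pose_elevates_front(self):
        script = scene.TrialScript(epochs=(scene.Epoch(label="rearing", duration=0.5),))
        gt = scene.script_trajectory(script, seed=0)
        shape = gt.shape_at(10)
        vols = np.array([4.0 / 3.0 * np.pi * np.prod(e.semi_axes) for e in shape.body[1:]])
        z = np.array([e.center[2] for e in shape.body[1:]])
        assert abs((vols * z).sum() / vols.sum() - gt.front[10, 2]) < 1.0
        assert gt.front[10, 2] >= 40.0

    def test_tailless_variant_drops_only_tail(self):
        gt = scene.script_trajectory(loco_script(), seed=2)
        with_tail = scene.pose_mouse(gt.rear[0], gt.front[0], gt.heading[0], True)
        tailless = scene.pose_mouse(gt.rear[0], gt.front[0], gt.heading[0], False)
        for a, b in zip(with_tail.body, tailless.body):
            assert np.allclose(a.center, b.center) and np.allclose(a.semi_axes, b.semi_axes)
        assert len(with_tail.components()) > len(tailless.components())

    def test_component_overlap(self):
        """Adjacent body ellipsoids overlap (connected silhouette)."""
        gt = scene.script_trajectory(loco_script(), seed=2)
        shape = gt.shape_at(0)
        for a, b in zip(shape.body[:-1], shape.body[1:]):
            gap = np.linalg.norm(b.center - a.center)
            assert gap < a.semi_axes[0] + b.semi_axes[0]


class TestRendering:
    def _sphere(self, center=(0.0, 0.0, 30.0), r=20.0):
        return scene.MouseShape(
            body=(scene.Ellipsoid(np.array(center), np.full(3, r), np.eye(3)),),
            tail_spheres=(),
            present_tail=False,
        )

    def test_sphere_mask_area_matches_analytic(self, rig):
        # sphere on the lateral cameras' optical axis: circular projection
        r = 20.0
        shape = self._sphere(center=(0.0, 0.0, 78.0), r=r)
        for cam in (rig.cameras[0], rig.cameras[3]):
            mask = scene.exact_mask(shape, cam)
            pc = cam.rotation @ shape.body[0].center + cam.translation
            d = np.linalg.norm(pc)
            area = np.pi * (cam.focal[0] * r / np.sqrt(d**2 - r**2)) ** 2
            assert abs(mask.sum() - area) < 0.05 * area

    def test_no_animal_composite_equals_background(self, rig):
        shape = scene.MouseShape(body=(), tail_spheres=(), present_tail=False)
        views = scene.render_views(shape, rig, noise_sd=0.0)
        for bg, comp, mask in views:
            assert not mask.any()
            assert np.array_equal(bg, comp)

    def test_noise_is_seeded(self, rig):
        shape = self._sphere()
        v1 = scene.render_views(shape, rig, noise_sd=0.02, seed=5, frame=3)
        v2 = scene.render_views(shape, rig, noise_sd=0.02, seed=5, frame=3)
        v3 = scene.render_views(shape, rig, noise_sd=0.02, seed=6, frame=3)
        assert np.array_equal(v1[0][1], v2[0][1])
        assert not np.array_equal(v1[0][1], v3[0][1])

    def test_shape_outside_frustum_names_camera(self, rig):
        shape = self._sphere(center=(2000.0, 0.0, 30.0))
        with pytest.raises(RenderError):
            scene.render_views(shape, rig)


class TestGenerateTrial:
    def test_layout_counting_contract(self, tmp_path, small_rig):
        script = scene.TrialScript(
            epochs=(scene.Epoch(label="standing", duration=0.1),)
        )
        gt = scene.generate_trial(script, small_rig, seed=0, outdir=tmp_path / "trial")
        assert gt.n_frames == 10
        for cam in small_rig:
            d = tmp_path / "trial" / cam.id
            assert (d / "background.png").exists()
            assert len(list(d.glob("frame_*.png"))) == 10
        assert (tmp_path / "trial" / "calibration.yaml").exists()
        df = pd.read_csv(tmp_path / "trial" / "ground_truth.csv")
        assert len(df) == 10

    def test_ground_truth_csv_reproducible(self, tmp_path, small_rig):
        script = scene.TrialScript(epochs=(scene.Epoch(label="standing", duration=0.05),))
        scene.generate_trial(script, small_rig, seed=3, outdir=tmp_path / "a")
        scene.generate_trial(script, small_rig, seed=3, outdir=tmp_path / "b")
        assert (tmp_path / "a" / "ground_truth.csv").read_bytes() == (
            tmp_path / "b" / "ground_truth.csv"
        ).read_bytes()
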