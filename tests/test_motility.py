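"""Detection, linking, kinematics and motility statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from biofilmkit import motility as mo
from biofilmkit import synthgen


def gaussian_spot_frame(shape, centers, amp=0.7, sigma=1.4, background=0.1):
    canvas = np.full(shape, background)
    synthgen._add_spots(canvas, [c[0] for c in centers], [c[1] for c in centers],
                        amp, sigma)
    return np.clip(canvas, 0, 1)


class TestDetection:
    def test_subpixel_accuracy_noise_free(self):
        frame = gaussian_spot_frame((64, 64), [(20.0, 30.0)])
        det = mo.detect_particles(frame)
        assert len(det) == 1
        assert det.loc[0, "x_px"] == pytest.approx(20.0, abs=0.1)
        assert det.loc[0, "y_px"] == pytest.approx(30.0, abs=0.1)

    def test_blank_frame_no_detections(self):
        assert mo.detect_particles(np.full((32, 32), 0.1)).empty

    def test_two_separated_spots(self):
        frame = gaussian_spot_frame((64, 64), [(15.0, 15.0), (40.0, 40.0)])
        assert len(mo.detect_particles(frame)) == 2

    def test_min_mass_filters(self):
        frame = gaussian_spot_frame((64, 64), [(20.0, 20.0)])
        assert mo.detect_particles(frame, min_mass=1e6).empty

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError):
            mo.detect_particles(np.zeros((8, 8)), spot_diameter_px=4)


def brute_force_best_assignment(prev, cur, radius):
    """Enumerate all one-to-one assignments, minimise total displacement."""
    best_cost, best = np.inf, None
    n = len(cur)
    for k in range(min(len(prev), n) + 1):
        for rows in itertools.permutations(range(len(prev)), k):
            for cols in itertools.permutations(range(n), k):
                d = [np.hypot(*(np.array(prev[r]) - cur[c]))
                     for r, c in zip(rows, cols)]
                if any(x > radius for x in d):
                    continue
                # prefer more matches, then lower cost
                cost = (-k, sum(d))
                if best is None or cost < best_cost:
                    best_cost, best = cost, dict(zip(cols, rows))
    return best or {}


class TestLinking:
    @staticmethod
    def _detections(paths):
        rows = []
        for pid, path in enumerate(paths):
            for t, (x, y) in enumerate(path):
                if x is None:
                    continue
                rows.append({"frame": t, "x_px": x, "y_px": y, "mass": 1.0})
        return pd.DataFrame(rows)

    def test_constant_velocity_single_track(self):
        det = self._detections([[(i * 2.0, 5.0) for i in range(6)]])
        tr = mo.link_detections(det, search_radius_px=5.0)
        assert tr["track_id"].nunique() == 1
        steps = mo.step_table(tr, fps=1.0, pixel_size_um=1.0)
        np.testing.assert_allclose(steps["speed_um_s"], 2.0)

    def test_parallel_particles_never_swap(self):
        det = self._detections([
            [(i * 2.0, 0.0) for i in range(6)],
            [(i * 2.0, 10.0) for i in range(6)],
        ])
        tr = mo.link_detections(det, search_radius_px=5.0)
        assert tr["track_id"].nunique() == 2
        for _, g in tr.groupby("track_id"):
            assert g["y_px"].nunique() == 1

    def test_assignment_matches_bruteforce(self, rng):
        """Optimal matching agrees with exhaustive assignment enumeration."""
        for _ in range(20):
            prev = rng.uniform(0, 30, (4, 2))
            cur = prev + rng.normal(0, 1.5, (4, 2))
            det = pd.DataFrame(
                [{"frame": 0, "x_px": x, "y_px": y, "mass": 1.0} for x, y in prev]
                + [{"frame": 1, "x_px": x, "y_px": y, "mass": 1.0} for x, y in cur]
            )
            tr = mo.link_detections(det, search_radius_px=6.0)
            expect = brute_force_best_assignment(prev, cur, 6.0)
            got = {}
            for _, g in tr.groupby("track_id"):
                fr = g["frame"].tolist()
                if fr == [0, 1]:
                    i0 = np.flatnonzero((prev == g[["x_px", "y_px"]].iloc[0].to_numpy()).all(1))[0]
                    i1 = np.flatnonzero((cur == g[["x_px", "y_px"]].iloc[1].to_numpy()).all(1))[0]
                    got[i1] = i0
            assert got == expect

    def test_memory_bridges_gap(self):
        path = [(0.0, 0.0), (2.0, 0.0), (None, None), (6.0, 0.0)]
        det = self._detections([path])
        assert mo.link_detections(det, 5.0, memory_frames=1)["track_id"].nunique() == 1
        assert mo.link_detections(det, 5.0, memory_frames=0)["track_id"].nunique() == 2


class TestKinematics:
    def test_printed_speed_arithmetic(self):
        # 0.745 μm displacement per frame at 20 fps = 14.9 μm/s
        tr = pd.DataFrame({"track_id": 0, "frame": [0, 1],
                           "x_px": [0.0, 0.745], "y_px": [0.0, 0.0]})
        steps = mo.step_table(tr, fps=20.0, pixel_size_um=1.0)
        assert steps["speed_um_s"].iloc[0] == pytest.approx(14.9)

    def test_stationary_track(self):
        tr = pd.DataFrame({"track_id": 0, "frame": range(4),
                           "x_px": [1.0] * 4, "y_px": [2.0] * 4})
        kin = mo.track_kinematics(tr, 20.0, 1.0)
        assert kin.loc[0, "mean_speed_um_s"] == 0
        assert kin.loc[0, "max_speed_um_s"] == 0

    def test_closed_square_path_zero_net_displacement(self):
        tr = pd.DataFrame({"track_id": 0, "frame": range(5),
                           "x_px": [0, 1, 1, 0, 0], "y_px": [0, 0, 1, 1, 0]})
        kin = mo.track_kinematics(tr, 1.0, 1.0)
        assert kin.loc[0, "net_disp_um"] == 0
        assert kin.loc[0, "mean_speed_um_s"] > 0

    def test_single_point_track_raises(self):
        tr = pd.DataFrame({"track_id": 0, "frame": [0], "x_px": [0.0],
                           "y_px": [0.0]})
        with pytest.raises(ValueError, match="single point"):
            mo.track_kinematics(tr, 1.0, 1.0)

    def test_gap_scaled_speed(self):
        tr = pd.DataFrame({"track_id": 0, "frame": [0, 2],
                           "x_px": [0.0, 4.0], "y_px": [0.0, 0.0]})
        steps = mo.step_table(tr, fps=1.0, pixel_size_um=1.0)
        assert steps["speed_um_s"].iloc[0] == pytest.approx(2.0)


class TestPopulationStats:
    def test_hand_arithmetic(self):
        steps = pd.DataFrame({"speed_um_s": [1.0, 3.0]})
        assert mo.population_speed_stats(steps) == (2.0, 3.0, 1.0)

    def test_equal_steps_zero_sd(self):
        steps = pd.DataFrame({"speed_um_s": [2.0] * 5})
        assert mo.population_speed_stats(steps)[2] == 0.0

    def test_no_steps_raises(self):
        with pytest.raises(ValueError):
            mo.population_speed_stats(pd.DataFrame({"speed_um_s": []}))


class TestClassifyMotile:
    def test_threshold_rules(self):
        kin = pd.DataFrame({
            "mean_speed_um_s": [14.9, 5.0, 0.3],
            "net_disp_um": [30.0, 0.5, 10.0],
        })
        out = mo.classify_motile(kin)
        # fast & far = motile; fast but no net displacement = jitter;
        # slow drift = not motile
        assert out["motile"].tolist() == [True, False, False]

    def test_zero_thresholds_everything_motile(self):
        kin = pd.DataFrame({"mean_speed_um_s": [0.0], "net_disp_um": [0.0]})
        assert mo.classify_motile(kin, 0.0, 0.0)["motile"].all()

    def test_immotile_jitter_rejected_end_to_end(self):
        _, gt = synthgen.simulate_motility_video("stationary", n_cells=5,
                                                 duration_s=2.0, seed=1)
        kin = mo.track_kinematics(
            gt.positions.rename(columns={"particle": "track_id"}),
            fps=20.0, pixel_size_um=0.33)
        assert not mo.classify_motile(kin)["motile"].any()


class TestMotileFractionBinned:
    def _kin(self, xs, motile):
        return pd.DataFrame({
            "mean_x_px": xs, "mean_y_px": 0.0, "motile": motile,
            "n_points": 10,
        })

    def test_67_of_100(self):
        kin = self._kin([50.0] * 100, [True] * 67 + [False] * 33)
        out = mo.motile_fraction_binned(kin, np.array([0.0, 1.0]), 10.0)
        assert out.loc[0, "motile_fraction"] == pytest.approx(0.67)

    def test_empty_bin_is_nan(self):
        kin = self._kin([50.0], [True])
        out = mo.motile_fraction_binned(kin, np.array([0.0, 1.0, 2.0]), 10.0)
        assert out.loc[0, "motile_fraction"] == 1.0
        assert np.isnan(out.loc[1, "motile_fraction"])

    def test_overflow_bin_reported(self):
        kin = self._kin([50.0, 5000.0], [True, True])
        out = mo.motile_fraction_binned(kin, np.array([0.0, 1.0]), 10.0)
        assert (out["bin"] == -1).sum() == 1


class TestVerticalDistribution:
    def test_small_sample_median(self):
        d = mo.vertical_distribution(np.array([1.0, 2.0, 3.0, 4.0]))
        assert d.median_um == 2.5

    def test_all_at_interface(self):
        d = mo.vertical_distribution(np.full(10, 25.2))
        assert d.median_um == 25.2 and d.iqr_um == 0.0

    def test_uniform_quantiles(self, rng):
        z = rng.uniform(0, 10, 20000)
        d = mo.vertical_distribution(z)
        assert d.median_um == pytest.approx(5.0, abs=0.2)
        assert d.q25_um == pytest.approx(2.5, abs=0.2)
        assert d.q75_um == pytest.approx(7.5, abs=0.2)


class TestVelocityField:
    def _steps(self, vx, vy, x, y):
        return pd.DataFrame({"vx_um_s": vx, "vy_um_s": vy,
                             "mid_x_px": x, "mid_y_px": y})

    def test_uniform_rightward_flow(self):
        steps = self._steps([5.0] * 4, [0.0] * 4, [5, 15, 25, 35], [5] * 4)
        vx, vy, n = mo.velocity_field(steps, 10, (10, 40))
        filled = n[0] > 0
        np.testing.assert_allclose(vx[0][filled], 5.0)
        np.testing.assert_allclose(vy[0][filled], 0.0)

    def test_opposite_flows_cancel_but_count(self):
        steps = self._steps([5.0, -5.0], [0.0, 0.0], [5, 5], [5, 5])
        vx, _, n = mo.velocity_field(steps, 10, (10, 10))
        assert n[0, 0] == 2 and vx[0, 0] == pytest.approx(0.0)

    def test_empty_cells_are_nan_not_zero(self):
        steps = self._steps([1.0], [0.0], [5], [5])
        vx, _, n = mo.velocity_field(steps, 10, (20, 20))
        assert np.isnan(vx[1, 1]) and n[1, 1] == 0


class TestFocusZAssignment:
    def test_sharpest_slice_wins(self, small_zstack):
        stack, gt = small_zstack
        # blob 1 spans z 16..26; its centre plane should be the focus peak
        z = mo.assign_z_by_focus(stack, [(60.0, 60.0)], window_px=9)
        assert 16 * 0.6 <= z[0] <= 26 * 0.6


class TestExactRecoveryInvariant:
    def test_noise_free_constant_velocity_exact(self):
        """Separated constant-velocity particles are recovered exactly."""
        shape = (64, 200)
        frames = []
        truth = [(10.0, 10.0, 3.0, 0.0), (10.0, 40.0, 0.0, 1.0),
                 (180.0, 20.0, -2.0, 0.5)]
        n_frames = 10
        for t in range(n_frames):
            centers = [(x0 + vx * t, y0 + vy * t) for x0, y0, vx, vy in truth]
            frames.append(gaussian_spot_frame(shape, centers))
        det = mo.detect_video(frames)
        tr = mo.link_detections(det, search_radius_px=4.0)
        assert tr["track_id"].nunique() == 3
        assert len(tr) == 3 * n_frames
        kin = mo.track_kinematics(tr, fps=1.0, pixel_size_um=1.0)
        expected = sorted(np.hypot(vx, vy) for *_, vx, vy in truth)
        got = sorted(kin["mean_speed_um_s"])
        np.testing.assert_allclose(got, expected, atol=0.02)

    def test_every_detection_in_at_most_one_track(self, small_motility_video):
        video, _ = small_motility_video
        det = mo.detect_video(video)
        tr = mo.link_detections(det, 10.0, 1)
        assert len(tr) == len(det)
        assert tr.groupby(["frame", "x_px", "y_px"]).size().max() == 1


class TestMotileFractionUnbiased:
    def test_recovered_fractions_track_ground_truth_across_seeds(self):
        """Scaled-down bias check: a two-bin channel at three seeds recovers
        the preset fractions with small mean absolute deviation."""
        base = synthgen.get_preset("channel_day1")
        preset = synthgen.Preset(
            "two_bin_bias",
            params={**base.params, "bin_edges_mm": (0.0, 0.25, 0.5),
                    "motile_fractions": (0.6, 0.1),
                    "channel_height_px": 512},
            provenance={**base.provenance, "bin_edges_mm": "default",
                        "motile_fractions": "default",
                        "channel_height_px": "default"},
        )
        devs = []
        for seed in (0, 1, 2):
            video, _ = synthgen.simulate_channel_gradient(
                preset, cells_per_bin=50, duration_s=2.5, seed=seed)
            det = mo.detect_video(video)
            tracks = mo.link_detections(det, 5.0, 3)
            kin = mo.classify_motile(
                mo.track_kinematics(tracks, video.fps, video.pixel_size_um,
                                    drop_singletons=True))
            frac = mo.motile_fraction_binned(
                kin, np.array([0.0, 0.25, 0.5]), video.pixel_size_um)
            frac = frac[frac["bin"] >= 0]
            devs.extend(np.abs(frac["motile_fraction"].to_numpy()
                               - np.array([0.6, 0.1])))
        assert np.mean(devs) <= 0.03


class TestVelocityFieldRadial:
    def test_radial_flow_vectors_point_outward(self, rng):
        """Gridded mean vectors of a radial flow stay within 15° of radial."""
        n = 400
        ang = rng.uniform(0, 2 * np.pi, n)
        r = rng.uniform(20, 45, n)
        cx = cy = 50.0
        x, y = cx + r * np.cos(ang), cy + r * np.sin(ang)
        speed = 5.0
        steps = pd.DataFrame({
            "vx_um_s": speed * np.cos(ang), "vy_um_s": speed * np.sin(ang),
            "mid_x_px": x, "mid_y_px": y,
        })
        vx, vy, cnt = mo.velocity_field(steps, grid_px=10, frame_shape=(100, 100))
        ny, nx = cnt.shape
        for gy in range(ny):
            for gx in range(nx):
                if cnt[gy, gx] < 3:
                    continue
                px, py = gx * 10 + 5 - cx, gy * 10 + 5 - cy
                if np.hypot(px, py) < 15:
                    continue
                radial = np.arctan2(py, px)
                mean_dir = np.arctan2(vy[gy, gx], vx[gy, gx])
                diff = np.angle(np.exp(1j * (mean_dir - radial)))
                assert abs(np.degrees(diff)) <= 15
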