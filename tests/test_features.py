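import math

import numpy as np
import pandas as pd
import pytest

from trackclass import features as ft
from oracle import naive_features, random_trajectory


def _df(rows):
    return pd.DataFrame(rows)


def _traj(points, fps_extra=None, **morph):
    defaults = dict(area=100.0, perimeter=40.0, major=20.0, minor=10.0, ar=2.0)
    defaults.update(morph)
    return _df(
        [
            {"frame": i, "x": float(x), "y": float(y), **defaults}
            for i, (x, y) in enumerate(points)
        ]
    )


class TestSteps:
    def test_three_four_five_triangle(self, toy_trajectory):
        steps = ft.compute_steps(toy_trajectory, fps=25)
        assert steps.displacement == pytest.approx([5.0])
        assert steps.speed == pytest.approx([125.0])

    def test_straight_line_has_zero_turnings(self):
        traj = _traj([(0, 0), (1, 0), (2, 0), (3, 0)])
        steps = ft.compute_steps(traj, fps=25)
        assert steps.turning == pytest.approx([0.0, 0.0])

    def test_square_path_turns_by_right_angles(self):
        traj = _traj([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        steps = ft.compute_steps(traj, fps=25)
        assert steps.turning == pytest.approx([math.pi / 2] * 3)

    def test_gap_normalised_speed(self):
        # frames 0 and 5: the 10 um step took 5 frames = 0.2 s
        traj = _df(
            [
                {"frame": 0, "x": 0.0, "y": 0.0, "area": 1.0, "perimeter": 1.0,
                 "major": 2.0, "minor": 1.0, "ar": 2.0},
                {"frame": 5, "x": 10.0, "y": 0.0, "area": 1.0, "perimeter": 1.0,
                 "major": 2.0, "minor": 1.0, "ar": 2.0},
            ]
        )
        steps = ft.compute_steps(traj, fps=25)
        assert steps.speed == pytest.approx([50.0])

    def test_single_detection_raises(self):
        with pytest.raises(ft.TrajectoryTooShort):
            ft.compute_steps(_traj([(0, 0)]), fps=25)


class TestCircularSD:
    def test_identical_angles_give_zero(self):
        assert ft.circular_sd(np.zeros(10)) == pytest.approx(0.0)
        assert ft.circular_sd(np.full(5, 1.3)) == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("a", [0.2, 0.7, 1.2])
    def test_symmetric_pair_closed_form(self, a):
        expected = math.sqrt(-2 * math.log(math.cos(a)))
        assert ft.circular_sd(np.array([a, -a])) == pytest.approx(expected)

    def test_dispersion_monotone(self):
        """Wider angle spread -> smaller resultant length -> larger SD."""
        spreads = [0.1, 0.5, 1.0, 1.5]
        sds = [ft.circular_sd(np.array([s, -s, s, -s])) for s in spreads]
        assert sds == sorted(sds)
        # four symmetric compass angles: resultant length 0, SD very large
        assert ft.circular_sd(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])) > 5


class TestAggregate:
    def test_constant_trajectory(self):
        traj = _traj([(0, 0), (0, 0)])
        out = ft.aggregate_features(traj, fps=25)
        assert out["mean_area"] == 100.0
        assert out["sd_area"] == 0.0
        assert out["gross_speed"] == 0.0
        assert math.isnan(out["sd_turning"])  # no turning defined for 2 frames

    def test_detection_rate_definition(self):
        # 8 detections over frames 0..9 -> rate 0.8
        frames = [0, 1, 2, 3, 4, 5, 6, 9]
        traj = _df(
            [
                {"frame": f, "x": float(f), "y": 0.0, "area": 1.0,
                 "perimeter": 1.0, "major": 2.0, "minor": 1.0, "ar": 2.0}
                for f in frames
            ]
        )
        out = ft.aggregate_features(traj, fps=25)
        assert out["detection_rate"] == pytest.approx(0.8)
        assert out["n_frames"] == 8
        assert out["duration"] == pytest.approx(9 / 25)

    def test_oracle_equivalence_random_trajectories(self, rng):
        """Vectorised features match a naive loop re-implementation."""
        for _ in range(200):
            rows = random_trajectory(rng)
            got = ft.aggregate_features(pd.DataFrame(rows), fps=25)
            want = naive_features(rows, fps=25)
            for key, expected in want.items():
                if isinstance(expected, float) and math.isnan(expected):
                    assert math.isnan(got[key]), key
                else:
                    assert got[key] == pytest.approx(expected, rel=1e-9, abs=1e-7), key

    def test_rigid_motion_invariance(self, rng):
        rows = random_trajectory(rng, min_frames=8)
        base = ft.aggregate_features(pd.DataFrame(rows), fps=25)
        # translation
        shifted = [dict(r, x=r["x"] + 500.0, y=r["y"] - 300.0) for r in rows]
        trans = ft.aggregate_features(pd.DataFrame(shifted), fps=25)
        # rotation by 37 degrees about the origin
        th = math.radians(37)
        rot = [
            dict(
                r,
                x=r["x"] * math.cos(th) - r["y"] * math.sin(th),
                y=r["x"] * math.sin(th) + r["y"] * math.cos(th),
            )
            for r in rows
        ]
        rotd = ft.aggregate_features(pd.DataFrame(rot), fps=25)
        for key in ft.FEATURE_COLUMNS + ["net_displacement", "median_step"]:
            assert trans[key] == pytest.approx(base[key], rel=1e-9), key
            assert rotd[key] == pytest.approx(base[key], rel=1e-9, abs=1e-9), key

    def test_all_features_finite_for_clean_input(self, rng):
        rows = random_trajectory(rng, min_frames=10)
        out = ft.aggregate_features(pd.DataFrame(rows), fps=25)
        for key in ft.FEATURE_COLUMNS:
            assert np.isfinite(out[key]), key


def test_features_from_table_drops_singletons(small_experiment):
    exp, feats = small_experiment
    assert set(feats.columns) == set(ft.FEATURE_COLUMNS + ft.META_COLUMNS)
    assert (feats["detection_rate"] <= 1.0).all()
    assert (feats["mean_ar"] >= 1.0).all()
    assert (
        feats[["sd_area", "sd_perimeter", "sd_major", "sd_minor", "sd_ar"]] >= 0
    ).all().all()
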