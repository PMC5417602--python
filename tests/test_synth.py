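import math
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import trackclass as tc
from trackclass.synth import (
    NOISE_ARCHETYPE,
    SynthConfig,
    default_archetypes,
    generate_experiment,
    generate_trajectory,
    with_crossing_sizes,
)


class TestGenerateTrajectory:
    def test_quiet_archetype_constant_morphology_and_speed(self):
        arch = replace(
            default_archetypes()["Colp"],
            cv_between=0.0, cv_within=0.0, speed_cv=0.0, turn_sd_rad=0.0,
        )
        rng = np.random.default_rng(0)
        traj = generate_trajectory(rng, arch, dropout=0.0)
        assert traj["area"].nunique() == 1
        feats = tc.aggregate_features(traj, fps=25.0)
        assert feats["gross_speed"] == pytest.approx(arch.speed_um_s, rel=1e-6)
        assert feats["sd_turning"] == pytest.approx(0.0, abs=1e-9)

    def test_low_turning_sd_approaches_straight_line(self):
        arch = replace(default_archetypes()["Colp"], turn_sd_rad=1e-4)
        rng = np.random.default_rng(1)
        traj = generate_trajectory(rng, arch, dropout=0.0)
        feats = tc.aggregate_features(traj, fps=25.0)
        assert feats["sd_turning"] < 0.01
        # net displacement close to the path length for straight motion
        path = feats["gross_speed"] * feats["duration"]
        assert feats["net_displacement"] / path > 0.99

    def test_size_drift_closed_form(self):
        """-2%/day drift: day-30 cohort mean area ~ 0.98^30 x day-0 mean."""
        arch = replace(
            default_archetypes()["Colp"], size_drift_per_day=-0.02, cv_between=0.05
        )
        rng = np.random.default_rng(2)
        def cohort_mean(day, n=300):
            areas = []
            for _ in range(n):
                t = generate_trajectory(rng, arch, day=day, dropout=0.0, length_s=0.2)
                areas.append(t["area"].mean())
            return np.mean(areas)
        ratio = cohort_mean(30.0) / cohort_mean(0.0)
        assert ratio == pytest.approx(0.98**30 * 0.98**30, rel=0.03)
        # area scales with the square of the linear drift factor

    def test_temperature_shrinks_size(self):
        arch = default_archetypes()["Para"]
        assert arch.size_multiplier(0, 25.0) < arch.size_multiplier(0, 15.0)

    def test_dropout_produces_gaps(self):
        rng = np.random.default_rng(3)
        traj = generate_trajectory(
            rng, default_archetypes()["Colp"], dropout=0.3
        )
        assert len(traj) < 125
        assert traj["frame"].is_monotonic_increasing


class TestGenerateExperiment:
    def test_deterministic_under_seed(self):
        cfg = SynthConfig(sampling_days=(0.0, 10.0), seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = generate_experiment(cfg)
            b = generate_experiment(SynthConfig(sampling_days=(0.0, 10.0), seed=9))
        pd.testing.assert_frame_equal(a.trajectories.df, b.trajectories.df)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_controls_contain_only_noise(self, small_experiment):
        exp, _ = small_experiment
        controls = [m.sample_id for m in exp.metadata if m.is_control]
        assert controls
        truth_ctrl = exp.truth[exp.truth["sample_id"].isin(controls)]
        assert set(truth_ctrl["species"]) == {tc.NOISE_LABEL}

    def test_monoculture_labels_match_composition(self, small_experiment):
        exp, _ = small_experiment
        for m in exp.metadata:
            if m.richness == 1:
                (sp,) = m.composition
                labels = set(
                    exp.truth[exp.truth["sample_id"] == m.sample_id]["species"]
                )
                assert labels <= {sp, tc.NOISE_LABEL}

    def test_realized_abundance_tracks_configuration(self):
        arch = default_archetypes()
        two = {
            "Colp": replace(arch["Colp"], abundance_mean=120.0, abundance_sigma=0.05),
            "Para": replace(arch["Para"], abundance_mean=30.0, abundance_sigma=0.05),
        }
        cfg = SynthConfig(
            archetypes=two,
            sampling_days=(0.0,),
            communities=(frozenset({"Colp", "Para"}),),
            noise_rate=0.0,
            seed=4,
        )
        exp = generate_experiment(cfg)
        comm = exp.truth[exp.truth["sample_id"].str.startswith("comm")]
        counts = comm["species"].value_counts()
        assert counts["Colp"] / counts["Para"] == pytest.approx(4.0, rel=0.35)

    def test_crossing_archetypes_actually_cross(self):
        arch = with_crossing_sizes()
        a0 = arch["SpA"].major_um * arch["SpA"].size_multiplier(0, 21)
        b0 = arch["SpB"].major_um * arch["SpB"].size_multiplier(0, 21)
        a60 = arch["SpA"].major_um * arch["SpA"].size_multiplier(60, 21)
        b60 = arch["SpB"].major_um * arch["SpB"].size_multiplier(60, 21)
        assert a0 > b0 and a60 < b60

    def test_species_pass_training_filter_noise_mostly_fails(self, small_experiment):
        """The speed structure anchors the 200 um/s training floor."""
        exp, feats = small_experiment
        labeled = feats.merge(exp.truth, on=["sample_id", "trajectory_id"])
        species = labeled[labeled["species"] != tc.NOISE_LABEL]
        noise = labeled[labeled["species"] == tc.NOISE_LABEL]
        assert (species["gross_speed"] > 200).mean() > 0.8
        assert (noise["gross_speed"] <= 200).mean() > 0.8
        # a usable fraction of noise still passes the test-stringency filter
        kept, _ = tc.apply_base_filter(noise, tc.FilterConfig(), "test")
        assert len(kept) > 0.2 * len(noise)
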