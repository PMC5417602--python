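import numpy as np
import pandas as pd
import pytest

from trackclass.io import SampleMeta
from trackclass.noise import NOISE_LABEL
from trackclass.windowing import (
    TrainingSet,
    WindowConfig,
    balance_classes,
    select_window,
    window_bounds,
)


def meta(day, temp=21.0, comp=("A", "B")):
    return SampleMeta(
        sample_id=f"s_d{day}",
        microcosm_id="m",
        day=day,
        temperature=temp,
        richness=len(comp),
        composition=frozenset(comp),
    )


def make_pool(days=range(0, 61, 5), temps=(19.0, 21.0), species=("A", "B", "C")):
    rows = []
    i = 0
    for d in days:
        for t in temps:
            for sp in list(species) + [NOISE_LABEL]:
                for _ in range(4):
                    rows.append(
                        {
                            "sample_id": f"p{i}",
                            "trajectory_id": f"t{i}",
                            "species": sp,
                            "day": float(d),
                            "temperature": t,
                            "x": i * 1.0,
                        }
                    )
                    i += 1
    return pd.DataFrame(rows)


class TestWindowBounds:
    def test_centered_window(self):
        assert window_bounds(30, 10, (0, 60)) == (25, 35)

    def test_edge_window_shifted_not_shrunk(self):
        # near the start the window slides right, preserving its width
        assert window_bounds(2, 10, (0, 60)) == (0, 10)
        assert window_bounds(59, 10, (0, 60)) == (50, 60)

    def test_window_spanning_whole_experiment(self):
        assert window_bounds(30, 60, (0, 60)) == (0, 60)

    def test_window_larger_than_span_clips(self):
        assert window_bounds(5, 100, (0, 60)) == (0, 60)


class TestSelectWindow:
    def test_day_selection(self):
        pool = make_pool()
        ts = select_window(pool, meta(30), WindowConfig(window_days=10))
        assert set(ts.features["day"]) == {25.0, 30.0, 35.0}

    def test_full_window_equals_global(self):
        pool = make_pool()
        cfg = WindowConfig(window_days=60, temperature_mode="all",
                           species_pool_mode="all_species")
        ts = select_window(pool, meta(30), cfg)
        assert len(ts.features) == len(pool)

    def test_same_temperature_only(self):
        pool = make_pool()
        ts = select_window(pool, meta(30, temp=21.0), WindowConfig(window_days=10))
        assert set(ts.features["temperature"]) == {21.0}

    def test_composition_pool_restriction(self):
        pool = make_pool()
        ts = select_window(pool, meta(30, comp=("A", "B")),
                           WindowConfig(window_days=10))
        assert set(ts.features["species"]) == {"A", "B", NOISE_LABEL}

    def test_composition_subset_of_all_species(self):
        pool = make_pool()
        comp = select_window(pool, meta(30), WindowConfig(window_days=10))
        full = select_window(
            pool, meta(30),
            WindowConfig(window_days=10, species_pool_mode="all_species"),
        )
        assert set(comp.features["species"]) <= set(full.features["species"])

    def test_nested_windows(self):
        pool = make_pool()
        small = select_window(pool, meta(30), WindowConfig(window_days=10))
        large = select_window(pool, meta(30), WindowConfig(window_days=30))
        assert set(small.features["trajectory_id"]) <= set(
            large.features["trajectory_id"]
        )

    def test_empty_window_raises_naming_window(self):
        pool = make_pool(temps=(15.0,))
        with pytest.raises(ValueError, match="no training data"):
            select_window(pool, meta(30, temp=25.0), WindowConfig(window_days=10))

    def test_provenance_recorded(self):
        pool = make_pool()
        ts = select_window(pool, meta(30), WindowConfig(window_days=10))
        assert ts.provenance["day_range"] == [25.0, 35.0]
        assert ts.provenance["window_days"] == 10


class TestBalance:
    def _training(self, counts):
        rows = []
        i = 0
        for cls, n in counts.items():
            for _ in range(n):
                rows.append({"species": cls, "trajectory_id": f"t{i}"})
                i += 1
        return TrainingSet(features=pd.DataFrame(rows))

    def test_majority_downsampled_exactly(self):
        ts = self._training({"A": 5000, "B": 300})
        out = balance_classes(ts, 250, seed=0)
        assert out.class_counts == {"A": 250, "B": 250}

    def test_minority_shortfall_kept_with_warning(self):
        ts = self._training({"A": 5000, "B": 100})
        with pytest.warns(UserWarning, match="'B'"):
            out = balance_classes(ts, 250, seed=0)
        assert out.class_counts == {"A": 250, "B": 100}

    def test_deterministic_under_seed(self):
        ts = self._training({"A": 1000, "B": 1000})
        a = balance_classes(ts, 100, seed=42)
        b = balance_classes(ts, 100, seed=42)
        assert a.features["trajectory_id"].tolist() == b.features["trajectory_id"].tolist()
        c = balance_classes(ts, 100, seed=43)
        assert a.features["trajectory_id"].tolist() != c.features["trajectory_id"].tolist()

    def test_sampling_without_replacement(self):
        ts = self._training({"A": 400})
        out = balance_classes(ts, 250, seed=1)
        assert out.features["trajectory_id"].is_unique

    def test_required_class_absent_raises(self):
        ts = self._training({"A": 10})
        with pytest.raises(ValueError, match="B"):
            balance_classes(ts, 5, seed=0, required_classes={"A", "B"})
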