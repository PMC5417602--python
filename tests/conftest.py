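import sys
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

import trackclass as tc
from trackclass.synth import SynthConfig, generate_experiment, with_crossing_sizes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment():
    """Compact 2-species experiment reused across pipeline tests."""
    cfg = SynthConfig(
        sampling_days=(0.0, 5.0, 10.0, 15.0, 20.0),
        communities=(frozenset({"Colp", "Para"}),),
        seed=101,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exp = generate_experiment(cfg)
    feats = tc.features_from_table(exp.trajectories)
    return exp, feats


@pytest.fixture(scope="session")
def crossing_experiment():
    """Two species whose size distributions cross mid-experiment.

    Thirteen sampling days over 60 days; identical movement traits, so
    body size carries the class signal and a global classifier blurs it.
    """
    arch = {
        k: replace(v, abundance_mean=100.0) for k, v in with_crossing_sizes().items()
    }
    cfg = SynthConfig(
        archetypes=arch,
        sampling_days=tuple(float(d) for d in range(0, 61, 5)),
        communities=(frozenset({"SpA", "SpB"}),),
        seed=7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exp = generate_experiment(cfg)
    feats = tc.features_from_table(exp.trajectories)
    return exp, feats


def fit_mean_species_oob(
    exp, feats, target, window_days, pool_mode, n_per_class, seed=11, n_trees=500
):
    """Mean per-species OOB success (noise class excluded) for one target."""
    model = tc.WindowedRandomForest(
        feats,
        exp.metadata,
        window=tc.WindowConfig(
            window_days=window_days,
            species_pool_mode=pool_mode,
            n_per_class=n_per_class,
            seed=seed,
        ),
        noise=tc.NoiseConfig(seed=seed),
        rf=tc.RFConfig(n_trees=n_trees, seed=seed),
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(target)
    species = [c for c in res.classes if c != tc.NOISE_LABEL]
    return float(
        np.mean([res.oob_report.per_class_success[c] for c in species])
    ), res


@pytest.fixture
def toy_trajectory():
    """3-4-5 right-triangle step on consecutive frames."""
    return pd.DataFrame(
        {
            "frame": [0, 1],
            "x": [0.0, 3.0],
            "y": [0.0, 4.0],
            "area": [100.0, 100.0],
            "perimeter": [40.0, 40.0],
            "major": [20.0, 20.0],
            "minor": [10.0, 10.0],
            "ar": [2.0, 2.0],
        }
    )
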