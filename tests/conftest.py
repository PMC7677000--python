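import numpy as np
import pandas as pd
import pytest

import symbioscreen as ss


@pytest.fixture(scope="session")
def planted_config():
    """Low-noise study-design configuration with three true candidates and
    one decoy that clears the vs-medium bar but not the vs-control bar."""
    config = ss.SimFeatureConfig(
        n_features_per_mode=200,
        baseline_log_sd=0.05,
        qc_noise_sd=0.05,
        missing_rate=0.0,
        seed=11,
    )
    planted = [
        ss.PlantedCandidate(0, ("B108",), 4.0, 20.0, "492-27-3"),
        ss.PlantedCandidate(1, ("B253",), 8.0, 32.0, "110-94-1"),
        ss.PlantedCandidate(2, ("B424",), 4.0, 40.0, "816-66-0"),
        ss.PlantedCandidate(3, ("B263",), 4.0, 4.0),
    ]
    return config, planted


@pytest.fixture(scope="session")
def planted_table(planted_config):
    config, planted = planted_config
    table, truth = ss.simulate_feature_table(config, planted)
    return table, truth


@pytest.fixture(scope="session")
def cleaned_table(planted_table):
    table, truth = planted_table
    cleaned = ss.normalize(
        ss.impute_missing(ss.qc_filter(table)), "median"
    )
    return cleaned, truth


@pytest.fixture()
def two_group_matrix():
    """12 x 8 intensity matrix with one strong class-separating feature."""
    rng = np.random.default_rng(5)
    X = 10 ** rng.normal(5, 0.2, (12, 8))
    y = np.array([0.0] * 6 + [1.0] * 6)
    X[:, 3] = 10 ** (5 + y + rng.normal(0, 0.02, 12))
    labels = ["a"] * 6 + ["b"] * 6
    return X, y, labels


@pytest.fixture(scope="session")
def measured_surface_means():
    """Measured per-group mean body-surface concentrations (mg/liter)."""
    path = (
        __import__("importlib.resources", fromlist=["files"])
        .files("symbioscreen.data") / "surface_concentrations.tsv"
    )
    return pd.read_csv(path, sep="\t")
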