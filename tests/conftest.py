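import numpy as np
import pandas as pd
import pytest

from hiphoptools import (AnalysisConfig, ScreenMatrix, SimulationConfig,
                         TagIntensityTable, generate_fd_dataset,
                         generate_tag_intensities)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def random_matrix(rng):
    """Random 100x20 FD matrix with a sprinkle of missing values."""
    vals = rng.normal(size=(100, 20))
    vals[rng.random(vals.shape) < 0.05] = np.nan
    df = pd.DataFrame(vals, index=[f"g{i:03d}:het" for i in range(100)],
                      columns=[f"s{j:02d}" for j in range(20)])
    return ScreenMatrix(df, value_kind="fd", orientation="sensitivity_positive")


@pytest.fixture
def small_fd_dataset():
    cfg = SimulationConfig(seed=7, n_strains=300, n_classes=4,
                           replicate_range=(4, 4), n_unstructured=4,
                           dropout_count=20)
    return generate_fd_dataset(cfg)


@pytest.fixture
def small_tag_table():
    cfg = SimulationConfig(seed=3, n_strains=60, n_treatment_screens=4,
                           n_control_arrays=4, n_background_features=20)
    return generate_tag_intensities(cfg)


def make_tag_table(signals: dict, *, role=None, batch=None, study=None,
                   background: dict | None = None) -> TagIntensityTable:
    """Build a TagIntensityTable from {(strain, tag): {array: signal}}.

    *background* maps array -> list of unused-feature signals.
    """
    rows = []
    arrays = sorted({a for per in signals.values() for a in per})
    role = role or {a: ("control" if a.startswith("c") else "treatment")
                    for a in arrays}
    batch = batch or {a: "b0" for a in arrays}
    study = study or {a: "st0" for a in arrays}
    for (strain, tag), per_array in signals.items():
        for a, sig in per_array.items():
            rows.append((strain, tag, a, sig, role[a], batch[a], study[a], True))
    for a, sigs in (background or {}).items():
        for i, sig in enumerate(sigs):
            rows.append((f"bg{i}", "up", a, sig, role[a], batch[a], study[a],
                         False))
    return TagIntensityTable(pd.DataFrame(
        rows, columns=["strain_id", "tag", "array_id", "signal", "role",
                       "batch", "study_id", "used"]))
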