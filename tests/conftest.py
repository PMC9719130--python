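import numpy as np
import pandas as pd
import pytest

from cfmeth.simulate import SimulationConfig
from cfmeth.windows import CountMatrix, WindowSet


@pytest.fixture
def toy_windows() -> WindowSet:
    df = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "start": [0, 500, 1000, 0],
            "end": [500, 1000, 2000, 800],
            "window_id": ["w1", "w2", "w3", "w4"],
            "n_cpg": [5, 3, 8, 2],
        }
    )
    return WindowSet(df, provenance="toy")


@pytest.fixture
def toy_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.poisson(20.0, size=(50, 4)),
        index=[f"w{i:03d}" for i in range(50)],
        columns=["s1", "s2", "s3", "s4"],
    )
    return CountMatrix(values, values.sum(axis=0) + 100, provenance="toy")


@pytest.fixture
def small_config() -> SimulationConfig:
    """Scaled-down generator settings for fast unit-level checks."""
    return SimulationConfig(
        n_windows=2_000,
        depth=80_000,
        n_true_dmrs=40,
        n_confounders=60,
        n_longitudinal=4,
    )
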