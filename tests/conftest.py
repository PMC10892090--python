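import numpy as np
import pandas as pd
import pytest

from phytoactive import (
    BioactivityVector,
    FeatureMatrix,
    SyntheticConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    return generate_dataset(SyntheticConfig(n_features=200, seed=11))


@pytest.fixture()
def toy_matrix():
    """4 fractions x 3 features, hand-enterable numbers."""
    df = pd.DataFrame(
        [[10.0, 0.0, 5.0], [20.0, 1.0, 5.0], [30.0, 4.0, 5.0], [40.0, 9.0, 5.0]],
        index=["A1", "A2", "A3", "A4"],
        columns=["1.00_100.0000", "1.10_200.0000", "1.20_300.0000"],
    )
    return FeatureMatrix(df, ion_mode="NEG")


@pytest.fixture()
def toy_viability():
    return BioactivityVector(
        fraction_ids=["A1", "A2", "A3", "A4"],
        viability_pct=np.array([10.0, 40.0, 70.0, 100.0]),
    )
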