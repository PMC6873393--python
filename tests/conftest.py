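import numpy as np
import pandas as pd
import pytest

from ruleforge.latticization import DiscretizationMap


@pytest.fixture
def dmap3() -> DiscretizationMap:
    """One feature, three bins with cutoffs [2.5, 7.0]."""
    return DiscretizationMap(cutoffs={"x": [2.5, 7.0]})


@pytest.fixture
def dmap_two_features() -> DiscretizationMap:
    """Feature 'a' with 2 bins, feature 'b' with 3 bins (total 5 bits)."""
    return DiscretizationMap(cutoffs={"a": [1.0], "b": [2.5, 7.0]})


@pytest.fixture
def separable_toy() -> tuple[pd.DataFrame, list[str]]:
    """One informative feature cleanly splitting two classes."""
    rng = np.random.default_rng(7)
    lo = rng.uniform(0.0, 4.0, size=10)
    hi = rng.uniform(6.0, 10.0, size=10)
    noise = rng.normal(5.0, 1.0, size=20)
    matrix = pd.DataFrame({"sig": np.concatenate([lo, hi]), "noise": noise})
    labels = ["neg"] * 10 + ["pos"] * 10
    return matrix, labels


def binary_feature_matrix(bits: np.ndarray) -> pd.DataFrame:
    """0/1 feature matrix (columns f1..fk) for implicant battery tests."""
    bits = np.asarray(bits)
    return pd.DataFrame(
        bits.astype(float), columns=[f"f{j + 1}" for j in range(bits.shape[1])]
    )
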