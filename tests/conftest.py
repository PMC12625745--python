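import numpy as np
import pytest

from oralage import FeatureTable, SampleMetadata, SyntheticConfig, generate


@pytest.fixture
def tiny_counts() -> FeatureTable:
    """3 features x 2 samples, the smallest interesting count table."""
    return FeatureTable(
        ["ASV_a", "ASV_b", "ASV_c"],
        ["S1", "S2"],
        np.array([[5.0, 0.0], [2.0, 0.0], [1.0, 7.0]]),
        "count",
    )


@pytest.fixture
def tiny_meta() -> list[SampleMetadata]:
    return [
        SampleMetadata("S1", 35, "male"),
        SampleMetadata("S2", 6, None),
    ]


@pytest.fixture(scope="session")
def cohort():
    """A mid-sized synthetic cohort with a presence/absence age signal,
    shared across tests that only read it."""
    cfg = SyntheticConfig(
        n_samples=120, n_features=80, n_signal_features=10, seed=11
    )
    table, meta = generate(cfg)
    return table, meta
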