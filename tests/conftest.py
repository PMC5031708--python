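import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort reused by recovery-flavoured unit tests:
    6 channels, 16 participants, full-length sessions, one interaction edge."""
    from nirscausal import PlantedEdge, SynthConfig, generate_cohort

    cfg = SynthConfig(
        n_participants=16,
        n_channels=6,
        planted=(PlantedEdge(1, 4, base=0.15, inter_slope=0.05),),
        seed=42,
    )
    return generate_cohort(cfg)
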