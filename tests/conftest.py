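import numpy as np
import pytest

from voxdep.synthgen import SynthConfig, generate_cohort, generate_longitudinal


@pytest.fixture(scope="session")
def small_cohort():
    """30 speakers, tiny dims — enough structure for pipeline tests."""
    cfg = SynthConfig(n_speakers=30, embedding_dim=16, acoustic_dim=12,
                      segments_per_recording=(16, 16), alpha=2.0,
                      noise_sigma=0.1, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def longitudinal_cohort():
    """12 speakers x 3 visits on the MADRS scale."""
    cfg = SynthConfig(n_speakers=12, embedding_dim=16, acoustic_dim=8,
                      segments_per_recording=(10, 10), severity_scale="MADRS",
                      alpha=2.0, noise_sigma=0.05, seed=11)
    return generate_longitudinal(cfg, visits_per_speaker=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
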