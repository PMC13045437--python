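import pytest

from uhsr.synthetic import SynthConfig, gen_dataset


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    """Small noiseless synthetic dataset for fast structural tests."""
    return gen_dataset(SynthConfig(n_samples=400, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def medium_dataset():
    """Mid-size noisy dataset shared by training-dependent tests."""
    return gen_dataset(SynthConfig(n_samples=1200, noise_sd=0.05, seed=5))
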