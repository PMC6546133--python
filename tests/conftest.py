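import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

from supnmf import SpectraDataset, SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small grouped, labeled synthetic dataset shared across tests."""
    spec = SynthSpec(n_groups=4, spectra_per_group=30, m=120, p_dominant=4,
                     n_discriminative=2, seed=42)
    ds, truth = generate_dataset(spec)
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_ds():
    """3 spectra x 4 channels with full metadata."""
    return SpectraDataset(
        intensities=[[1.0, 0.0, 2.5, 3.0], [0.5, 1.5, 0.0, 1.0],
                     [2.0, 2.0, 2.0, 2.0]],
        mz_axis=[100.0, 200.0, 300.0, 400.0],
        labels=[0, 1, 0],
        groups=["A", "A", "B"],
        spectrum_ids=["s1", "s2", "s3"],
    )
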