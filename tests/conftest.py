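import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from localpls.io import SpectralDataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dataset(spectra, wavenumbers=None, traits=None, animal_ids=None):
    """Small hand-rolled dataset for unit tests."""
    spectra = np.asarray(spectra, dtype=float)
    n, p = spectra.shape
    if wavenumbers is None:
        wavenumbers = 1000.0 + 10.0 * np.arange(p)
    ids = np.array([f"S{i:03d}" for i in range(n)], dtype=object)
    if animal_ids is None:
        animal_ids = np.array([f"A{i:03d}" for i in range(n)], dtype=object)
    if traits is None:
        traits = {"y": spectra.sum(axis=1)}
    frame = pd.DataFrame(traits, index=pd.Index(ids, name="sample_id"))
    return SpectralDataset(
        wavenumbers=np.asarray(wavenumbers, dtype=float),
        spectra=spectra,
        sample_ids=ids,
        animal_ids=np.asarray(animal_ids, dtype=object),
        traits=frame,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
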