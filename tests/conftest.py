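import numpy as np
import pytest

from photoqspr import (KineticScheme, NoiseModel, default_component_spectra,
                       simulate_series)


@pytest.fixture
def two_component_series():
    """Factory for the standard two-species photodegradation synthetic."""

    def make(k1=1e-3, noise=0.0, seed=0, **kwargs):
        spectra = default_component_spectra(n_species=2)
        return simulate_series(spectra, KineticScheme("single", k1=k1),
                               noise=NoiseModel(noise, seed), **kwargs)

    return make


@pytest.fixture
def three_component_series():
    """Factory for the sequential A -> P1 -> P2 synthetic (trace P2 spectrum)."""

    def make(k1=1e-3, k2=2e-4, noise=0.0, seed=0):
        spectra = default_component_spectra(n_species=3)
        return simulate_series(spectra, KineticScheme("sequential", k1=k1, k2=k2),
                               noise=NoiseModel(noise, seed))

    return make


@pytest.fixture
def cosine():
    def cos(a, b):
        return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))

    return cos
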