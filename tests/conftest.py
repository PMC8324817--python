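import numpy as np
import pytest

from rhythmdeg.params import PhosphoParams, UbParams
from rhythmdeg.synthetic import WaveformSpec, make_profile


@pytest.fixture(scope="session")
def sin_profile():
    """Sinusoidal profile, mean 1, relative amplitude 0.5 (Rmax*r0 ~ 0.1511)."""
    return make_profile(WaveformSpec(rel_amplitude=0.5))


@pytest.fixture(scope="session")
def mild_profile():
    """Gentler waveform used where feasibility headroom matters."""
    return make_profile(WaveformSpec(rel_amplitude=0.3))


@pytest.fixture(scope="session")
def reference_ub_params():
    """Ubiquitination constants of the worked phospho-independent example."""
    return UbParams(u_bar=0.22, a0=234.9, a1=17880.6, a2=15347.2,
                    q=262.2, r0=1.3)


@pytest.fixture(scope="session")
def reference_phospho():
    """Tied-rate kinase chain factory matching the worked phospho example."""
    def make(n, y=152.7, k=0.013, z=0.0, l=0.0):
        return PhosphoParams.tied(n, y=y, k=k, z=z, l=l)
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
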