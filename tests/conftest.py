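import numpy as np
import pytest

from foxptools import synthgen
from foxptools.synthgen import GeneratorConfig, PhotonStreamSpec, SpeciesSpec


@pytest.fixture(scope="session")
def two_rho_stream():
    """Medium anisotropy stream: 70/30 fast/slow rotational mixture."""
    species = SpeciesSpec(
        fraction=1.0,
        lifetimes=((1.0, 4.35),),
        r0=0.38,
        rotations=((0.7, 0.2), (0.3, 60.0)),
    )
    spec = PhotonStreamSpec(
        duration_s=20.0,
        background_rate_hz=0.0,
        burst_rate_hz=300.0,
        molecular_brightness_hz=5e4,
        t_diff_ms=1.0,
        species=(species,),
    )
    return synthgen.gen_photon_stream(spec, GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def bursty_stream():
    """Sparse bursts over background, for burst-search tests."""
    spec = PhotonStreamSpec(
        duration_s=20.0,
        background_rate_hz=250.0,
        burst_rate_hz=3.0,
        molecular_brightness_hz=1e5,
        t_diff_ms=2.0,
        species=(SpeciesSpec(fraction=1.0),),
    )
    return synthgen.gen_photon_stream(spec, GeneratorConfig(seed=21))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
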