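import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from specklemode.photon_mc import Source, run_transport
from specklemode.tissue_optics import preset_geometry


@pytest.fixture(scope="session")
def dermis_preset():
    return preset_geometry("single_dermis_520")


@pytest.fixture(scope="session")
def dermis_tallies(dermis_preset):
    """One scored pencil-beam run through the 520-um dermis, reused by the
    fluence/flux tests (2e5 photons keeps it quick but well resolved)."""
    tissue, _planes, _meta = dermis_preset
    return run_transport(tissue, Source.pencil("top"), 200_000, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
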