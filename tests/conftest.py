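import numpy as np
import pytest

from maraq.phantom import AcquisitionProtocol, PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def coarse_spec():
    """Physical phantom on a coarse grid — keeps per-test volumes ~1M voxels."""
    return PhantomSpec.coarse()


@pytest.fixture(scope="session")
def eid140():
    return AcquisitionProtocol.from_table("EID-CT 140")


@pytest.fixture(scope="session")
def macro140():
    return AcquisitionProtocol.from_table("Macro-HTI 140/75")


@pytest.fixture(scope="session")
def clean_phantom(coarse_spec, eid140):
    """Noiseless, artifact-free phantom shared by read-only tests."""
    return build_phantom(coarse_spec, eid140)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
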