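import numpy as np
import pytest

from ntrtdose.beam import BeamSpec, default_6mv_spectrum
from ntrtdose.phantom import HeadPhantomParams


@pytest.fixture(scope="session")
def beam6():
    return default_6mv_spectrum()


@pytest.fixture(scope="session")
def mono_1mev():
    return BeamSpec(bin_edges=[0.999, 1.001], probabilities=[1.0], field_size=(2.0, 2.0))


@pytest.fixture(scope="session")
def small_head_params():
    """A scaled-down head geometry for fast end-to-end runs."""
    return HeadPhantomParams(
        shape=(60, 60, 80),
        semi_axes=(26.0, 26.0, 34.0),
        bone_thickness=4.0,
        ptv_edge_voxels=6,
        cavity_size=(14.0, 14.0, 12.0),
        cavity_offset_mm=18.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def water_1mev_run():
    """1 MeV pencil-ish beam on a homogeneous water slab, with fluence
    scoring; shared by the attenuation and bookkeeping checks."""
    from ntrtdose.phantom import make_slab_phantom
    from ntrtdose.materials import WATER
    from ntrtdose.transport import FieldSpec, TransportConfig, run_simulation

    ph = make_slab_phantom([(WATER, 150.0)], lateral_size=(24.0, 24.0), spacing=(2.0, 2.0, 2.0))
    beam = BeamSpec(bin_edges=[0.999, 1.001], probabilities=[1.0], field_size=(2.0, 2.0))
    cfg = TransportConfig(n_primaries=20_000, n_cycles=5, seed=11, score_fluence=True)
    return ph, run_simulation(ph, beam, FieldSpec(), cfg)
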