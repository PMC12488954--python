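import numpy as np
import pytest

from lambdabf.systems import (ParticleSystem, make_host_guest_fixture,
                              make_mini_complex_fixture,
                              make_two_particle_fixture)


@pytest.fixture(scope="session")
def host_guest():
    return make_host_guest_fixture(seed=1)


@pytest.fixture(scope="session")
def mini_complex():
    return make_mini_complex_fixture(seed=0)


@pytest.fixture(scope="session")
def two_particle():
    return make_two_particle_fixture()


@pytest.fixture
def free_particle():
    """A single uncharged, LJ-less particle (external wells attach to it)."""
    def build(x0=0.0, mass=6.0):
        return ParticleSystem(
            positions=np.array([[x0, 0.0, 0.0]]),
            masses=np.array([mass]),
            charges=np.zeros(1),
            lj_epsilon=np.zeros(1),
            lj_sigma=np.full(1, 3.0),
            roles=np.asarray(["ligand"], dtype=object),
        )
    return build


def neutral_pair(r, eps=1.0, sigma=3.0):
    """Two neutral LJ particles at separation r."""
    return ParticleSystem(
        positions=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        masses=np.array([10.0, 10.0]),
        charges=np.zeros(2),
        lj_epsilon=np.full(2, eps),
        lj_sigma=np.full(2, sigma),
        roles=np.asarray(["host", "ligand"], dtype=object),
    )
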