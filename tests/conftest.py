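import numpy as np
import pytest

from nanopockets.fixtures import make_cup_fixture, make_coated_np_fixture
from nanopockets.model_io import Structure
from nanopockets.pocket_detect import PocketParams


@pytest.fixture(scope="session")
def cup():
    """Default cup: one probe-size-selective cavity."""
    return make_cup_fixture(seed=1)


@pytest.fixture(scope="session")
def small_cup():
    """Scaled cup whose cavity (~70-80 Å³) falls below the 100 Å³ cutoff."""
    return make_cup_fixture(inner_radius=2.6, bead_radius=1.2,
                            aperture_deg=50, n_beads=70, seed=2)


@pytest.fixture(scope="session")
def np_fixture():
    """Coated nanoparticle with two carved wedge cavities."""
    return make_coated_np_fixture(seed=0, n_frames=1)


@pytest.fixture(scope="session")
def default_params():
    return PocketParams()


@pytest.fixture()
def single_atom():
    return Structure(
        ids=np.array([0]), elements=np.array(["C"], dtype=object),
        positions=np.zeros((1, 3)), radii=np.array([1.5]),
        roles=np.array(["ligand"], dtype=object))


def merge_structures(a: Structure, b: Structure, offset) -> Structure:
    """Concatenate two structures, shifting the second by ``offset`` (Å)."""
    offset = np.asarray(offset, dtype=float)
    return Structure(
        ids=np.concatenate([a.ids, b.ids + a.ids.max() + 1]),
        elements=np.concatenate([a.elements, b.elements]),
        positions=np.vstack([a.positions, b.positions + offset]),
        radii=np.concatenate([a.radii, b.radii]),
        roles=np.concatenate([a.roles, b.roles]),
    )
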