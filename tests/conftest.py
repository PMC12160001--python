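import numpy as np
import pytest

from solvmode.structure import AtomicStructure, read_xyz
from solvmode.synthetic import DropletConfig, make_droplet, make_reactive_complex


@pytest.fixture(scope="session")
def water() -> AtomicStructure:
    from importlib import resources
    with resources.as_file(
            resources.files("solvmode.data").joinpath("water.xyz")) as p:
        return read_xyz(p)


@pytest.fixture(scope="session")
def toy_rc() -> AtomicStructure:
    return make_reactive_complex()


@pytest.fixture(scope="session")
def droplet_system(toy_rc):
    """A small seeded droplet: two-atom reactive complex + 8 waters."""
    return make_droplet(toy_rc, DropletConfig(n_solvent=8, seed=42),
                        reactive_atoms={0, 1}, active_atoms={1})


def random_structure(rng: np.random.Generator, n: int) -> AtomicStructure:
    """Random well-separated atom cloud for geometric property tests."""
    symbols = tuple(rng.choice(["H", "C", "N", "O", "Cl"], size=n))
    coords = rng.uniform(-6.0, 6.0, size=(n, 3))
    return AtomicStructure(symbols, coords)
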