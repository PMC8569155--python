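import pytest

from capsidkit.geometry import build_icosahedral_lattice, build_prolate_lattice
from capsidkit.lattice import LatticeVectors


@pytest.fixture(scope="session")
def phi12_lattice():
    """Prolate (2,0)/(7,0) shell with portal — the phi12 procapsid model."""
    return build_prolate_lattice(LatticeVectors(2, 0, 7, 0), portal=True)


@pytest.fixture(scope="session")
def t4_lattice():
    """Isometric (2,0) T=4 shell — the small-capsid model."""
    return build_icosahedral_lattice(2, 0)


@pytest.fixture(scope="session")
def t4_prolate_degenerate():
    """The prolate builder's realisation of the isometric (2,0) shell."""
    return build_prolate_lattice(LatticeVectors(2, 0, 2, 0))
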