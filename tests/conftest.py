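import numpy as np
import pytest

from macrorew.core_io import Atom, Topology
from macrorew.synthgen import toy_macrocycle


@pytest.fixture(scope="session")
def macrocycle():
    """Toy 3-residue macrocycle with a 2-carbon linker: (topology, coords)."""
    return toy_macrocycle(3, 2)


@pytest.fixture()
def nma_topology():
    """N-methylacetamide: CH3-C(=O)-N(H)-CH3, built by hand.

    Atom order: C1 methyl (+3H), C2 carbonyl, O, N, HN, C3 methyl (+3H).
    """
    atoms = [
        Atom(0, "C1", "C", 0, "NMA"),
        Atom(1, "H11", "H", 0, "NMA"),
        Atom(2, "H12", "H", 0, "NMA"),
        Atom(3, "H13", "H", 0, "NMA"),
        Atom(4, "C2", "C", 0, "NMA"),
        Atom(5, "O", "O", 0, "NMA"),
        Atom(6, "N", "N", 0, "NMA"),
        Atom(7, "HN", "H", 0, "NMA"),
        Atom(8, "C3", "C", 0, "NMA"),
        Atom(9, "H31", "H", 0, "NMA"),
        Atom(10, "H32", "H", 0, "NMA"),
        Atom(11, "H33", "H", 0, "NMA"),
    ]
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4), (4, 5), (4, 6), (6, 7), (6, 8),
             (8, 9), (8, 10), (8, 11)]
    return Topology(atoms=atoms, bonds=bonds)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def dyadic_weights(rng, n, bits=20):
    """Nonuniform normalized weights that are exact multiples of 2^-bits.

    Dyadic weights make weighted counts bitwise independent of summation
    order, so 'exact recovery' assertions are meaningful in floating point.
    """
    m = rng.integers(1, 1000, size=n).astype(float)
    denom = 2**bits
    c = np.floor(m / m.sum() * denom).astype(int) + 1
    c[0] += denom - c.sum()
    assert c.sum() == denom and (c > 0).all()
    return c / denom
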