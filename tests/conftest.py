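import math

import numpy as np
import pytest

from lnbuild.bondtables import BondTargetTable
from lnbuild.complexes import Metal
from lnbuild.fixtures import make_fixture
from lnbuild.molgraph import Atom, MolecularSystem, Topology


def make_system(elements, bonds, coords=None):
    """Assemble a MolecularSystem from element symbols and (i, j, order)."""
    atoms = [Atom(i, el) for i, el in enumerate(elements)]
    topo = Topology()
    for a, b, o in bonds:
        topo.set_bond(a, b, o)
    if coords is None:
        rng = np.random.default_rng(len(elements) * 37 + len(bonds))
        coords = rng.normal(scale=2.0, size=(len(elements), 3))
    return MolecularSystem(atoms, topo, np.asarray(coords, dtype=float))


def staggered_ethane():
    """C2H6 with an exactly staggered conformation."""
    d_cc, d_ch = 1.54, 1.09
    tet = math.radians(109.47)
    coords = [[0.0, 0.0, 0.0], [0.0, 0.0, d_cc]]
    elements = ["C", "C"]
    bonds = [(0, 1, 1)]
    for k in range(3):  # H on C0, pointing -z-ish
        phi = math.radians(120.0 * k)
        coords.append([
            d_ch * math.sin(tet) * math.cos(phi),
            d_ch * math.sin(tet) * math.sin(phi),
            d_ch * math.cos(tet),
        ])
        elements.append("H")
        bonds.append((0, len(elements) - 1, 1))
    for k in range(3):  # H on C1, staggered (+60 deg)
        phi = math.radians(120.0 * k + 60.0)
        coords.append([
            d_ch * math.sin(tet) * math.cos(phi),
            d_ch * math.sin(tet) * math.sin(phi),
            d_cc - d_ch * math.cos(tet),
        ])
        elements.append("H")
        bonds.append((1, len(elements) - 1, 1))
    return make_system(elements, bonds, coords)


def benzene_ring():
    """C6H6, planar hexagon, aromatic bond orders."""
    elements, bonds, coords = [], [], []
    for k in range(6):
        ang = math.radians(60.0 * k)
        coords.append([1.39 * math.cos(ang), 1.39 * math.sin(ang), 0.0])
        elements.append("C")
    for k in range(6):
        bonds.append((k, (k + 1) % 6, 1.5))
    for k in range(6):
        ang = math.radians(60.0 * k)
        coords.append([2.47 * math.cos(ang), 2.47 * math.sin(ang), 0.0])
        elements.append("H")
        bonds.append((k, 6 + k, 1))
    return make_system(elements, bonds, coords)


def butane_chain():
    """n-butane heavy-atom zigzag with explicit hydrogens."""
    elements = ["C", "C", "C", "C"]
    bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1)]
    coords = [[0.0, 0.0, 0.0], [1.4, 0.6, 0.0], [2.8, 0.0, 0.0], [4.2, 0.6, 0.0]]
    h_offsets = {
        0: [(-0.6, -0.6, 0.8), (-0.6, -0.6, -0.8), (0.3, 0.9, 0.0)],
        1: [(1.4, 1.2, 0.9), (1.4, 1.2, -0.9)],
        2: [(2.8, -0.6, 0.9), (2.8, -0.6, -0.9)],
        3: [(4.8, 0.0, 0.8), (4.8, 0.0, -0.8), (3.9, 1.5, 0.0)],
    }
    for c, offs in h_offsets.items():
        for off in offs:
            elements.append("H")
            coords.append(list(off))
            bonds.append((c, len(elements) - 1, 1))
    return make_system(elements, bonds, coords)


def ethanol_like():
    """CH3-CH2-OH: 9 atoms."""
    elements = ["C", "C", "O"]
    bonds = [(0, 1, 1), (1, 2, 1)]
    coords = [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.1, 1.3, 0.0]]
    for k, off in enumerate([(-0.5, 0.9, 0.5), (-0.5, -0.9, 0.5), (-0.5, 0.0, -1.0)]):
        elements.append("H")
        coords.append([off[0], off[1], off[2]])
        bonds.append((0, 3 + k, 1))
    for k, off in enumerate([(1.9, -0.6, 0.8), (1.9, -0.6, -0.8)]):
        elements.append("H")
        coords.append(list(off))
        bonds.append((1, 6 + k, 1))
    elements.append("H")
    coords.append([3.05, 1.2, 0.0])
    bonds.append((2, 8, 1))
    return make_system(elements, bonds, coords)


@pytest.fixture(scope="session")
def bond_table():
    return BondTargetTable.default()


@pytest.fixture
def water():
    return make_fixture("water")


@pytest.fixture
def nitrate():
    return make_fixture("nitrate")


@pytest.fixture
def eu3():
    return Metal("Eu", 3)
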