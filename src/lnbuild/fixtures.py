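"""Built-in template ligands with idealized geometries.

Every fixture is generated programmatically (no data files) with standard
bond lengths and angles, explicit bond orders and declared teeth, so small
complexes can be assembled and tested without any external structure input.

The ``vanillinate`` template is a synthetic stand-in: a minimal asymmetric
O,O-chelator (an acetylacetonate with one methyl replaced by hydrogen) whose
two oxygen teeth have distinct chemical environments, i.e. a generic (AB)
bidentate; it is not the literal vanillin anion.
"""

from __future__ import annotations

import math

import numpy as np

from .complexes import Ligand
from .molgraph import Atom, InputError, MolecularSystem, Topology

__all__ = ["make_fixture", "FIXTURE_NAMES"]


def _system(elements, coords, bonds) -> MolecularSystem:
    atoms = [Atom(i, el) for i, el in enumerate(elements)]
    topo = Topology()
    for a, b, o in bonds:
        topo.set_bond(a, b, o)
    return MolecularSystem(atoms, topo, np.asarray(coords, dtype=float))


def _water() -> Ligand:
    r, half = 0.9572, math.radians(104.52 / 2)
    coords = [
        [0.0, 0.0, 0.0],
        [r * math.sin(half), 0.0, r * math.cos(half)],
        [-r * math.sin(half), 0.0, r * math.cos(half)],
    ]
    sys_ = _system(["O", "H", "H"], coords, [(0, 1, 1), (0, 2, 1)])
    return Ligand(sys_, teeth=(0,), charge=0, name="water")


def _ammonia() -> Ligand:
    r = 1.012
    theta = math.asin(math.sqrt((1.0 - math.cos(math.radians(106.7))) / 1.5))
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = math.radians(120.0 * k)
        coords.append(
            [
                r * math.sin(theta) * math.cos(phi),
                r * math.sin(theta) * math.sin(phi),
                r * math.cos(theta),
            ]
        )
    sys_ = _system(
        ["N", "H", "H", "H"], coords, [(0, 1, 1), (0, 2, 1), (0, 3, 1)]
    )
    return Ligand(sys_, teeth=(0,), charge=0, name="ammonia")


def _chloride() -> Ligand:
    sys_ = _system(["Cl"], [[0.0, 0.0, 0.0]], [])
    return Ligand(sys_, teeth=(0,), charge=-1, name="chloride")


def _nitrate() -> Ligand:
    r = 1.256
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = math.radians(120.0 * k)
        coords.append([r * math.cos(phi), r * math.sin(phi), 0.0])
    sys_ = _system(
        ["N", "O", "O", "O"],
        coords,
        [(0, 1, 1.5), (0, 2, 1.5), (0, 3, 1.5)],
    )
    # chelating kappa-O,O' nitrate: teeth are two of the three equivalent O
    return Ligand(sys_, teeth=(1, 2), charge=-1, name="nitrate")


def _nitrite() -> Ligand:
    r, half = 1.24, math.radians(115.0 / 2)
    coords = [
        [0.0, 0.0, 0.0],
        [r * math.sin(half), 0.0, r * math.cos(half)],
        [-r * math.sin(half), 0.0, r * math.cos(half)],
    ]
    sys_ = _system(["N", "O", "O"], coords, [(0, 1, 1.5), (0, 2, 1.5)])
    # N-bound (nitro) monodentate
    return Ligand(sys_, teeth=(0,), charge=-1, name="nitrite")


def _chelate_backbone(methyls: tuple[bool, bool]):
    """Planar O-C-C-C-O chelate skeleton with optional methyl substituents.

    Returns (elements, coords, bonds, teeth serials).
    """
    d_cc, d_co, d_cme, d_ch = 1.40, 1.28, 1.50, 1.09
    c3 = np.array([0.0, 0.0, 0.0])  # central carbon
    up = math.radians(120.0)
    c2 = c3 + d_cc * np.array([math.cos(math.radians(210)), math.sin(math.radians(210)), 0])
    c4 = c3 + d_cc * np.array([math.cos(math.radians(-30)), math.sin(math.radians(-30)), 0])
    # carbonyl/enolate oxygens point "down", toward the future metal
    o1 = c2 + d_co * np.array([math.cos(math.radians(270)), math.sin(math.radians(270)), 0])
    o5 = c4 + d_co * np.array([math.cos(math.radians(270)), math.sin(math.radians(270)), 0])
    h3 = c3 + d_ch * np.array([0.0, 1.0, 0.0])
    elements = ["O", "C", "C", "C", "O", "H"]
    coords = [o1, c2, c3, c4, o5, h3]
    bonds = [
        (0, 1, 1.5), (1, 2, 1.5), (2, 3, 1.5), (3, 4, 1.5), (2, 5, 1),
    ]
    for side, has_methyl in enumerate(methyls):
        cc = c2 if side == 0 else c4
        direction = np.array(
            [math.cos(math.radians(150 if side == 0 else 30)),
             math.sin(math.radians(150 if side == 0 else 30)), 0.0]
        )
        if has_methyl:
            cme = cc + d_cme * direction
            mi = len(elements)
            elements.append("C")
            coords.append(cme)
            bonds.append((1 if side == 0 else 3, mi, 1))
            # tetrahedral hydrogens on the methyl
            axis = direction
            perp1 = np.array([0.0, 0.0, 1.0])
            perp2 = np.cross(axis, perp1)
            for k in range(3):
                ang = math.radians(120.0 * k)
                hdir = (
                    math.cos(math.radians(70.5)) * axis
                    + math.sin(math.radians(70.5))
                    * (math.cos(ang) * perp1 + math.sin(ang) * perp2)
                )
                elements.append("H")
                coords.append(cme + d_ch * hdir)
                bonds.append((mi, len(elements) - 1, 1))
        else:
            elements.append("H")
            coords.append(cc + d_ch * direction)
            bonds.append((1 if side == 0 else 3, len(elements) - 1, 1))
    return elements, coords, bonds, (0, 4)


def _acetylacetonate() -> Ligand:
    elements, coords, bonds, teeth = _chelate_backbone((True, True))
    return Ligand(_system(elements, coords, bonds), teeth, -1, "acetylacetonate")


def _vanillinate() -> Ligand:
    # synthetic asymmetric (AB) O,O-chelator: methyl on one side only
    elements, coords, bonds, teeth = _chelate_backbone((True, False))
    return Ligand(_system(elements, coords, bonds), teeth, -1, "vanillinate")


def _bipyridine() -> Ligand:
    d_ring, d_inter, d_ch = 1.39, 1.48, 1.08
    half = d_inter / 2.0
    center_a = np.array([half + d_ring, 0.0, 0.0])
    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int, float]] = []

    def add_ring(sign: float) -> None:
        base = len(elements)
        # vertex angles: 180 deg vertex is the link carbon; 120 deg is N (+y)
        ring_serials = []
        for k, ang in enumerate((180, 120, 60, 0, -60, -120)):
            pos = sign * (center_a + d_ring * np.array(
                [math.cos(math.radians(ang)), 0.0, 0.0]
            )) + d_ring * np.array([0.0, math.sin(math.radians(ang)), 0.0])
            el = "N" if k == 1 else "C"
            elements.append(el)
            coords.append(pos)
            ring_serials.append(base + k)
        for k in range(6):
            bonds.append((ring_serials[k], ring_serials[(k + 1) % 6], 1.5))
        # hydrogens on C3-C6 (k = 2..5)
        for k in range(2, 6):
            ang = (180, 120, 60, 0, -60, -120)[k]
            direction = np.array(
                [sign * math.cos(math.radians(ang)), math.sin(math.radians(ang)), 0.0]
            )
            elements.append("H")
            coords.append(coords[ring_serials[k]] + d_ch * direction)
            bonds.append((ring_serials[k], len(elements) - 1, 1))

    add_ring(+1.0)
    add_ring(-1.0)
    bonds.append((0, 10, 1))  # inter-ring C2-C2'
    sys_ = _system(elements, coords, bonds)
    return Ligand(sys_, teeth=(1, 11), charge=0, name="bipyridine")


_FIXTURES = {
    "water": _water,
    "ammonia": _ammonia,
    "chloride": _chloride,
    "nitrate": _nitrate,
    "nitrite": _nitrite,
    "acetylacetonate": _acetylacetonate,
    "vanillinate": _vanillinate,
    "bipyridine": _bipyridine,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> Ligand:
    """Deterministic idealized template ligand by name."""
    try:
        build = _FIXTURES[name]
    except KeyError:
        raise InputError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return build()
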