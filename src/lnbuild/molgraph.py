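"""Molecular graphs: atoms, bond topology, cycles, proper dihedrals, free
torsions and torsional updates of Cartesian geometry.

A molecular system is a triple (atom list, topology function, geometry
matrix).  The topology function tau maps unordered atom pairs to one of the
five allowed bond orders {0, 1, 1.5, 2, 3}; 1 doubles as the coordination
bond order.  Atom serials are 0-based row indices into the |A| x 3 geometry
matrix (Angstrom).

Free torsions are the only internal degrees of freedom considered downstream:
proper dihedrals whose internal bond does not lie on any ring.  Rotating a
free torsion moves the smaller of the two connected components obtained by
deleting the internal bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

ALLOWED_BOND_ORDERS = (1, 1.5, 2, 3)

GEOM_TOL = 1e-8  # Angstrom, geometric identity
UNIT_TOL = 1e-8  # unit-vector check


class InputError(ValueError):
    """Invalid user input (unknown serial, malformed value...)."""


@dataclass(frozen=True)
class Atom:
    serial: int
    element: str

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


class Topology:
    """Symmetric bond-order map over unordered atom pairs."""

    def __init__(self) -> None:
        self._orders: dict[tuple[int, int], float] = {}
        self._adj: dict[int, set[int]] = {}

    @staticmethod
    def _key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def set_bond(self, a: int, b: int, order: float) -> None:
        if a == b:
            raise InputError("atoms cannot bond to themselves")
        if order not in ALLOWED_BOND_ORDERS:
            raise InputError(
                f"bond order {order!r} not in allowed set {ALLOWED_BOND_ORDERS}"
            )
        self._orders[self._key(a, b)] = order
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    def order(self, a: int, b: int) -> float:
        if a == b:
            return 0.0
        return self._orders.get(self._key(a, b), 0.0)

    def bonds(self) -> list[tuple[int, int, float]]:
        return [(a, b, o) for (a, b), o in sorted(self._orders.items())]

    def adjacency(self, a: int) -> set[int]:
        return set(self._adj.get(a, set()))

    def copy(self) -> "Topology":
        t = Topology()
        t._orders = dict(self._orders)
        t._adj = {k: set(v) for k, v in self._adj.items()}
        return t


@dataclass
class MolecularSystem:
    """Atoms + topology + geometry; the in-memory molecule container."""

    atoms: list[Atom]
    topology: Topology
    X: np.ndarray  # |A| x 3, Angstrom

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.atoms), 3):
            raise InputError(
                f"geometry matrix shape {self.X.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.X)):
            raise InputError("geometry matrix contains non-finite entries")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            list(self.atoms), self.topology.copy(), self.X.copy()
        )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((a, b) for a, b, _ in self.topology.bonds())
        return g


@dataclass(frozen=True)
class Dihedral:
    """Proper dihedral e1-i1-i2-e2 keyed on its internal pair."""

    e1: int
    i1: int
    i2: int
    e2: int


@dataclass(frozen=True)
class FreeTorsion:
    dihedral: Dihedral
    moving_set: frozenset[int]
    fixed_set: frozenset[int]

    @property
    def axis_atoms(self) -> tuple[int, int]:
        return (self.dihedral.i1, self.dihedral.i2)


def neighbors(system: MolecularSystem, a: int) -> set[int]:
    """Set of atoms bonded to ``a`` (tau(a, b) != 0)."""
    if not 0 <= a < system.n_atoms:
        raise InputError(f"unknown atom serial {a}")
    return system.topology.adjacency(a)


def sorted_neighborhood(system: MolecularSystem, a: int, origin: int) -> list[int]:
    """Neighbors of ``a`` ordered by increasing distance from ``origin``."""
    ns = neighbors(system, a)
    o = system.X[origin]
    return sorted(ns, key=lambda b: (float(np.linalg.norm(system.X[b] - o)), b))


def find_cycles(system: MolecularSystem) -> list[list[int]]:
    """A cycle basis of the bond graph as ordered atom sequences.

    Every atom that lies on at least one simple cycle of the graph appears in
    at least one returned cycle, which is the property consumed downstream
    (in-ring dihedrals are frozen).
    """
    g = system.graph()
    cycles = []
    for cyc in nx.cycle_basis(g):
        if len(cyc) >= 3:
            cycles.append([int(v) for v in cyc])
    return cycles


def cycle_edges(system: MolecularSystem) -> set[frozenset[int]]:
    """Bonds lying on at least one cycle (i.e. non-bridge bonds)."""
    g = system.graph()
    bridges = set(frozenset(e) for e in nx.bridges(g))
    return {
        frozenset((a, b))
        for a, b, _ in system.topology.bonds()
        if frozenset((a, b)) not in bridges
    }


def _qualifying_externals(
    system: MolecularSystem, i1: int, i2: int
) -> tuple[int, int] | None:
    """Lowest-serial (e1, e2) satisfying the proper-dihedral conditions."""
    n1 = neighbors(system, i1)
    n2 = neighbors(system, i2)
    for e1 in sorted(n1):
        if e1 == i2 or e1 in n2:
            continue
        ne1 = neighbors(system, e1)
        for e2 in sorted(n2):
            if e2 == i1 or e2 in ne1 or e2 in n1:
                continue
            return e1, e2
    return None


def enumerate_free_torsions(system: MolecularSystem) -> list[FreeTorsion]:
    """All unique free torsions: one per rotatable internal bond.

    A bond qualifies if it carries a proper dihedral (externals exist on both
    sides) and does not lie on a cycle.
    """
    in_cycle = cycle_edges(system)
    torsions = []
    for a, b, _ in system.topology.bonds():
        if frozenset((a, b)) in in_cycle:
            continue
        i1, i2 = (a, b) if a < b else (b, a)
        ext = _qualifying_externals(system, i1, i2)
        if ext is None:
            continue
        e1, e2 = ext
        moving, fixed = split_torsion_sets(system, Dihedral(e1, i1, i2, e2))
        torsions.append(
            FreeTorsion(Dihedral(e1, i1, i2, e2), frozenset(moving), frozenset(fixed))
        )
    return torsions


def split_torsion_sets(
    system: MolecularSystem, t: Dihedral
) -> tuple[set[int], set[int]]:
    """Split atoms into (moving, fixed) halves across the i1-i2 bond.

    The moving set is the smaller connected component after deleting the bond;
    equal sizes break toward the i2 side.
    """
    g = system.graph()
    if not g.has_edge(t.i1, t.i2):
        raise InputError(f"no bond between internal atoms {t.i1} and {t.i2}")
    g.remove_edge(t.i1, t.i2)
    comp1 = nx.node_connected_component(g, t.i1)
    if t.i2 in comp1:
        raise InputError(
            f"bond {t.i1}-{t.i2} lies on a cycle; not a valid free torsion"
        )
    comp2 = nx.node_connected_component(g, t.i2)
    if len(comp1) < len(comp2):
        return set(comp1), set(comp2)
    return set(comp2), set(comp1)


def rotation_about_axis(u: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation by ``angle_deg`` about unit axis ``u`` through origin.

    Built as the factor product: project the axis into the xz plane, align it
    with z, rotate about z, then undo the two alignments.  The axis-parallel-
    to-z case (d = 0) is a removable singularity handled with identity
    factors.
    """
    u = np.asarray(u, dtype=float)
    norm = np.linalg.norm(u)
    if norm < UNIT_TOL:
        raise InputError("rotation axis must be a non-zero vector")
    if abs(norm - 1.0) > 1e-6:
        raise InputError("rotation axis must be a unit vector")
    s, t, w = u / norm
    d = np.hypot(s, t)
    phi = np.radians(angle_deg)
    Rz = np.array(
        [
            [np.cos(phi), -np.sin(phi), 0.0],
            [np.sin(phi), np.cos(phi), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    if d < UNIT_TOL:
        Txz = np.eye(3)
        w = 1.0 if w > 0 else -1.0
        Tz = np.array([[w, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, w]])
    else:
        mu, nu = s / d, t / d
        Txz = np.array([[mu, nu, 0.0], [-nu, mu, 0.0], [0.0, 0.0, 1.0]])
        Tz = np.array([[w, 0.0, -d], [0.0, 1.0, 0.0], [d, 0.0, w]])
    return Txz.T @ Tz.T @ Rz @ Tz @ Txz


def apply_torsion(
    system: MolecularSystem, t: FreeTorsion, angle_deg: float
) -> np.ndarray:
    """Geometry with the torsion's moving set rotated by ``angle_deg``.

    The axis runs along X[i1] - X[i2] and passes through X[i1], so bond
    lengths are preserved; only moving-set rows change.
    """
    i1, i2 = t.axis_atoms
    X = system.X.copy()
    axis = X[i1] - X[i2]
    norm = np.linalg.norm(axis)
    if norm < UNIT_TOL:
        raise InputError("degenerate torsion axis: coincident internal atoms")
    R = rotation_about_axis(axis / norm, angle_deg)
    idx = sorted(t.moving_set)
    origin = X[i1]
    X[idx] = (X[idx] - origin) @ R.T + origin
    return X


def measure_dihedral(X: np.ndarray, e1: int, i1: int, i2: int, e2: int) -> float:
    """Signed dihedral angle e1-i1-i2-e2 in degrees, IUPAC sign convention."""
    b0 = X[e1] - X[i1]
    b1 = X[i2] - X[i1]
    b2 = X[e2] - X[i2]
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))
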