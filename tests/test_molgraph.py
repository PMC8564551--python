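"""Molecular-graph layer: neighborhoods, cycles, free torsions, rotations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lnbuild.molgraph import (
    Dihedral,
    InputError,
    apply_torsion,
    cycle_edges,
    enumerate_free_torsions,
    find_cycles,
    measure_dihedral,
    neighbors,
    rotation_about_axis,
    split_torsion_sets,
)

from conftest import (
    benzene_ring,
    butane_chain,
    ethanol_like,
    make_system,
    staggered_ethane,
)


# -- independent oracles ----------------------------------------------------

def brute_force_cycle_atoms(system):
    """Atoms on at least one simple cycle, by exhaustive DFS path search."""
    adj = {a.serial: system.topology.adjacency(a.serial) for a in system.atoms}
    on_cycle = set()

    def dfs(start, node, path):
        for nxt in adj[node]:
            if nxt == start and len(path) >= 3:
                on_cycle.update(path)
            elif nxt not in path and nxt > start:
                dfs(start, nxt, path + [nxt])

    for a in adj:
        dfs(a, a, [a])
    return on_cycle


def brute_force_torsion_bonds(system):
    """Internal pairs of proper dihedrals not on a cycle, by scanning all
    atom quadruples against the membership conditions."""
    n = system.n_atoms
    N = {a: neighbors(system, a) for a in range(n)}
    in_cycle = cycle_edges(system)
    pairs = set()
    for e1, i1, i2, e2 in itertools.permutations(range(n), 4):
        if (
            e1 in N[i1]
            and i2 in N[i1]
            and e1 not in N[i2]
            and e2 in N[i2]
            and e2 not in N[e1]
            and e2 not in N[i1]
        ):
            if frozenset((i1, i2)) not in in_cycle:
                pairs.add(frozenset((i1, i2)))
    return pairs


def rodrigues(u, angle_deg):
    u = np.asarray(u, dtype=float)
    t = np.radians(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * K @ K


# -- neighborhoods ----------------------------------------------------------

def test_neighbors_water_and_symmetry(water):
    sys_ = water.system
    assert neighbors(sys_, 0) == {1, 2}
    assert neighbors(sys_, 1) == {0}
    assert sys_.topology.order(0, 0) == 0.0
    for a in range(sys_.n_atoms):
        for b in neighbors(sys_, a):
            assert a in neighbors(sys_, b)


def test_neighbors_isolated_atom_and_bad_serial():
    sys_ = make_system(["Cl"], [])
    assert neighbors(sys_, 0) == set()
    with pytest.raises(InputError):
        neighbors(sys_, 5)


def test_self_bond_rejected():
    from lnbuild.molgraph import Topology

    with pytest.raises(InputError):
        Topology().set_bond(2, 2, 1)


def test_disallowed_bond_order_rejected():
    from lnbuild.molgraph import Topology

    with pytest.raises(InputError):
        Topology().set_bond(0, 1, 2.5)


# -- cycles -----------------------------------------------------------------

@pytest.mark.parametrize(
    "builder,expected_cycles",
    [
        (lambda: make_system(["C"] * 3, [(0, 1, 1), (1, 2, 1)]), 0),
        (benzene_ring, 1),
    ],
)
def test_cycle_counts(builder, expected_cycles):
    system = builder()
    cycles = find_cycles(system)
    assert len(cycles) == expected_cycles
    for cyc in cycles:
        assert len(cyc) >= 3
        assert len(set(cyc)) == len(cyc)
        ring = cyc + [cyc[0]]
        for a, b in zip(ring, ring[1:]):
            assert system.topology.order(a, b) != 0


def test_fused_free_biphenyl_like_two_rings():
    # two 6-rings joined by one bond: no cycle spans the inter-ring bond
    elements = ["C"] * 12
    bonds = [(k, (k + 1) % 6, 1.5) for k in range(6)]
    bonds += [(6 + k, 6 + (k + 1) % 6, 1.5) for k in range(6)]
    bonds.append((0, 6, 1))
    system = make_system(elements, bonds)
    cycles = find_cycles(system)
    assert len(cycles) == 2
    assert all(len(c) == 6 for c in cycles)
    assert frozenset((0, 6)) not in cycle_edges(system)


@pytest.mark.parametrize(
    "builder",
    [staggered_ethane, benzene_ring, butane_chain, ethanol_like],
    ids=["ethane", "benzene", "butane", "ethanol"],
)
def test_cycle_membership_matches_brute_force(builder):
    system = builder()
    expected = brute_force_cycle_atoms(system)
    got = {a for cyc in find_cycles(system) for a in cyc}
    assert got == expected


def test_cycle_membership_brute_force_fused_bicyclic():
    # bicyclo[2.2.0]-like fused pair sharing an edge: all atoms cyclic
    bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 0, 1), (3, 4, 1), (4, 5, 1), (5, 0, 1)]
    system = make_system(["C"] * 6, bonds)
    assert {a for c in find_cycles(system) for a in c} == brute_force_cycle_atoms(system)


# -- free torsions ----------------------------------------------------------

@pytest.mark.parametrize(
    "builder,n_torsions",
    [
        (staggered_ethane, 1),
        (benzene_ring, 0),
        (butane_chain, 3),
        (ethanol_like, 2),
    ],
    ids=["ethane", "benzene", "butane", "ethanol"],
)
def test_free_torsion_counts_match_brute_force(builder, n_torsions):
    system = builder()
    torsions = enumerate_free_torsions(system)
    assert len(torsions) == n_torsions
    got = {frozenset(t.axis_atoms) for t in torsions}
    assert got == brute_force_torsion_bonds(system)


def test_torsion_externals_lowest_serial():
    system = staggered_ethane()
    (t,) = enumerate_free_torsions(system)
    assert t.dihedral.e1 == min(
        b for b in neighbors(system, t.dihedral.i1) if b != t.dihedral.i2
    )
    assert t.dihedral.e2 == min(
        b for b in neighbors(system, t.dihedral.i2) if b != t.dihedral.i1
    )


def test_torsion_invariant_under_reserialization():
    """Relabeling atoms permutes the torsion bonds accordingly."""
    system = butane_chain()
    rng = np.random.default_rng(11)
    perm = rng.permutation(system.n_atoms)
    elements = [None] * system.n_atoms
    for old, atom in enumerate(system.atoms):
        elements[perm[old]] = atom.element
    bonds = [(perm[a], perm[b], o) for a, b, o in system.topology.bonds()]
    coords = np.empty_like(system.X)
    coords[perm] = system.X
    shuffled = make_system(elements, bonds, coords)
    orig = {frozenset(t.axis_atoms) for t in enumerate_free_torsions(system)}
    relabeled = {
        frozenset(int(perm[a]) for a in pair) for pair in orig
    }
    got = {frozenset(t.axis_atoms) for t in enumerate_free_torsions(shuffled)}
    assert got == relabeled


def test_split_sets_ethanol_and_tie():
    eth = ethanol_like()
    (t_co,) = [t for t in enumerate_free_torsions(eth) if frozenset(t.axis_atoms) == frozenset((1, 2))]
    assert t_co.moving_set == frozenset({2, 8})
    # symmetric ethane: tie goes to the i2 side
    ethane = staggered_ethane()
    (t,) = enumerate_free_torsions(ethane)
    moving, fixed = split_torsion_sets(ethane, t.dihedral)
    assert len(moving) == len(fixed) == 4
    assert t.dihedral.i2 in moving


def test_split_sets_terminal_methyl_butane():
    system = butane_chain()
    tor = [t for t in enumerate_free_torsions(system) if frozenset(t.axis_atoms) == frozenset((0, 1))]
    (t,) = tor
    assert len(t.moving_set) == 4  # CH3 side
    assert 0 in t.moving_set


def test_split_sets_cycle_edge_rejected():
    system = benzene_ring()
    with pytest.raises(InputError):
        split_torsion_sets(system, Dihedral(6, 0, 1, 7))


# -- rotations --------------------------------------------------------------

def test_rotation_about_z_and_x():
    Rz = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 90.0)
    assert np.allclose(Rz @ [1, 0, 0], [0, 1, 0], atol=1e-12)
    Rx = rotation_about_axis(np.array([1.0, 0.0, 0.0]), 90.0)
    assert np.allclose(Rx @ [0, 1, 0], [0, 0, 1], atol=1e-12)


@given(st.integers(0, 2**32 - 1), st.floats(-360, 720))
@settings(max_examples=60, deadline=None)
def test_rotation_matches_rodrigues_and_is_proper(seed, angle):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    R = rotation_about_axis(u, angle)
    assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
    assert np.isclose(np.linalg.det(R), 1.0, atol=1e-10)
    assert np.allclose(R @ u, u, atol=1e-9)
    assert np.allclose(R, rodrigues(u, angle), atol=1e-9)


def test_rotation_full_turn_identity_and_degenerate_axis():
    for u in ([0.0, 0.0, 1.0], [0.0, 0.0, -1.0], [0.6, -0.8, 0.0]):
        assert np.allclose(rotation_about_axis(np.array(u), 360.0), np.eye(3), atol=1e-10)
    Rdown = rotation_about_axis(np.array([0.0, 0.0, -1.0]), 90.0)
    assert np.allclose(Rdown @ [1, 0, 0], [0, -1, 0], atol=1e-12)


def test_rotation_bad_axis():
    with pytest.raises(InputError):
        rotation_about_axis(np.zeros(3), 10.0)
    with pytest.raises(InputError):
        rotation_about_axis(np.array([1.0, 1.0, 0.0]), 10.0)


# -- torsion application ----------------------------------------------------

def test_apply_torsion_zero_and_roundtrip():
    system = staggered_ethane()
    (t,) = enumerate_free_torsions(system)
    assert np.allclose(apply_torsion(system, t, 0.0), system.X)
    forward = system.copy()
    forward.X = apply_torsion(forward, t, 37.0)
    forward.X = apply_torsion(forward, t, -37.0)
    assert np.allclose(forward.X, system.X, atol=1e-9)


def test_apply_torsion_changes_dihedral_by_angle():
    system = staggered_ethane()
    (t,) = enumerate_free_torsions(system)
    d = t.dihedral
    before = measure_dihedral(system.X, d.e1, d.i1, d.i2, d.e2)
    X = apply_torsion(system, t, 60.0)
    after = measure_dihedral(X, d.e1, d.i1, d.i2, d.e2)
    delta = (after - before + 180.0) % 360.0 - 180.0
    assert np.isclose(abs(delta), 60.0, atol=1e-8)


def test_apply_torsion_preserves_half_gram_matrices():
    system = butane_chain()
    for t in enumerate_free_torsions(system):
        X = apply_torsion(system, t, 73.0)
        for group in (sorted(t.moving_set), sorted(t.fixed_set)):
            G0 = system.X[group] @ system.X[group].T
            # Gram of centered coordinates is rotation+translation invariant
            A0 = system.X[group] - system.X[group].mean(axis=0)
            A1 = X[group] - X[group].mean(axis=0)
            assert np.allclose(A0 @ A0.T, A1 @ A1.T, atol=1e-9)
        # only moving rows change
        fixed = sorted(t.fixed_set)
        assert np.allclose(X[fixed], system.X[fixed])


def test_apply_torsion_preserves_bond_geometry():
    system = ethanol_like()
    for t in enumerate_free_torsions(system):
        X = apply_torsion(system, t, 49.0)
        for a, b, _ in system.topology.bonds():
            d0 = np.linalg.norm(system.X[a] - system.X[b])
            d1 = np.linalg.norm(X[a] - X[b])
            assert np.isclose(d0, d1, atol=1e-8)
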