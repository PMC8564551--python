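"""Initialization (Fibonacci lattice, docking) and crowding optimization."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import kstest

from lnbuild.assemble import (
    GOLDEN_RATIO,
    build,
    dock_ligands,
    farthest_point_order,
    fibonacci_lattice,
    init_free_shape,
    lattice_to_sphere,
    ligand_reference_point,
    min_nonbonded_distance,
    optimize_crowding,
    site_reference_point,
)
from lnbuild.complexes import Metal, assemble_complex
from lnbuild.fixtures import make_fixture
from lnbuild.molgraph import InputError
from lnbuild.shapes import assign_sites, load_shape, rescale_vertices


def _angles_between(T):
    out = []
    for i, j in itertools.combinations(range(len(T)), 2):
        c = np.dot(T[i], T[j]) / (np.linalg.norm(T[i]) * np.linalg.norm(T[j]))
        out.append(math.degrees(math.acos(max(-1.0, min(1.0, c)))))
    return sorted(out)


# -- lattice ----------------------------------------------------------------

def test_fibonacci_lattice_values():
    pts = fibonacci_lattice(30)
    assert pts.shape == (31, 2)
    assert np.allclose(pts[0], [0.0, 0.0])
    assert pts[1, 0] == pytest.approx((1.0 / GOLDEN_RATIO) % 1.0)
    assert pts[1, 0] == pytest.approx(0.6180, abs=1e-4)
    assert np.allclose(pts[:, 1], np.arange(31) / 30.0)


def test_lattice_to_sphere_landmarks_and_area_preservation():
    pts = np.array([[0.0, 0.0], [0.0, 0.5], [0.25, 0.5], [0.0, 1.0]])
    S = lattice_to_sphere(pts)
    assert np.allclose(S[0], [0, 0, 1], atol=1e-12)
    assert np.allclose(S[1], [1, 0, 0], atol=1e-12)
    assert np.allclose(S[2], [0, 1, 0], atol=1e-12)
    assert np.allclose(S[3], [0, 0, -1], atol=1e-12)
    assert np.allclose(np.linalg.norm(S, axis=1), 1.0)
    # z of a large lattice is uniform on [-1, 1]
    big = lattice_to_sphere(fibonacci_lattice(10_000))
    stat = kstest(big[:, 2], "uniform", args=(-1.0, 2.0))
    assert stat.pvalue > 0.01
    with pytest.raises(InputError):
        lattice_to_sphere(np.array([[0.0, 1.5]]))


def test_farthest_point_order_properties():
    oct_pts = np.array(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0], [0, -1, 0], [0, 0, -1]],
        dtype=float,
    )
    ordered = farthest_point_order(oct_pts)
    assert np.allclose(ordered[0], oct_pts[0])
    assert np.allclose(ordered[1], -oct_pts[0])  # antipode is farthest
    # output is a permutation of the input
    assert sorted(map(tuple, ordered)) == sorted(map(tuple, oct_pts))
    single = farthest_point_order(np.array([[0.0, 0.0, 1.0]]))
    assert np.allclose(single, [[0, 0, 1]])
    # greedy max-min property on the lattice
    lat = lattice_to_sphere(fibonacci_lattice(30))
    ordered = farthest_point_order(lat)
    for k in range(1, 6):
        chosen_min = min(
            np.linalg.norm(ordered[k] - ordered[j]) for j in range(k)
        )
        for other in map(np.asarray, ordered[k + 1 :]):
            other_min = min(np.linalg.norm(other - ordered[j]) for j in range(k))
            assert chosen_min >= other_min - 1e-12


# -- reference points -------------------------------------------------------

def test_site_reference_point_examples():
    assert np.allclose(site_reference_point(np.array([[1.0, 0, 0]])), [1.7, 0, 0])
    two = np.array([[0.5, 0.5, 1.0], [-0.5, -0.5, 1.0]])
    ref = site_reference_point(two)
    assert np.allclose(ref, [0.0, 0.0, 1.7])
    assert np.allclose(site_reference_point(two, d=3.4), [0.0, 0.0, 3.4])
    with pytest.raises(InputError):
        site_reference_point(np.zeros((0, 3)))


def test_ligand_reference_points():
    water = make_fixture("water")
    ref, fallback = ligand_reference_point(water)
    assert not fallback
    assert np.allclose(ref, water.system.X[[1, 2]].mean(axis=0))
    bipy = make_fixture("bipyridine")
    ref_b, fb = ligand_reference_point(bipy)
    assert not fb
    nbrs = sorted(
        {b for t in bipy.teeth for b in bipy.system.topology.adjacency(t)}
        - set(bipy.teeth)
    )
    assert np.allclose(ref_b, bipy.system.X[nbrs].mean(axis=0))
    chloride = make_fixture("chloride")
    _, fb2 = ligand_reference_point(chloride)
    assert fb2


# -- free-shape initialization ----------------------------------------------

def test_init_two_ligands_near_antipodal(bond_table):
    cx = assemble_complex(Metal("Eu", 3), [make_fixture("water")] * 2)
    init_free_shape(cx, bond_table)
    (ang,) = _angles_between(cx.X[cx.teeth_global])
    assert ang > 150.0


def test_init_single_ligand_tooth_near_target(bond_table):
    cx = assemble_complex(Metal("Eu", 3), [make_fixture("water")])
    init_free_shape(cx, bond_table)
    tooth_r = np.linalg.norm(cx.X[cx.teeth_global[0]])
    assert tooth_r == pytest.approx(2.51, abs=0.35)
    # teeth point toward the metal: tooth radius below barycenter radius
    bary_r = np.linalg.norm(cx.X[cx.ligand_rows(0)].mean(axis=0))
    assert tooth_r < bary_r + 1e-9


def test_init_six_ligands_roughly_octahedral(bond_table):
    cx = assemble_complex(Metal("Eu", 3), [make_fixture("water")] * 6)
    init_free_shape(cx, bond_table)
    angles = _angles_between(cx.X[cx.teeth_global])
    # twelve near-90 cis angles within 25 deg on the initialized structure
    assert sum(1 for a in angles if abs(a - 90.0) < 25.0) >= 10


def test_init_too_many_ligands_errors(bond_table):
    cx = assemble_complex(Metal("Eu", 3), [make_fixture("water")] * 8)
    with pytest.raises(InputError):
        init_free_shape(cx, bond_table, N=5)


# -- docking ----------------------------------------------------------------

def _docked_water_octahedron(bond_table):
    cx = assemble_complex(Metal("Eu", 3), [make_fixture("water")] * 6)
    shape = load_shape("OC-6")
    assignment = rescale_vertices(assign_sites(shape, cx), cx, bond_table)
    rmsds = dock_ligands(cx, assignment)
    return cx, assignment, rmsds


def test_dock_monodentate_teeth_on_vertices(bond_table):
    cx, assignment, rmsds = _docked_water_octahedron(bond_table)
    teeth = cx.X[cx.teeth_global]
    assert np.abs(teeth - assignment.shape.Z).max() < 1e-6
    # ligand bulk radially outside the tooth
    for m in range(6):
        bary_r = np.linalg.norm(cx.X[cx.ligand_rows(m)].mean(axis=0))
        tooth_r = np.linalg.norm(cx.X[cx.teeth_global[m]])
        assert bary_r > tooth_r


def test_dock_bidentate_teeth_near_vertices(bond_table):
    ligs = [make_fixture("water")] * 3 + [make_fixture("nitrate")] * 3
    cx = assemble_complex(Metal("Lu", 3), ligs)
    shape = load_shape("MFF-9")
    assignment = rescale_vertices(assign_sites(shape, cx), cx, bond_table)
    rmsds = dock_ligands(cx, assignment)
    teeth = cx.X[cx.teeth_global]
    # teeth within the superposition residual of their vertices
    for k in range(9):
        d = np.linalg.norm(teeth[k] - assignment.shape.Z[k])
        assert d < 0.8  # bite-length mismatch bound, nitrate on muffin edges
    # no ligand bulk over the metal
    for m, lig in enumerate(cx.ligands):
        bary = cx.X[cx.ligand_rows(m)].mean(axis=0)
        teeth_c = cx.X[[cx.global_index(m, t) for t in lig.teeth]].mean(axis=0)
        assert np.linalg.norm(bary) > 0.8 * np.linalg.norm(teeth_c)


# -- optimization -----------------------------------------------------------

def test_optimization_monotone_and_clash_free(bond_table):
    result = build(
        Metal("Eu", 3), [make_fixture("water")] * 6, shape="OC-6",
        seed=0, chirality_iterations=200,
    )
    traj = result.crowding_trajectory
    assert all(a >= b - 1e-9 for a, b in zip(traj, traj[1:]))
    assert result.final_crowding.W < 0.05
    assert min_nonbonded_distance(result.complex) > 1.5
    assert result.stereoisomer.permutation == tuple(range(6))


def test_antipodal_two_ligand_complex_reaches_scalar_optimum(bond_table):
    """Two antipodal chlorides: the symmetric radial profile
    Xi(r) = 4 (2/r + 1/(2r)) + 2 alpha (r - r0)^2 has a closed scalar
    optimum; the full optimizer must land on it and keep the antipodal
    arrangement."""
    from scipy.optimize import minimize_scalar

    r0 = 2.6
    alpha = 100.0 * 3 / np.sqrt(2.0)
    profile = lambda r: 4.0 * (2.0 / r + 1.0 / (2.0 * r)) + 2.0 * alpha * (r - r0) ** 2
    r_star = minimize_scalar(profile, bracket=(2.0, 2.6, 3.2)).x

    cx = assemble_complex(Metal("Eu", 3), [make_fixture("chloride")] * 2)
    cx.X[1] = [r0, 0.0, 0.0]
    cx.X[2] = [-r0, 0.0, 0.0]
    outcome = optimize_crowding(cx, "free", np.array([r0, r0]), max_iter=30)
    assert outcome.converged
    radii = np.linalg.norm(cx.X[1:], axis=1)
    assert np.allclose(radii, r_star, atol=1e-3)
    cosang = np.dot(cx.X[1], cx.X[2]) / (radii[0] * radii[1])
    assert cosang == pytest.approx(-1.0, abs=1e-6)
    assert outcome.final.Xi == pytest.approx(profile(r_star), abs=1e-3)


@pytest.mark.parametrize(
    "n,ideal",
    [(2, [180.0]), (3, [120.0] * 3), (4, [109.47] * 6)],
    ids=["linear", "trigonal", "tetrahedral"],
)
def test_free_shape_recovers_ideal_arrangements(n, ideal, bond_table):
    result = build(
        Metal("Eu", 3), [make_fixture("water")] * n,
        seed=0, chirality_iterations=100, max_iter=300,
    )
    angles = _angles_between(result.complex.X[result.complex.teeth_global])
    for got, want in zip(angles, sorted(ideal)):
        assert abs(got - want) < 10.0
    assert result.stereoisomer is None


def test_fixed_shape_build_preserves_stereoisomer(bond_table):
    from lnbuild.shapes import enumerate_stereoisomers

    ligs = [make_fixture("water")] * 3 + [make_fixture("nitrate")] * 3
    mff = load_shape("MFF-9")
    ids = enumerate_stereoisomers(mff, "Ma3(AA)3")
    for pick in (3, 100):
        result = build(
            Metal("Lu", 3), [l.copy() for l in ligs], shape="MFF-9",
            stereoisomer=ids[pick], seed=1, chirality_iterations=200,
        )
        assert result.stereoisomer.permutation == ids[pick].permutation
        assert min_nonbonded_distance(result.complex) > 1.2


def test_build_deterministic_for_a_seed(bond_table):
    kwargs = dict(shape="OC-6", seed=7, chirality_iterations=300)
    r1 = build(Metal("Eu", 3), [make_fixture("water")] * 6, **kwargs)
    r2 = build(Metal("Eu", 3), [make_fixture("water")] * 6, **kwargs)
    assert np.array_equal(r1.complex.X, r2.complex.X)
    assert r1.report() == r2.report()


def test_free_shape_build_dispatch(bond_table):
    result = build(
        Metal("Eu", 3), [make_fixture("water")] * 6,
        seed=0, chirality_iterations=100, max_iter=60,
    )
    assert result.stereoisomer is None
    assert result.final_crowding.W < 0.5  # radial tether respected
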