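"""Geometry initialization and crowding minimization: the build pipeline.

Free-shape complexes are initialized by spreading ligands on a spherical
Fibonacci lattice, greedily reordered so each point maximizes its distance to
all predecessors; the first |L| points seed the ligand barycenters, teeth
oriented toward the metal.

Fixed-shape complexes are initialized by docking: every ligand's effective
teeth set (teeth + a reference point behind the teeth) is superposed onto its
site's effective vertex set (vertices + the site centroid pushed radially
outward), so teeth land on vertices with the ligand bulk radially away from
the metal.

The crowding objective is then minimized with a trust-region method over the
active degrees of freedom (fixed shape: free torsions + wheel/hinge angles;
free shape: free torsions + Euler angles + coordination-space positions),
with numerical gradients and a 1e-4 A^-1 objective-decrease threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .bondtables import BondTargetTable
from .chirality import ChiralityVerdict, is_chiral, kearsley_superpose
from .complexes import Complex, Ligand, Metal, assemble_complex
from .dof import (
    CrowdingResult,
    _euler_zyz,
    crowding,
    set_position,
)
from .geometry import rotation_aligning
from .molgraph import InputError, enumerate_free_torsions, rotation_about_axis
from .shapes import (
    Shape,
    SiteAssignment,
    StereoisomerID,
    assign_sites,
    canonical_stereoisomer,
    identify_placement,
    load_shape,
    rescale_vertices,
)

__all__ = [
    "fibonacci_lattice",
    "lattice_to_sphere",
    "lattice_to_circle",
    "farthest_point_order",
    "site_reference_point",
    "ligand_reference_point",
    "init_free_shape",
    "dock_ligands",
    "optimize_crowding",
    "relax_ligand_directions",
    "build",
    "BuildResult",
    "min_nonbonded_distance",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0
SITE_REFERENCE_SCALE = 1.7
CONVERGENCE_TOL = 1e-4  # A^-1, objective decrease
DEFAULT_LATTICE_N = 30


# -- point sets on the sphere ----------------------------------------------

def fibonacci_lattice(N: int) -> np.ndarray:
    """(N+1) x 2 unit-square lattice: x = frac(n/GoldenRatio), y = n/N."""
    if N < 1:
        raise InputError("need N >= 1 lattice points")
    n = np.arange(N + 1, dtype=float)
    return np.column_stack([(n / GOLDEN_RATIO) % 1.0, n / N])


def lattice_to_circle(points: np.ndarray) -> np.ndarray:
    """Area-preserving unit-square -> unit-disk map: (2 pi x, sqrt(y)) polar."""
    pts = np.asarray(points, dtype=float)
    theta = 2.0 * np.pi * pts[:, 0]
    r = np.sqrt(pts[:, 1])
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def lattice_to_sphere(points: np.ndarray) -> np.ndarray:
    """Area-preserving unit-square -> unit-sphere map.

    Azimuth 2 pi x, inclination arccos(1 - 2y); uniform y gives uniform
    cos(inclination), i.e. uniform area density.
    """
    pts = np.asarray(points, dtype=float)
    if np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > 1):
        raise InputError("lattice y values must lie in [0, 1]")
    az = 2.0 * np.pi * pts[:, 0]
    inc = np.arccos(1.0 - 2.0 * pts[:, 1])
    return np.column_stack(
        [np.sin(inc) * np.cos(az), np.sin(inc) * np.sin(az), np.cos(inc)]
    )


def farthest_point_order(points: np.ndarray) -> np.ndarray:
    """Greedy reorder: each point maximizes its minimum distance to all
    predecessors; ties break toward the lower original index."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        raise InputError("empty point set")
    order = [0]
    remaining = list(range(1, n))
    dmin = np.full(n, np.inf)
    while remaining:
        d = np.linalg.norm(pts[remaining] - pts[order[-1]], axis=1)
        dmin[remaining] = np.minimum(dmin[remaining], d)
        best = max(remaining, key=lambda i: (dmin[i], -i))
        order.append(best)
        remaining.remove(best)
    return pts[order]


# -- reference points -------------------------------------------------------

def site_reference_point(site_vertices: np.ndarray, d: float = SITE_REFERENCE_SCALE) -> np.ndarray:
    """Site centroid scaled radially outward by the free parameter d."""
    V = np.atleast_2d(np.asarray(site_vertices, dtype=float))
    if len(V) == 0:
        raise InputError("empty site")
    return d * V.mean(axis=0)


def ligand_reference_point(lig: Ligand, X: np.ndarray | None = None) -> tuple[np.ndarray, bool]:
    """Centroid of the atoms bonded to the teeth (teeth themselves excluded).

    Returns ``(point, fallback)``; for a bare monoatomic ligand there are no
    qualifying neighbors and the tooth position itself is returned with
    ``fallback=True`` (callers then orient the ligand arbitrarily, which is
    harmless for a spherical ion).
    """
    if X is None:
        X = lig.system.X
    teeth = set(lig.teeth)
    nbrs = sorted(
        {b for t in lig.teeth for b in lig.system.topology.adjacency(t)} - teeth
    )
    if not nbrs:
        return X[lig.teeth[0]].copy(), True
    return X[nbrs].mean(axis=0), False


# -- initialization ---------------------------------------------------------

def init_free_shape(
    cx: Complex,
    table: BondTargetTable,
    N: int = DEFAULT_LATTICE_N,
) -> None:
    """Place ligands on the ordered Fibonacci lattice, teeth toward metal.

    Each ligand's barycenter goes to a lattice direction at radius
    (mean tooth r0) + |barycenter - teeth centroid|, so the teeth start near
    their target bond lengths.
    """
    n_lig = len(cx.ligands)
    if n_lig > N:
        raise InputError(
            f"{n_lig} ligands exceed the {N}-point lattice; pass a larger N"
        )
    directions = farthest_point_order(lattice_to_sphere(fibonacci_lattice(N)))
    metal = cx.metal
    for m, lig in enumerate(cx.ligands):
        rows = cx.ligand_rows(m)
        Xl = cx.X[rows]
        bary = Xl.mean(axis=0)
        teeth_local = [cx.global_index(m, t) for t in lig.teeth]
        tc = cx.X[teeth_local].mean(axis=0)
        r0s = [
            table.target_length_angstrom(
                metal.element, metal.oxidation_state,
                cx.system.atoms[t].element,
            )
            for t in teeth_local
        ]
        radius = float(np.mean(r0s)) + float(np.linalg.norm(bary - tc))
        p = directions[m]
        # orient teeth toward the metal: teeth-centroid direction -> -p
        v = tc - bary
        if np.linalg.norm(v) > 1e-9:
            R = rotation_aligning(v / np.linalg.norm(v), -p)
            Xl = (Xl - bary) @ R.T + bary
        cx.X[rows] = Xl + (radius * p - bary)


def dock_ligands(cx: Complex, assignment: SiteAssignment) -> list[float]:
    """Superpose each ligand's effective teeth onto its effective site.

    The Kearsley fit of (teeth + ligand reference point) onto (site vertices
    + site reference point) is applied rigidly to the whole ligand; teeth
    land on their vertices with the ligand bulk radially outward.  Returns
    the per-ligand superposition RMSD.
    """
    Z = assignment.shape.Z
    rmsds = []
    for m, lig in enumerate(cx.ligands):
        block = assignment.shape.sites[m]
        site = Z[list(block)]
        p_site = site_reference_point(site)
        rows = cx.ligand_rows(m)
        teeth_global = [cx.global_index(m, t) for t in lig.teeth]
        teeth_xyz = cx.X[teeth_global]
        p_lig, fallback = ligand_reference_point(lig, cx.X[rows])
        if fallback:
            # single-atom ligand: fabricate a second point behind the tooth
            p_lig = teeth_xyz[0] + np.array([1.0, 0.0, 0.0])
        P = np.vstack([site, p_site])
        Q = np.vstack([teeth_xyz, p_lig])
        try:
            R, _, rmsd = kearsley_superpose(P, Q)
        except np.linalg.LinAlgError:
            jitter = np.random.default_rng(0).normal(scale=1e-6, size=Q.shape)
            R, _, rmsd = kearsley_superpose(P, Q + jitter)
        # rotation from the effective sets (reference points fix the outward
        # orientation); translation from the teeth alone, so teeth centroids
        # coincide with site centroids exactly
        t = site.mean(axis=0) - R @ teeth_xyz.mean(axis=0)
        cx.X[rows] = cx.X[rows] @ R.T + t
        rmsds.append(float(rmsd))
    return rmsds


def relax_ligand_directions(cx: Complex, reference: np.ndarray, max_iter: int = 200) -> None:
    """Rigid-ligand angular pre-relaxation for free-shape initialization.

    Each ligand is treated as a rigid body riding on its coordination-ray
    direction: only the (inclination, azimuth) of the barycenter vary, at
    fixed radius, with the whole ligand co-rotating.  Minimizing crowding in
    this tiny subspace first steers the ligand *directions* into the basin a
    purely repulsive objective favors (linear / trigonal / tetrahedral ...)
    before the full-dimensional refinement, which otherwise can stall in the
    shallow saddle-like arrangements the lattice seed starts near.
    """
    n_lig = len(cx.ligands)
    base = cx.X.copy()
    barys = [base[cx.ligand_rows(m)].mean(axis=0) for m in range(n_lig)]
    radii = [float(np.linalg.norm(b)) for b in barys]
    x0 = []
    for b, r in zip(barys, radii):
        x0 += [math.acos(max(-1.0, min(1.0, b[2] / r))), math.atan2(b[1], b[0])]

    def apply(x: np.ndarray) -> None:
        cx.X = base.copy()
        for m in range(n_lig):
            th, ph = x[2 * m], x[2 * m + 1]
            p = np.array(
                [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
            )
            b0 = barys[m]
            R = rotation_aligning(b0 / np.linalg.norm(b0), p)
            rows = cx.ligand_rows(m)
            cx.X[rows] = (base[rows] - b0) @ R.T + radii[m] * p

    def f(x: np.ndarray) -> float:
        apply(x)
        return crowding(cx, reference, "free").Xi

    res = minimize(
        f, np.array(x0), method="trust-constr", jac="3-point",
        options={"maxiter": max_iter, "gtol": 1e-10},
    )
    apply(res.x if res.fun <= f(np.array(x0)) else np.array(x0))


# -- degrees of freedom vector ---------------------------------------------

@dataclass
class _LigandDofs:
    torsions: list  # FreeTorsion in ligand-local serials
    single_angle: str | None  # "wheel" | "hinge" | None
    n_external: int  # 1 (wheel/hinge), 6 (euler+space) or 0


class DofVector:
    """Flat parameter vector over the active degrees of freedom.

    Fixed-shape mode: per ligand, free-torsion angles plus one wheel (mono)
    or hinge (bidentate) angle.  Free-shape mode: free-torsion angles, three
    barycenter-centered Euler angles and the spherical coordination-space
    position of the barycenter.  Angles in degrees, lengths in Angstrom.
    """

    def __init__(self, cx: Complex, mode: str):
        if mode not in ("fixed", "free"):
            raise InputError(f"unknown mode {mode!r}")
        self.mode = mode
        self.base_X = cx.X.copy()
        self.specs: list[_LigandDofs] = []
        for lig in cx.ligands:
            torsions = enumerate_free_torsions(lig.system)
            if mode == "fixed":
                single = (
                    "wheel" if lig.denticity == 1
                    else "hinge" if lig.denticity == 2
                    else None
                )
                self.specs.append(
                    _LigandDofs(torsions, single, 1 if single else 0)
                )
            else:
                self.specs.append(_LigandDofs(torsions, None, 6))
        self.size = sum(len(s.torsions) + s.n_external for s in self.specs)

    def initial(self, cx: Complex) -> np.ndarray:
        x0 = np.zeros(self.size)
        if self.mode == "free":
            k = 0
            for m, spec in enumerate(self.specs):
                k += len(spec.torsions) + 3  # torsions + euler at 0
                bary = self.base_X[cx.ligand_rows(m)].mean(axis=0)
                r = np.linalg.norm(bary)
                theta = math.acos(max(-1.0, min(1.0, bary[2] / r))) if r > 0 else 0.0
                phi = math.atan2(bary[1], bary[0])
                x0[k : k + 3] = (r, theta, phi)
                k += 3
        return x0

    def apply(self, cx: Complex, x: np.ndarray) -> None:
        """Rebuild the geometry from the base structure and the vector."""
        cx.X = self.base_X.copy()
        k = 0
        for m, (lig, spec) in enumerate(zip(cx.ligands, self.specs)):
            rows = cx.ligand_rows(m)
            off = cx.ligand_offset(m)
            for tor in spec.torsions:
                angle = x[k]
                k += 1
                if angle == 0.0:
                    continue
                i1, i2 = (off + a for a in tor.axis_atoms)
                axis = cx.X[i1] - cx.X[i2]
                R = rotation_about_axis(axis / np.linalg.norm(axis), angle)
                idx = [off + a for a in sorted(tor.moving_set)]
                origin = cx.X[i1].copy()
                cx.X[idx] = (cx.X[idx] - origin) @ R.T + origin
            if self.mode == "fixed":
                if spec.single_angle == "wheel":
                    from .dof import wheel_rotate

                    wheel_rotate(cx, m, x[k])
                    k += 1
                elif spec.single_angle == "hinge":
                    from .dof import hinge_rotate

                    hinge_rotate(cx, m, x[k])
                    k += 1
            else:
                bary = cx.X[rows].mean(axis=0)
                R = _euler_zyz(x[k], x[k + 1], x[k + 2])
                cx.X[rows] = (cx.X[rows] - bary) @ R.T + bary
                k += 3
                set_position(cx, m, space=tuple(x[k : k + 3]))
                k += 3


# -- optimization -----------------------------------------------------------

@dataclass
class OptimizationOutcome:
    trajectory: list[float]
    converged: bool
    n_iterations: int
    final: CrowdingResult


def optimize_crowding(
    cx: Complex,
    mode: str,
    reference: np.ndarray,
    max_iter: int = 200,
    tol: float = CONVERGENCE_TOL,
) -> OptimizationOutcome:
    """Trust-region minimization of crowding over the active DOF vector.

    The geometry of ``cx`` is updated in place to the optimum.  Iteration
    stops when the objective decrease falls below ``tol`` (A^-1) or after
    ``max_iter`` trust-region iterations.
    """
    dofs = DofVector(cx, mode)
    x0 = dofs.initial(cx)

    def objective(x: np.ndarray) -> float:
        dofs.apply(cx, x)
        return crowding(cx, reference, mode).Xi

    trajectory = [objective(x0)]
    converged = False
    stall = 0

    def callback(xk, state) -> bool:
        nonlocal converged, stall
        prev = trajectory[-1]
        trajectory.append(float(state.fun))
        # trust-region radius adaptation can make little progress on early
        # iterations; declare convergence only on sustained sub-tol decrease
        if prev - state.fun < tol:
            stall += 1
        else:
            stall = 0
        if stall >= 3 and state.nit >= 5:
            converged = True
            return True
        return False

    if dofs.size == 0:
        final = crowding(cx, reference, mode)
        return OptimizationOutcome(trajectory, True, 0, final)

    res = minimize(
        objective,
        x0,
        method="trust-constr",
        jac="3-point",
        callback=callback,
        options={"maxiter": max_iter, "gtol": 1e-10, "xtol": 1e-12},
    )
    best = res.x if res.fun <= trajectory[-1] else x0
    dofs.apply(cx, best)
    final = crowding(cx, reference, mode)
    return OptimizationOutcome(trajectory, converged or res.success, res.nit, final)


# -- end-to-end build -------------------------------------------------------

@dataclass
class BuildResult:
    complex: Complex
    crowding_trajectory: list[float]
    final_crowding: CrowdingResult
    stereoisomer: StereoisomerID | None
    chirality: ChiralityVerdict
    converged: bool
    seed: int
    dock_rmsds: list[float] = field(default_factory=list)

    def report(self) -> dict:
        """Machine-readable build report."""
        sid = self.stereoisomer
        return {
            "seed": self.seed,
            "converged": self.converged,
            "crowding": {
                "S": self.final_crowding.S,
                "S_HH": self.final_crowding.S_HH,
                "S_HJ": self.final_crowding.S_HJ,
                "S_JJ": self.final_crowding.S_JJ,
                "W": self.final_crowding.W,
                "alpha": self.final_crowding.alpha,
                "Xi": self.final_crowding.Xi,
            },
            "crowding_trajectory": self.crowding_trajectory,
            "stereoisomer": sid.text() if sid else None,
            "shape": sid.shape_label if sid else None,
            "chiral": self.chirality.chiral,
            "chirality_min_rmsd": self.chirality.min_rmsd,
            "dock_rmsds": self.dock_rmsds,
        }


def min_interatomic_distance(cx: Complex) -> float:
    from scipy.spatial.distance import pdist

    return float(pdist(cx.X).min())


def min_nonbonded_distance(cx: Complex) -> float:
    """Smallest distance between atoms that are not bonded to each other
    (coordinate bonds included as bonds); the clash-floor measure."""
    from scipy.spatial.distance import squareform, pdist

    D = squareform(pdist(cx.X))
    n = len(D)
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)
    for a, b, _ in cx.system.topology.bonds():
        mask[a, b] = mask[b, a] = False
    return float(D[mask].min())


def build(
    metal: Metal,
    ligands: list[Ligand],
    shape: Shape | str | None = None,
    stereoisomer: StereoisomerID | tuple[int, ...] | str | None = None,
    *,
    table: BondTargetTable | None = None,
    seed: int = 0,
    max_iter: int = 200,
    chirality_iterations: int = 10_000,
    optimize: bool = True,
) -> BuildResult:
    """Full pipeline: assemble, place, optimize, classify.

    With a shape (and optionally a stereoisomer permutation) the complex is
    built in fixed-shape mode: sites assigned, vertices rescaled to target
    bond lengths, ligands docked, crowding minimized over torsions and
    wheel/hinge angles, and the output's stereoisomer re-identified and
    checked against the request.  Without a shape, ligands are spread on the
    Fibonacci lattice and crowding is minimized over torsions, Euler angles
    and coordination-space positions with the radial warp.  Deterministic for
    a given seed.
    """
    if table is None:
        table = BondTargetTable.default()
    cx = assemble_complex(metal, ligands)
    formula = cx.generic_formula()

    sid: StereoisomerID | None = None
    dock_rmsds: list[float] = []
    if shape is not None:
        ref_shape = load_shape(shape) if isinstance(shape, str) else shape
        assignment = assign_sites(ref_shape, cx, stereoisomer)
        assignment = rescale_vertices(assignment, cx, table)
        sid = assignment.stereoisomer
        dock_rmsds = dock_ligands(cx, assignment)
        reference = assignment.shape.Z
        mode = "fixed"
    else:
        init_free_shape(cx, table)
        reference = np.array(
            [
                table.target_length_angstrom(
                    metal.element, metal.oxidation_state,
                    cx.system.atoms[t].element,
                )
                for t in cx.teeth_global
            ]
        )
        if optimize:
            relax_ligand_directions(cx, reference)
        mode = "free"
        ref_shape = None

    if optimize:
        outcome = optimize_crowding(cx, mode, reference, max_iter=max_iter)
    else:
        final = crowding(cx, reference, mode)
        outcome = OptimizationOutcome([final.Xi], True, 0, final)

    if mode == "fixed" and sid is not None:
        observed = identify_placement(ref_shape, formula, cx.X[cx.teeth_global])
        requested = canonical_stereoisomer(ref_shape, formula, sid.permutation)
        if observed.permutation != requested.permutation:
            raise RuntimeError(
                "stereoisomer drift during optimization: requested "
                f"{requested.text()}, output identifies as {observed.text()}"
            )

    verdict = is_chiral(
        cx.X[cx.teeth_global],
        cx.tooth_colors,
        iterations=chirality_iterations,
        seed=seed,
    )
    return BuildResult(
        cx,
        outcome.trajectory,
        outcome.final,
        sid,
        verdict,
        outcome.converged,
        seed,
        dock_rmsds,
    )
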