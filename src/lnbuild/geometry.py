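"""Shared geometric utilities: convex-hull edges, discrete isometry detection,
vector alignment and uniform random rotations.

These are generic point-set operations used by the shape library, the docking
stage and the chirality test.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "hull_edges",
    "find_vertex_isometries",
    "rotation_aligning",
    "random_rotation",
    "kabsch_orthogonal",
]


def hull_edges(points: np.ndarray, tol: float = 1e-6) -> list[tuple[int, int]]:
    """Edges of the convex hull of a 3D point set.

    Qhull triangulates planar faces; a simplex edge is a true polyhedron edge
    only if its two adjacent facets are non-coplanar, so triangulation
    diagonals of planar (e.g. square) faces are dropped.
    """
    points = np.asarray(points, dtype=float)
    hull = ConvexHull(points)
    edge_normals: dict[tuple[int, int], list[np.ndarray]] = defaultdict(list)
    for simplex, eq in zip(hull.simplices, hull.equations):
        for i, j in itertools.combinations(sorted(int(v) for v in simplex), 2):
            edge_normals[(i, j)].append(eq[:3])
    edges = []
    for edge, normals in edge_normals.items():
        for a, b in itertools.combinations(normals, 2):
            if np.linalg.norm(np.cross(a, b)) > tol:
                edges.append(edge)
                break
    return sorted(edges)


def kabsch_orthogonal(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best proper and improper orthogonal matrices M minimizing |Q @ M.T - P|.

    Returns (proper, improper); both are exact orthogonal matrices from the
    SVD of the covariance, with det +1 and -1 respectively.
    """
    H = Q.T @ P
    U, _, Vt = np.linalg.svd(H)
    M = Vt.T @ U.T
    flip = np.diag([1.0, 1.0, -1.0])
    if np.linalg.det(M) > 0:
        proper = M
        improper = Vt.T @ flip @ U.T
    else:
        proper = Vt.T @ flip @ U.T
        improper = M
    return proper, improper


def find_vertex_isometries(
    points: np.ndarray,
    kind: str = "proper",
    tol: float = 1e-5,
) -> list[tuple[int, ...]]:
    """All vertex permutations of a point set realizable by an orthogonal map.

    ``kind`` selects proper rotations (``"proper"``), reflections/rotoreflections
    (``"improper"``) or both (``"all"``).  Candidate permutations are grown by
    backtracking on pairwise-distance compatibility (plus distance to the
    origin), then verified by fitting an exact orthogonal matrix.
    """
    V = np.asarray(points, dtype=float)
    n = len(V)
    D = np.linalg.norm(V[:, None] - V[None, :], axis=2)
    R = np.linalg.norm(V, axis=1)

    candidates: list[tuple[int, ...]] = []

    def backtrack(mapping: list[int]) -> None:
        k = len(mapping)
        if k == n:
            candidates.append(tuple(mapping))
            return
        for cand in range(n):
            if cand in mapping:
                continue
            if abs(R[k] - R[cand]) > tol:
                continue
            if all(abs(D[k, i] - D[cand, mapping[i]]) < tol for i in range(k)):
                backtrack(mapping + [cand])

    backtrack([])

    accepted = []
    want_proper = kind in ("proper", "all")
    want_improper = kind in ("improper", "all")
    for perm in candidates:
        P = V[list(perm)]
        proper, improper = kabsch_orthogonal(P, V)
        if want_proper and np.abs(V @ proper.T - P).max() < tol:
            accepted.append(perm)
            continue
        if want_improper and np.abs(V @ improper.T - P).max() < tol:
            accepted.append(perm)
    return sorted(set(accepted))


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector ``a`` onto unit vector ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix sampled uniformly from SO(3) via a unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
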