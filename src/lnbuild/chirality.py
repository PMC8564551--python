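"""Coordination chirality by stochastic mirror-image pairing.

Only the coordination polyhedron is examined: the teeth positions (metal at
the origin) plus a *precedence* integer per tooth encoding its chemical
identity, in the spirit of CIP priorities.  The polyhedron is mirrored,
randomly reoriented, optimally paired with the original under a
precedence-respecting assignment (Hungarian method on a distance cost with a
1e10 penalty factor for mismatched precedences), and superposed with the
quaternion least-RMSD method.  If the RMSD ever drops below the threshold the
arrangement is superimposable on its mirror image (achiral); if it survives
every iteration it is declared chiral.

Radii are normalized to the unit sphere by default so the threshold is
meaningful across bond-length scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .geometry import random_rotation

__all__ = [
    "ChiralityVerdict",
    "kearsley_superpose",
    "pairing_cost_matrix",
    "assign_pairs",
    "is_chiral",
]

MISMATCH_FACTOR = 1e10
DEFAULT_THRESHOLD = 0.14  # Angstrom on the (normalized) polyhedron
DEFAULT_ITERATIONS = 10_000


@dataclass(frozen=True)
class ChiralityVerdict:
    chiral: bool
    min_rmsd: float
    iterations_run: int
    seed: int | None
    threshold: float = DEFAULT_THRESHOLD


def kearsley_superpose(
    P: np.ndarray, Q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-RMSD proper rotation superposing ``Q`` onto ``P``.

    Solves the quaternion eigenproblem on the centered coordinates; the
    smallest eigenvalue gives the residual directly.  Returns
    ``(R, t, rmsd)`` with the fitted map x -> R x + t.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching n x 3 arrays")
    n = len(P)
    if n < 1:
        raise ValueError("need at least one point")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    # differences and sums of the centered sets
    m = (Q - qc) - (P - pc)
    s = (Q - qc) + (P - pc)
    xm, ym, zm = m.T
    xs, ys, zs = s.T
    K = np.empty((4, 4))
    K[0, 0] = np.sum(xm * xm + ym * ym + zm * zm)
    K[1, 1] = np.sum(xm * xm + ys * ys + zs * zs)
    K[2, 2] = np.sum(xs * xs + ym * ym + zs * zs)
    K[3, 3] = np.sum(xs * xs + ys * ys + zm * zm)
    K[0, 1] = K[1, 0] = np.sum(ys * zm - ym * zs)
    K[0, 2] = K[2, 0] = np.sum(xm * zs - xs * zm)
    K[0, 3] = K[3, 0] = np.sum(xs * ym - xm * ys)
    K[1, 2] = K[2, 1] = np.sum(xm * ym - xs * ys)
    K[1, 3] = K[3, 1] = np.sum(xm * zm - xs * zs)
    K[2, 3] = K[3, 2] = np.sum(ym * zm - ys * zs)
    w, v = np.linalg.eigh(K)
    lam = max(float(w[0]), 0.0)
    q = v[:, 0]
    q1, q2, q3, q4 = q
    R = np.array(
        [
            [
                q1 * q1 + q2 * q2 - q3 * q3 - q4 * q4,
                2 * (q2 * q3 + q1 * q4),
                2 * (q2 * q4 - q1 * q3),
            ],
            [
                2 * (q2 * q3 - q1 * q4),
                q1 * q1 + q3 * q3 - q2 * q2 - q4 * q4,
                2 * (q3 * q4 + q1 * q2),
            ],
            [
                2 * (q2 * q4 + q1 * q3),
                2 * (q3 * q4 - q1 * q2),
                q1 * q1 + q4 * q4 - q2 * q2 - q3 * q3,
            ],
        ]
    )
    R = R.T  # the quaternion matrix above maps P->Q; we report Q->P
    rmsd = float(np.sqrt(lam / n))
    t = pc - R @ qc
    return R, t, rmsd


def pairing_cost_matrix(
    P: np.ndarray,
    Q: np.ndarray,
    prec_P: np.ndarray,
    prec_Q: np.ndarray,
) -> np.ndarray:
    """Pairing costs: the separation distance, times 1e10 on precedence
    mismatch so mismatched teeth are never paired when avoidable."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    D = cdist(P, Q)
    mism = np.not_equal.outer(np.asarray(prec_P), np.asarray(prec_Q))
    return np.where(mism, MISMATCH_FACTOR * D, D)


def assign_pairs(cost: np.ndarray) -> np.ndarray:
    """Minimum-total-cost bijection (Hungarian / linear sum assignment).

    Returns ``pairing`` with column ``pairing[i]`` assigned to row ``i``.
    """
    rows, cols = linear_sum_assignment(np.asarray(cost, dtype=float))
    out = np.empty(len(rows), dtype=int)
    out[rows] = cols
    return out


def is_chiral(
    points: np.ndarray,
    precedence,
    iterations: int = DEFAULT_ITERATIONS,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int | None = 0,
    normalize: bool = True,
) -> ChiralityVerdict:
    """Decide coordination chirality of a precedence-labeled polyhedron.

    ``points`` are tooth positions with the metal at the origin.  Each
    iteration mirrors the polyhedron (x -> -x), applies a uniformly random
    rotation, pairs mirrored and original teeth by the precedence-aware
    assignment and measures the Kearsley RMSD under that pairing; the
    arrangement is achiral as soon as the RMSD falls below ``threshold``,
    and chiral if it never does.
    """
    P = np.asarray(points, dtype=float)
    prec = np.asarray(precedence)
    if len(P) != len(prec):
        raise ValueError("one precedence per point required")
    if len(P) < 1:
        raise ValueError("need at least one point")
    if normalize:
        radii = np.linalg.norm(P, axis=1)
        if np.any(radii < 1e-9):
            raise ValueError("tooth at the metal position")
        P = P / radii[:, None]
    if len(P) <= 2:
        # one or two teeth are always coplanar with the metal: achiral
        return ChiralityVerdict(False, 0.0, 0, seed, threshold)
    mirror = P * np.array([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    min_rmsd = np.inf
    for it in range(1, iterations + 1):
        Q = mirror @ random_rotation(rng).T
        cost = pairing_cost_matrix(P, Q, prec, prec)
        pairing = assign_pairs(cost)
        *_, rmsd = kearsley_superpose(P, Q[pairing])
        if rmsd < min_rmsd:
            min_rmsd = rmsd
        if rmsd < threshold:
            return ChiralityVerdict(False, float(min_rmsd), it, seed, threshold)
    return ChiralityVerdict(True, float(min_rmsd), iterations, seed, threshold)
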