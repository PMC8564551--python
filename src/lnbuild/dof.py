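"""Ligand degrees of freedom and the crowding objective.

External degrees of freedom move a whole ligand: Euler rotations about its
barycenter, the wheel angle (monodentate: spin about the metal-tooth axis),
the hinge angle (bidentate: swing about the tooth-tooth axis, like an open
notebook), and positional moves along the coordination ray or in coordination
space (spherical coordinates of the barycenter).  Ray and space positions are
mutually exclusive modes.  Internal degrees of freedom (free torsions) live
in :mod:`lnbuild.molgraph`.

The objective is *crowding*  Xi = S + alpha W, with

  S  steric congestion: sum of inverse distances over every unique atom pair,
     weighted 1 (H-H), 2 (H-nonH), 4 (nonH-nonH); purely repulsive, so
     minimization spreads the ligands apart;
  W  coordination warp: squared tooth-to-vertex deviations (fixed-shape mode)
     or squared radial deviations from the target bond lengths (free-shape
     mode), tethering the coordination polyhedron;
  alpha = 100 |A| / sqrt(|Pi|)  (A^-3), balancing the two scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .complexes import Complex
from .molgraph import InputError, rotation_about_axis

__all__ = [
    "CrowdingResult",
    "euler_rotate",
    "wheel_rotate",
    "hinge_rotate",
    "set_position",
    "steric_congestion",
    "coordination_warp",
    "crowding",
    "alpha_weight",
]

COINCIDENCE_TOL = 1e-6  # Angstrom


@dataclass(frozen=True)
class CrowdingResult:
    S: float      # steric congestion, 1/Angstrom
    S_HH: float
    S_HJ: float
    S_JJ: float
    W: float      # coordination warp, Angstrom^2
    alpha: float  # 1/Angstrom^3
    Xi: float     # crowding, 1/Angstrom


def _euler_zyz(a_deg: float, b_deg: float, c_deg: float) -> np.ndarray:
    """Z-Y-Z Euler rotation matrix (degrees)."""
    Rz1 = rotation_about_axis(np.array([0.0, 0.0, 1.0]), a_deg)
    Ry = rotation_about_axis(np.array([0.0, 1.0, 0.0]), b_deg)
    Rz2 = rotation_about_axis(np.array([0.0, 0.0, 1.0]), c_deg)
    return Rz1 @ Ry @ Rz2


def euler_rotate(cx: Complex, m: int, angles_deg: tuple[float, float, float]) -> None:
    """Rotate ligand ``m`` about its barycenter (Z-Y-Z convention).

    The barycenter, hence the metal-ligand center distance, is unchanged.
    """
    rows = cx.ligand_rows(m)
    bary = cx.X[rows].mean(axis=0)
    R = _euler_zyz(*angles_deg)
    cx.X[rows] = (cx.X[rows] - bary) @ R.T + bary


def wheel_rotate(cx: Complex, m: int, angle_deg: float) -> None:
    """Spin monodentate ligand ``m`` about the metal-tooth axis.

    Metal and tooth are on the axis and therefore fixed.
    """
    lig = cx.ligands[m]
    if lig.denticity != 1:
        raise InputError("wheel angles are defined for monodentate ligands only")
    tooth = cx.global_index(m, lig.teeth[0])
    axis = cx.X[tooth] - cx.X[0]
    norm = np.linalg.norm(axis)
    if norm < COINCIDENCE_TOL:
        raise InputError("tooth coincides with the metal center")
    R = rotation_about_axis(axis / norm, angle_deg)
    rows = cx.ligand_rows(m)
    origin = cx.X[tooth].copy()
    cx.X[rows] = (cx.X[rows] - origin) @ R.T + origin


def hinge_rotate(cx: Complex, m: int, angle_deg: float) -> None:
    """Swing bidentate ligand ``m`` about its tooth-tooth axis.

    Both teeth are on the axis and therefore fixed.
    """
    lig = cx.ligands[m]
    if lig.denticity != 2:
        raise InputError("hinge angles are defined for bidentate ligands only")
    t1 = cx.global_index(m, lig.teeth[0])
    t2 = cx.global_index(m, lig.teeth[1])
    axis = cx.X[t2] - cx.X[t1]
    norm = np.linalg.norm(axis)
    if norm < COINCIDENCE_TOL:
        raise InputError("coincident teeth: degenerate hinge axis")
    R = rotation_about_axis(axis / norm, angle_deg)
    rows = cx.ligand_rows(m)
    origin = cx.X[t1].copy()
    cx.X[rows] = (cx.X[rows] - origin) @ R.T + origin


def set_position(
    cx: Complex,
    m: int,
    *,
    ray: float | None = None,
    space: tuple[float, float, float] | None = None,
) -> None:
    """Translate ligand ``m`` rigidly to a new barycenter position.

    ``ray=r`` slides the ligand along its coordination ray (the half-line
    from the metal through the barycenter) to barycenter distance ``r``;
    ``space=(r, inclination, azimuth)`` places the barycenter at those
    spherical coordinates (radians), orientation preserved.  The two modes
    cannot be combined.
    """
    if (ray is None) == (space is None):
        raise InputError("exactly one of ray= or space= must be given")
    rows = cx.ligand_rows(m)
    bary = cx.X[rows].mean(axis=0)
    if ray is not None:
        norm = np.linalg.norm(bary)
        if norm < COINCIDENCE_TOL:
            raise InputError("barycenter at the metal: coordination ray undefined")
        target = bary / norm * float(ray)
    else:
        r, theta, phi = space
        target = np.array(
            [
                r * np.sin(theta) * np.cos(phi),
                r * np.sin(theta) * np.sin(phi),
                r * np.cos(theta),
            ]
        )
    cx.X[rows] = cx.X[rows] + (target - bary)


def steric_congestion(cx: Complex) -> tuple[float, float, float, float]:
    """Weighted inverse-distance sum over every unique atom pair.

    Returns ``(S, S_HH, S_HJ, S_JJ)``; the metal counts as a non-hydrogen
    atom and all pairs (bonded, intra-ligand, metal) are included.
    """
    X = cx.X
    is_h = np.array([a.is_hydrogen for a in cx.system.atoms])
    D = pdist(X)
    if D.min(initial=np.inf) < COINCIDENCE_TOL:
        M = squareform(D)
        np.fill_diagonal(M, np.inf)
        i, j = np.unravel_index(np.argmin(M), M.shape)
        raise InputError(
            f"coincident atoms {i} ({cx.system.atoms[i].element}) and "
            f"{j} ({cx.system.atoms[j].element}): steric congestion singular"
        )
    inv = 1.0 / D
    n = len(X)
    iu, ju = np.triu_indices(n, k=1)
    hh = is_h[iu] & is_h[ju]
    jj = ~is_h[iu] & ~is_h[ju]
    hj = ~(hh | jj)
    s_hh = float(inv[hh].sum())
    s_hj = 2.0 * float(inv[hj].sum())
    s_jj = 4.0 * float(inv[jj].sum())
    return s_hh + s_hj + s_jj, s_hh, s_hj, s_jj


def coordination_warp(cx: Complex, reference: np.ndarray, mode: str) -> float:
    """Squared deviation of the coordination polyhedron from its target.

    ``mode="fixed"``: ``reference`` is the rescaled, permuted vertex matrix
    aligned with the tooth order; W is the sum of squared tooth-to-vertex
    distances.  ``mode="free"``: ``reference`` is the per-tooth target bond
    length vector (Angstrom); W is the sum of squared radial deviations.
    """
    teeth = cx.teeth_global
    T = cx.X[teeth]
    reference = np.asarray(reference, dtype=float)
    if mode == "fixed":
        if reference.shape != T.shape:
            raise InputError(
                f"reference vertex matrix shape {reference.shape} does not "
                f"match {len(teeth)} teeth"
            )
        return float(np.sum((T - reference) ** 2))
    if mode == "free":
        if reference.shape != (len(teeth),):
            raise InputError(
                f"need one target length per tooth ({len(teeth)}), got "
                f"{reference.shape}"
            )
        radii = np.linalg.norm(T, axis=1)
        return float(np.sum((radii - reference) ** 2))
    raise InputError(f"unknown warp mode {mode!r}")


def alpha_weight(cx: Complex) -> float:
    """Scale factor balancing warp against congestion: 100 |A| / sqrt(|Pi|)."""
    return 100.0 * cx.system.n_atoms / np.sqrt(cx.coordination_number)


def crowding(cx: Complex, reference: np.ndarray, mode: str) -> CrowdingResult:
    """Crowding Xi = S + alpha W with all parts reported."""
    S, s_hh, s_hj, s_jj = steric_congestion(cx)
    W = coordination_warp(cx, reference, mode)
    alpha = alpha_weight(cx)
    return CrowdingResult(S, s_hh, s_hj, s_jj, W, alpha, S + alpha * W)
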