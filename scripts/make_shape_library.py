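"""Regenerate the packaged reference-polyhedron library (data/shapes.json).

Each shape is an ideal coordination polyhedron with a documented, fixed
orientation and vertex numbering.  Bite pairs (vertex pairs eligible to host
one bidentate ligand) are the true convex-hull edges of the reference
vertices.  The script validates every entry before writing:

  * detected proper rotation-group order matches the polyhedron's point group
  * all-distinct-monodentate stereoisomer counts match the classical census
    (2, 20, 30, 504, 5040, 60480, 453600 for CN 4-10 prevalent shapes)
  * edge-restricted chelate censuses: Ma3b(AB)2 on BTPR-8 -> 640 (12 achiral)
    and Ma3(AA)3 on MFF-9 -> 232 (10 achiral)

Run from the repository root:  python scripts/make_shape_library.py
"""

from __future__ import annotations

import json
import math
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lnbuild.geometry import hull_edges, find_vertex_isometries  # noqa: E402


def ring(k: int, inclination_deg: float, az_offset_deg: float = 0.0) -> list[list[float]]:
    th = math.radians(inclination_deg)
    out = []
    for i in range(k):
        az = math.radians(az_offset_deg + 360.0 * i / k)
        out.append([math.sin(th) * math.cos(az), math.sin(th) * math.sin(az), math.cos(th)])
    return out


def tetrahedron() -> list[list[float]]:
    s = 1.0 / math.sqrt(3.0)
    return [[s, s, s], [s, -s, -s], [-s, s, -s], [-s, -s, s]]


def trigonal_bipyramid() -> list[list[float]]:
    return ring(3, 90.0) + [[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]


def square_pyramid() -> list[list[float]]:
    # apical vertex on +z; basal ring lowered below the metal plane so the
    # centroid stays inside (spherical square pyramid, basal inclination
    # 104.45 deg as in the continuous shape-measure references)
    return [[0.0, 0.0, 1.0]] + ring(4, 104.45)


def octahedron() -> list[list[float]]:
    # numbering chosen so the antipodal index pairs are (1,6), (2,4), (3,5)
    # (1-based); consecutive index pairs are then edges, which keeps the
    # classical tris-chelate permutations [1 2 3 4 5 6] / [1 2 5 4 3 6] valid
    return [
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, -1.0, 0.0],
        [0.0, 0.0, -1.0],
        [-1.0, 0.0, 0.0],
    ]


def capped_octahedron() -> list[list[float]]:
    # C3v: cap on +z over an upper triangular face, lower face staggered
    return [[0.0, 0.0, 1.0]] + ring(3, 75.0) + ring(3, 138.0, 60.0)


def pentagonal_bipyramid() -> list[list[float]]:
    return ring(5, 90.0) + [[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]


def _sapr_theta() -> float:
    # ring inclination that equalizes intra-ring and inter-ring edges of the
    # sphere-inscribed square antiprism
    from scipy.optimize import brentq

    def gap(th):
        a = np.array([math.sin(th), 0.0, math.cos(th)])
        b = np.array(
            [
                math.sin(th) * math.cos(math.pi / 4),
                math.sin(th) * math.sin(math.pi / 4),
                -math.cos(th),
            ]
        )
        ring_edge = math.sqrt(2.0) * math.sin(th)
        return np.linalg.norm(a - b) - ring_edge

    return brentq(gap, math.radians(30), math.radians(89))


def square_antiprism() -> list[list[float]]:
    th = math.degrees(_sapr_theta())
    return ring(4, th) + ring(4, 180.0 - th, 45.0)


def triangular_dodecahedron() -> list[list[float]]:
    # two orthogonal planar trapezoids (D2d), A/B vertex inclinations from the
    # classical hard-sphere ideal of the eight-coordinate dodecahedron
    ta, tb = math.radians(36.85), math.radians(69.46)
    sa, ca = math.sin(ta), math.cos(ta)
    sb, cb = math.sin(tb), math.cos(tb)
    return [
        [sa, 0.0, ca], [-sa, 0.0, ca],      # A pair, xz plane, up
        [sb, 0.0, -cb], [-sb, 0.0, -cb],    # B pair, xz plane, down
        [0.0, sa, -ca], [0.0, -sa, -ca],    # A pair, yz plane, down
        [0.0, sb, cb], [0.0, -sb, cb],      # B pair, yz plane, up
    ]


def biaugmented_trigonal_prism() -> list[list[float]]:
    # Johnson solid J50, unit edge; vertex centroid at the origin.  Not
    # radially projected: projection would fold the remaining square face and
    # create a spurious hull diagonal.
    s = 1.0
    R = s / math.sqrt(3.0)
    h = s / 2.0
    az = [math.radians(a) for a in (90.0, 210.0, 330.0)]
    top = [[R * math.cos(a), R * math.sin(a), h] for a in az]
    bot = [[R * math.cos(a), R * math.sin(a), -h] for a in az]
    verts = top + bot
    for i, j in ((0, 1), (0, 2)):  # augment the two faces sharing vertex 0's edge
        quad = np.array([top[i], top[j], bot[j], bot[i]])
        c = quad.mean(axis=0)
        n = c.copy()
        n[2] = 0.0
        n /= np.linalg.norm(n)
        verts.append(list(c + n * (s / math.sqrt(2.0))))
    V = np.array(verts)
    V -= V.mean(axis=0)
    V /= np.linalg.norm(V, axis=1).mean()
    return V.tolist()


def tricapped_trigonal_prism() -> list[list[float]]:
    # D3h: prism triangles at +-45 deg inclination, caps on the equator over
    # the three square faces
    return ring(3, 45.0, 90.0) + ring(3, 135.0, 90.0) + ring(3, 90.0, 30.0)


def muffin() -> list[list[float]]:
    # Cs: apical cap, a 5-ring and a staggered 3-ring sharing the cap's
    # mirror plane (xz); validated against the published chelate census
    return [[0.0, 0.0, 1.0]] + ring(5, 75.0) + ring(3, 138.0)


def bicapped_square_antiprism() -> list[list[float]]:
    th = math.degrees(_sapr_theta())
    return (
        [[0.0, 0.0, 1.0]]
        + ring(4, th)
        + ring(4, 180.0 - th, 45.0)
        + [[0.0, 0.0, -1.0]]
    )


SHAPES = {
    "T-4": ("Tetrahedron", tetrahedron, 12),
    "TBPY-5": ("Trigonal bipyramid", trigonal_bipyramid, 6),
    "SPY-5": ("Square pyramid", square_pyramid, 4),
    "OC-6": ("Octahedron", octahedron, 24),
    "COC-7": ("Capped octahedron", capped_octahedron, 3),
    "PBPY-7": ("Pentagonal bipyramid", pentagonal_bipyramid, 10),
    "SAPR-8": ("Square antiprism", square_antiprism, 8),
    "TDD-8": ("Triangular dodecahedron", triangular_dodecahedron, 4),
    "BTPR-8": ("Biaugmented trigonal prism", biaugmented_trigonal_prism, 2),
    "TCTPR-9": ("Tricapped trigonal prism", tricapped_trigonal_prism, 6),
    "MFF-9": ("Muffin", muffin, 1),
    "JBCSAPR-10": ("Bicapped square antiprism", bicapped_square_antiprism, 8),
}

CLASSIC_COUNTS = {
    "T-4": 2, "TBPY-5": 20, "OC-6": 30, "PBPY-7": 504,
    "SAPR-8": 5040, "TCTPR-9": 60480, "JBCSAPR-10": 453600,
}


def main() -> None:
    out = {}
    for label, (name, build, expected_order) in SHAPES.items():
        V = np.array(build(), dtype=float)
        edges = hull_edges(V)
        order = len(find_vertex_isometries(V, kind="proper"))
        assert order == expected_order, (label, order, expected_order)
        if label in CLASSIC_COUNTS:
            assert math.factorial(len(V)) // order == CLASSIC_COUNTS[label], label
        out[label] = {
            "name": name,
            "vertices": [[round(float(x), 12) for x in row] for row in V],
            "bite_pairs": [list(e) for e in edges],
        }
        print(f"{label:12s} |G| = {order:3d}  edges = {len(edges)}")

    target = Path(__file__).resolve().parents[1] / "src" / "lnbuild" / "data" / "shapes.json"
    target.write_text(json.dumps(out, indent=1))
    print(f"wrote {target}")

    # chelate censuses through the package machinery
    from lnbuild import shapes as sh

    sh._library.cache_clear()
    sh._isometries_cached.cache_clear()
    n640 = sh.count_stereoisomers(sh.load_shape("BTPR-8"), "Ma3b(AB)2")
    n232 = sh.count_stereoisomers(sh.load_shape("MFF-9"), "Ma3(AA)3")
    print(f"BTPR-8 Ma3b(AB)2: {n640}   MFF-9 Ma3(AA)3: {n232}")
    assert n640 == 640 and n232 == 232
    ach_btpr = sum(
        sh.is_achiral_isomer(sh.load_shape("BTPR-8"), "Ma3b(AB)2", s.permutation)
        for s in sh.enumerate_stereoisomers(sh.load_shape("BTPR-8"), "Ma3b(AB)2")
    )
    ach_mff = sum(
        sh.is_achiral_isomer(sh.load_shape("MFF-9"), "Ma3(AA)3", s.permutation)
        for s in sh.enumerate_stereoisomers(sh.load_shape("MFF-9"), "Ma3(AA)3")
    )
    print(f"achiral: BTPR-8 {ach_btpr} (expect 12), MFF-9 {ach_mff} (expect 10)")
    assert ach_btpr == 12 and ach_mff == 10


if __name__ == "__main__":
    main()
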