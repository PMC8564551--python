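"""Reference coordination polyhedra, sites, rotation groups, stereoisomer
enumeration and permutation encoding.

A shape is a labeled ideal polyhedron: a vertex geometry matrix, a partition
of the vertices into *sites* (one per ligand; a site's size equals the
ligand's denticity) and vertex colors mirroring tooth colors.  Stereoisomers
of a complex on a shape are encoded as permutations of the vertex rows: the
k-th tooth of the complex (in canonical ligand order) sits on vertex
``perm[k]``.  Two permutations encode the same stereoisomer when a proper
rotation of the polyhedron (combined with exchanges of identical ligands and
the tooth swap of symmetric bidentates) maps one tooth placement onto the
other; enumeration therefore counts orbits of valid placements under the
polyhedron's proper rotation group.

A bidentate ligand's two teeth must sit on a *bite pair*: an edge of the
reference polyhedron (convex-hull edge; triangulation diagonals of planar
faces are not edges).
"""

from __future__ import annotations

import itertools
import json
import math
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import numpy as np

from .bondtables import BondTargetTable
from .complexes import Complex, GenericFormula, parse_formula
from .geometry import find_vertex_isometries, kabsch_orthogonal
from .molgraph import InputError

__all__ = [
    "Shape",
    "RotationGroup",
    "StereoisomerID",
    "SHAPE_LABELS",
    "load_shape",
    "rotation_group",
    "enumerate_stereoisomers",
    "count_stereoisomers",
    "apply_stereoisomer",
    "assign_sites",
    "rescale_vertices",
    "parse_permutation",
    "format_permutation",
    "point_group_label",
]


@dataclass
class Shape:
    """An ideal coordination polyhedron."""

    label: str
    name: str
    Z: np.ndarray  # n x 3 vertex geometry
    bite_pairs: tuple[tuple[int, int], ...]
    sites: tuple[tuple[int, ...], ...] = ()
    vertex_colors: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)

    @property
    def n_vertices(self) -> int:
        return len(self.Z)

    def copy(self) -> "Shape":
        return Shape(
            self.label, self.name, self.Z.copy(), tuple(self.bite_pairs),
            tuple(self.sites), tuple(self.vertex_colors),
        )


@dataclass(frozen=True)
class RotationGroup:
    """Finite group of vertex permutations realizable by proper rotations."""

    perms: tuple[tuple[int, ...], ...]

    @property
    def order(self) -> int:
        return len(self.perms)

    def __iter__(self):
        return iter(self.perms)

    def verify_axioms(self) -> bool:
        ps = set(self.perms)
        n = len(self.perms[0])
        if tuple(range(n)) not in ps:
            return False
        for a in self.perms:
            for b in self.perms:
                if tuple(a[b[i]] for i in range(n)) not in ps:
                    return False
        return True


@dataclass(frozen=True)
class StereoisomerID:
    """A stereoisomer: shape label + vertex permutation (0-based internally)."""

    shape_label: str
    permutation: tuple[int, ...]
    point_group: str | None = None

    def text(self) -> str:
        return format_permutation(self.permutation)


def parse_permutation(text: str) -> tuple[int, ...]:
    """Parse the bracketed 1-based style, e.g. "[1 2 5 4 3 6]"."""
    body = text.strip()
    if body.startswith("[") and body.endswith("]"):
        body = body[1:-1]
    toks = [t for t in re.split(r"[,\s]+", body.strip()) if t]
    try:
        vals = [int(t) for t in toks]
    except ValueError as exc:
        raise InputError(f"cannot parse permutation {text!r}") from exc
    if sorted(vals) != list(range(1, len(vals) + 1)):
        raise InputError(f"{text!r} is not a permutation of 1..{len(vals)}")
    return tuple(v - 1 for v in vals)


def format_permutation(perm: tuple[int, ...]) -> str:
    return "[" + " ".join(str(v + 1) for v in perm) + "]"


# -- shape library ---------------------------------------------------------

@lru_cache(maxsize=1)
def _library() -> dict:
    path = resources.files("lnbuild").joinpath("data").joinpath("shapes.json")
    with path.open() as fh:
        return json.load(fh)


SHAPE_LABELS = (
    "T-4", "TBPY-5", "SPY-5", "OC-6", "COC-7", "PBPY-7",
    "SAPR-8", "TDD-8", "BTPR-8", "TCTPR-9", "MFF-9", "JBCSAPR-10",
)


def load_shape(label: str) -> Shape:
    """Load an ideal polyhedron from the packaged library."""
    lib = _library()
    if label not in lib:
        raise InputError(
            f"unknown shape {label!r}; library: {', '.join(sorted(lib))}"
        )
    entry = lib[label]
    return Shape(
        label=label,
        name=entry["name"],
        Z=np.array(entry["vertices"], dtype=float),
        bite_pairs=tuple((int(a), int(b)) for a, b in entry["bite_pairs"]),
    )


@lru_cache(maxsize=32)
def _isometries_cached(label: str, kind: str) -> tuple[tuple[int, ...], ...]:
    shape = load_shape(label)
    return tuple(find_vertex_isometries(shape.Z, kind=kind))


def rotation_group(shape: Shape, tol: float = 1e-5) -> RotationGroup:
    """Proper rotation group of the polyhedron, as vertex permutations."""
    if shape.label in _library() and np.array_equal(shape.Z, load_shape(shape.label).Z):
        perms = _isometries_cached(shape.label, "proper")
    else:
        perms = tuple(find_vertex_isometries(shape.Z, kind="proper", tol=tol))
    group = RotationGroup(perms)
    assert group.verify_axioms(), "rotation set is not closed; tolerance issue"
    return group


def improper_isometries(shape: Shape) -> tuple[tuple[int, ...], ...]:
    """Vertex permutations realizable by improper isometries (det = -1)."""
    if shape.label in _library() and np.array_equal(shape.Z, load_shape(shape.label).Z):
        return _isometries_cached(shape.label, "improper")
    return tuple(find_vertex_isometries(shape.Z, kind="improper"))


# -- placements ------------------------------------------------------------
#
# A placement assigns every vertex a tooth label and groups bidentate teeth
# into pairs.  Serialized form: (labels tuple, sorted tuple of sorted pairs).

def _formula_groups(formula: GenericFormula) -> list[tuple[str, int]]:
    """Ligand groups in canonical order: [(kind, count)]; mono kinds are the
    single letters, bidentate kinds the two-letter strings."""
    groups = [(sym, count) for sym, count in formula.monodentate]
    for sym, count in formula.polydentate:
        if len(sym) != 2:
            raise InputError(
                "stereoisomer enumeration supports mono- and bidentate "
                f"ligands only (got ({sym}))"
            )
        groups.append((sym, count))
    return groups


def _mono_label(letter: str) -> str:
    return f"m:{letter}"


def _bi_label(kind: str, letter: str) -> str:
    return f"b:{kind}:{letter}"


class Placement:
    """Immutable tooth placement on a shape's vertices."""

    __slots__ = ("labels", "pairs")

    def __init__(self, labels: tuple[str, ...], pairs: tuple[tuple[int, int], ...]):
        self.labels = labels
        self.pairs = tuple(sorted(tuple(sorted(p)) for p in pairs))

    def key(self):
        return (self.labels, self.pairs)

    def __eq__(self, other):
        return self.key() == other.key()

    def __hash__(self):
        return hash(self.key())

    def transform(self, perm: tuple[int, ...]) -> "Placement":
        """Placement after moving vertex v to vertex perm[v]."""
        labels = [""] * len(self.labels)
        for v, lab in enumerate(self.labels):
            labels[perm[v]] = lab
        pairs = tuple((perm[a], perm[b]) for a, b in self.pairs)
        return Placement(tuple(labels), pairs)


def _canonical(placement: Placement, group: RotationGroup) -> Placement:
    return min((placement.transform(g) for g in group), key=Placement.key)


def _enumerate_placements(
    shape: Shape, groups: list[tuple[str, int]]
) -> list[Placement]:
    n = shape.n_vertices
    bites = [tuple(sorted(p)) for p in shape.bite_pairs]
    results: list[Placement] = []
    labels0: list[str | None] = [None] * n

    def rec(gi: int, labels: list[str | None], pairs: list[tuple[int, int]]):
        if gi == len(groups):
            results.append(Placement(tuple(labels), tuple(pairs)))  # type: ignore[arg-type]
            return
        kind, count = groups[gi]
        free = [v for v in range(n) if labels[v] is None]
        if len(kind) == 1:
            for combo in itertools.combinations(free, count):
                for v in combo:
                    labels[v] = _mono_label(kind)
                rec(gi + 1, labels, pairs)
                for v in combo:
                    labels[v] = None
        else:
            avail = [p for p in bites if labels[p[0]] is None and labels[p[1]] is None]
            symmetric = kind[0] == kind[1]
            for combo in itertools.combinations(avail, count):
                flat = [v for p in combo for v in p]
                if len(flat) != len(set(flat)):
                    continue  # overlapping bite pairs
                orient_choices = (
                    [[p] for p in combo]
                    if symmetric
                    else [[p, (p[1], p[0])] for p in combo]
                )
                for directed in itertools.product(*orient_choices):
                    for (a, b) in directed:
                        labels[a] = _bi_label(kind, kind[0])
                        labels[b] = _bi_label(kind, kind[1])
                    rec(gi + 1, labels, list(pairs) + [tuple(sorted(p)) for p in directed])
                    for (a, b) in directed:
                        labels[a] = labels[b] = None
        return

    rec(0, labels0, [])
    # orientation products of symmetric kinds or overlapping recursion can
    # produce duplicates; dedup on the serialized form
    return list(dict.fromkeys(results))


def _placement_to_permutation(
    placement: Placement, groups: list[tuple[str, int]]
) -> tuple[int, ...]:
    """Teeth-to-vertex permutation in canonical ligand order."""
    perm: list[int] = []
    used_pairs = set()
    for kind, count in groups:
        if len(kind) == 1:
            verts = sorted(
                v for v, lab in enumerate(placement.labels) if lab == _mono_label(kind)
            )
            perm.extend(verts)
        else:
            instances = []
            for a, b in placement.pairs:
                la, lb = placement.labels[a], placement.labels[b]
                if {la, lb} == {_bi_label(kind, kind[0]), _bi_label(kind, kind[1])} or (
                    kind[0] == kind[1] and la == lb == _bi_label(kind, kind[0])
                ):
                    if (a, b) in used_pairs:
                        continue
                    if kind[0] == kind[1]:
                        instances.append((a, b))
                    else:
                        first = a if la == _bi_label(kind, kind[0]) else b
                        second = b if first == a else a
                        instances.append((first, second))
                    used_pairs.add((a, b))
            instances.sort(key=lambda p: min(p))
            for inst in instances:
                perm.extend(inst)
    return tuple(perm)


def _permutation_to_placement(
    shape: Shape, perm: tuple[int, ...], groups: list[tuple[str, int]]
) -> Placement:
    n = shape.n_vertices
    if sorted(perm) != list(range(n)):
        raise InputError(
            f"permutation {format_permutation(tuple(perm))} is not a "
            f"bijection on {n} vertices"
        )
    labels: list[str | None] = [None] * n
    pairs: list[tuple[int, int]] = []
    bites = {tuple(sorted(p)) for p in shape.bite_pairs}
    k = 0
    for kind, count in groups:
        for _ in range(count):
            if len(kind) == 1:
                labels[perm[k]] = _mono_label(kind)
                k += 1
            else:
                a, b = perm[k], perm[k + 1]
                if tuple(sorted((a, b))) not in bites:
                    raise InputError(
                        f"teeth {k + 1},{k + 2} of a ({kind}) ligand sit on "
                        f"vertices {a + 1},{b + 1}, which are not an edge "
                        f"(bite pair) of {shape.label}"
                    )
                labels[a] = _bi_label(kind, kind[0])
                labels[b] = _bi_label(kind, kind[1])
                pairs.append((a, b))
                k += 2
    if k != n:
        raise InputError(
            f"formula denticities sum to {k}, but {shape.label} has {n} vertices"
        )
    return Placement(tuple(labels), tuple(pairs))  # type: ignore[arg-type]


def _formula_of(formula: GenericFormula | str | Complex) -> GenericFormula:
    if isinstance(formula, Complex):
        return formula.generic_formula()
    if isinstance(formula, str):
        return parse_formula(formula)
    return formula


def enumerate_stereoisomers(
    shape: Shape, formula: GenericFormula | str | Complex
) -> list[StereoisomerID]:
    """All distinct stereoisomers, one canonical representative per orbit.

    The canonical representative is the placement whose serialized form is
    lexicographically least within its orbit under the proper rotation group;
    the returned list is sorted by permutation.
    """
    f = _formula_of(formula)
    groups = _formula_groups(f)
    if f.coordination_number != shape.n_vertices:
        raise InputError(
            f"formula coordination number {f.coordination_number} does not "
            f"match {shape.label} ({shape.n_vertices} vertices)"
        )
    group = rotation_group(shape)
    canon: dict[tuple, Placement] = {}
    for placement in _enumerate_placements(shape, groups):
        c = _canonical(placement, group)
        canon.setdefault(c.key(), c)
    ids = [
        StereoisomerID(shape.label, _placement_to_permutation(c, groups))
        for c in canon.values()
    ]
    return sorted(ids, key=lambda s: s.permutation)


def _burnside_monodentate(shape: Shape, counts: list[int]) -> int:
    """Burnside orbit count for monodentate-only color multisets."""
    group = rotation_group(shape)
    total = 0
    for g in group:
        # cycle lengths of g
        seen = set()
        cycles = []
        for v in range(len(g)):
            if v in seen:
                continue
            c, w = 0, v
            while w not in seen:
                seen.add(w)
                w = g[w]
                c += 1
            cycles.append(c)

        from functools import lru_cache as _lru

        @_lru(maxsize=None)
        def ways(ci: int, remaining: tuple[int, ...]) -> int:
            if ci == len(cycles):
                return 1 if not any(remaining) else 0
            tot = 0
            for li, r in enumerate(remaining):
                if r >= cycles[ci]:
                    nxt = list(remaining)
                    nxt[li] -= cycles[ci]
                    tot += ways(ci + 1, tuple(nxt))
            return tot

        total += ways(0, tuple(counts))
    return total // group.order


def count_stereoisomers(
    shape: Shape, formula: GenericFormula | str | Complex, method: str = "auto"
) -> int:
    """Number of distinct stereoisomers of the formula on the shape.

    ``method``: "auto" picks Burnside orbit counting for monodentate-only
    formulas (instantaneous even for 10 coordination) and canonical-form
    enumeration otherwise; "enumerate" forces explicit enumeration;
    "burnside" forces the lemma (monodentate-only formulas).
    """
    f = _formula_of(formula)
    if f.coordination_number != shape.n_vertices:
        raise InputError(
            f"formula coordination number {f.coordination_number} does not "
            f"match {shape.label} ({shape.n_vertices} vertices)"
        )
    mono_only = not f.polydentate
    if method == "burnside" or (method == "auto" and mono_only):
        if not mono_only:
            raise InputError("Burnside counting requires monodentate-only formulas")
        counts = [c for _, c in f.monodentate]
        if all(c == 1 for c in counts):
            # free action: only the identity fixes an all-distinct labeling
            n = shape.n_vertices
            return math.factorial(n) // rotation_group(shape).order
        return _burnside_monodentate(shape, counts)
    return len(enumerate_stereoisomers(shape, f))


def canonical_stereoisomer(
    shape: Shape, formula: GenericFormula | str | Complex, perm: tuple[int, ...]
) -> StereoisomerID:
    """Canonical representative of the orbit containing ``perm``."""
    f = _formula_of(formula)
    groups = _formula_groups(f)
    placement = _permutation_to_placement(shape, perm, groups)
    c = _canonical(placement, rotation_group(shape))
    return StereoisomerID(shape.label, _placement_to_permutation(c, groups))


def is_achiral_isomer(
    shape: Shape, formula: GenericFormula | str | Complex, perm: tuple[int, ...]
) -> bool:
    """True when some improper isometry maps the isomer onto its own orbit."""
    f = _formula_of(formula)
    groups = _formula_groups(f)
    placement = _permutation_to_placement(shape, perm, groups)
    group = rotation_group(shape)
    canon = _canonical(placement, group).key()
    for m in improper_isometries(shape):
        if _canonical(placement.transform(m), group).key() == canon:
            return True
    return False


def apply_stereoisomer(shape: Shape, sid: StereoisomerID) -> Shape:
    """Shape with vertex rows reordered so row k hosts tooth k.

    Site memberships (consecutive tooth blocks) and vertex colors follow the
    same reordering.
    """
    perm = sid.permutation
    n = shape.n_vertices
    if sorted(perm) != list(range(n)):
        raise InputError("stereoisomer permutation is not a bijection")
    Z = shape.Z[list(perm)]
    inv = {v: k for k, v in enumerate(perm)}
    bites = tuple(
        tuple(sorted((inv[a], inv[b]))) for a, b in shape.bite_pairs
    )
    sites = tuple(
        tuple(sorted(inv[v] for v in site)) for site in shape.sites
    ) if shape.sites else ()
    colors = (
        tuple(shape.vertex_colors[perm[k]] for k in range(n))
        if shape.vertex_colors
        else ()
    )
    return Shape(shape.label, shape.name, Z, bites, sites, colors)


# -- site assignment and rescaling ----------------------------------------

@dataclass(frozen=True)
class SiteAssignment:
    """Ligand-to-site binding: per ligand, the vertex row of each tooth."""

    shape: Shape  # vertex rows aligned with teeth order
    vertices_per_ligand: tuple[tuple[int, ...], ...]
    color_map: dict[int, int]  # ligand tooth color -> site color
    stereoisomer: StereoisomerID


def assign_sites(
    shape: Shape,
    cx: Complex,
    stereoisomer: StereoisomerID | tuple[int, ...] | str | None = None,
) -> SiteAssignment:
    """Associate every ligand of the complex with one site of the shape.

    With an explicit stereoisomer permutation the sites are its consecutive
    tooth blocks; otherwise the canonical first stereoisomer of the formula
    is used.  The returned assignment carries the shape with rows permuted to
    line up with the complex's tooth order, plus the ligand-color to
    vertex-color map.
    """
    formula = cx.generic_formula()
    groups = _formula_groups(formula)
    if formula.coordination_number != shape.n_vertices:
        raise InputError(
            f"complex has {formula.coordination_number} teeth but "
            f"{shape.label} has {shape.n_vertices} vertices: cannot bind all "
            "ligands without leaving a site vacant"
        )
    if stereoisomer is None:
        ids = enumerate_stereoisomers(shape, formula)
        sid = ids[0]
    else:
        if isinstance(stereoisomer, str):
            perm = parse_permutation(stereoisomer)
        elif isinstance(stereoisomer, StereoisomerID):
            perm = stereoisomer.permutation
        else:
            perm = tuple(stereoisomer)
        _permutation_to_placement(shape, perm, groups)  # validates
        sid = StereoisomerID(shape.label, perm)

    aligned = apply_stereoisomer(shape, sid)
    # consecutive blocks per ligand
    blocks: list[tuple[int, ...]] = []
    k = 0
    for lig in cx.ligands:
        blocks.append(tuple(range(k, k + lig.denticity)))
        k += lig.denticity
    aligned.sites = tuple(blocks)
    tooth_colors = cx.tooth_colors
    aligned.vertex_colors = tuple(tooth_colors)
    color_map = {c: c for c in set(tooth_colors)}
    return SiteAssignment(aligned, tuple(blocks), color_map, sid)


def rescale_vertices(
    assignment: SiteAssignment,
    cx: Complex,
    table: BondTargetTable,
) -> SiteAssignment:
    """Scale each vertex to its target coordinate bond length (Angstrom).

    Directions are unchanged; vertex k is placed at
    r0[metal, element of tooth k] along its unit direction.  Idempotent.
    """
    shape = assignment.shape.copy()
    teeth = cx.teeth_global
    metal = cx.metal
    for k, tooth in enumerate(teeth):
        element = cx.system.atoms[tooth].element
        r0 = table.target_length_angstrom(metal.element, metal.oxidation_state, element)
        direction = shape.Z[k] / np.linalg.norm(shape.Z[k])
        shape.Z[k] = direction * r0
    return replace(assignment, shape=shape)


# -- identification and point groups ---------------------------------------

def identify_placement(
    shape: Shape,
    formula: GenericFormula | str | Complex,
    teeth_xyz: np.ndarray,
) -> StereoisomerID:
    """Canonical stereoisomer of teeth positions docked on a shape.

    Tooth k (row k of ``teeth_xyz``, complex tooth order) is matched to the
    angularly nearest vertex of the *reference* shape by optimal assignment;
    the resulting placement is canonicalized.
    """
    from scipy.optimize import linear_sum_assignment

    f = _formula_of(formula)
    groups = _formula_groups(f)
    T = np.asarray(teeth_xyz, dtype=float)
    T = T / np.linalg.norm(T, axis=1, keepdims=True)
    V = shape.Z / np.linalg.norm(shape.Z, axis=1, keepdims=True)
    cost = np.linalg.norm(T[:, None] - V[None, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = tuple(int(cols[list(rows).index(k)]) for k in range(len(T)))
    return canonical_stereoisomer(shape, f, perm)


def _axis_and_angle(M: np.ndarray) -> tuple[np.ndarray | None, float]:
    angle = math.acos(min(1.0, max(-1.0, (np.trace(M) - 1.0) / 2.0)))
    if angle < 1e-8:
        return None, 0.0
    w, v = np.linalg.eig(M)
    idx = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, idx])
    axis /= np.linalg.norm(axis)
    return axis, angle


def point_group_label(
    shape: Shape, formula: GenericFormula | str | Complex, perm: tuple[int, ...]
) -> str:
    """Schoenflies label of the colored coordination polyhedron.

    The stabilizer of the tooth placement inside the polyhedron's full
    isometry group is classified by its element inventory (principal axis
    order, perpendicular two-fold axes, mirror planes).
    """
    f = _formula_of(formula)
    groups = _formula_groups(f)
    placement = _permutation_to_placement(shape, perm, groups)
    key = placement.key()

    proper_ms, improper_ms = [], []
    V = shape.Z
    for g in find_vertex_isometries(V, kind="proper"):
        if placement.transform(g).key() == key:
            M, _ = kabsch_orthogonal(V[list(g)], V)
            proper_ms.append(M)
    for g in find_vertex_isometries(V, kind="improper"):
        if placement.transform(g).key() == key:
            _, M = kabsch_orthogonal(V[list(g)], V)
            improper_ms.append(M)

    h = len(proper_ms)
    chiral = not improper_ms

    # principal axis
    axes = []
    for M in proper_ms:
        axis, angle = _axis_and_angle(M)
        if axis is not None:
            order = int(round(2.0 * math.pi / angle))
            axes.append((order, axis))
    n = max((o for o, _ in axes), default=1)
    principal = next((a for o, a in axes if o == n), None)
    perp_c2 = 0
    if principal is not None:
        for o, a in axes:
            if o == 2 and abs(float(np.dot(a, principal))) < 1e-6:
                perp_c2 += 1
    dihedral = n >= 2 and perp_c2 >= n and h >= 2 * n

    if h == 1:
        if chiral:
            return "C1"
        M = improper_ms[0]
        return "Ci" if np.allclose(M, -np.eye(3), atol=1e-6) else "Cs"
    if dihedral:
        if chiral:
            return f"D{n}"
        # distinguish by a horizontal mirror (normal along principal axis)
        for M in improper_ms:
            if np.allclose(M @ principal, -principal, atol=1e-6) and np.allclose(
                M @ M, np.eye(3), atol=1e-6
            ):
                return f"D{n}h"
        return f"D{n}d"
    if chiral:
        return f"C{n}"
    has_sigma_v = False
    has_sigma_h = False
    for M in improper_ms:
        if not np.allclose(M @ M, np.eye(3), atol=1e-6):
            continue  # rotoreflection, not a plane
        if principal is None:
            continue
        if np.allclose(M @ principal, principal, atol=1e-6):
            has_sigma_v = True
        if np.allclose(M @ principal, -principal, atol=1e-6):
            has_sigma_h = True
    if has_sigma_h:
        return f"C{n}h"
    if has_sigma_v:
        return f"C{n}v"
    return f"S{2 * n}"
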