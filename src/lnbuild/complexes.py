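"""Ligands, tooth colors, ligand ordering, complex assembly and the generic
formula grammar.

A ligand is a molecular system plus a distinguished set of coordinating atoms
(its *teeth*).  Every tooth carries a *color*: an integer such that two teeth
share a color exactly when their rooted chemical environments (element and
bond orders, recursively outward) are indistinguishable.  The tuple of tooth
colors, in tooth-serial order, is the ligand *type*.

A complex is a metal center at the origin plus an ordered ligand list; the
complex geometry matrix is the metal row followed by each ligand's block, in
canonical ligand order.

Generic formulas follow the field's compact notation: ``M`` for the metal,
lower-case letters for monodentate ligands, parenthesized upper-case strings
for polydentate ones, with trailing multiplicities, e.g. ``Ma3(AA)3``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .molgraph import Atom, InputError, MolecularSystem, Topology, neighbors


@dataclass
class Ligand:
    """A molecular system with teeth (coordinating atom serials) and charge."""

    system: MolecularSystem
    teeth: tuple[int, ...]
    charge: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.teeth = tuple(sorted(self.teeth))
        if not self.teeth:
            raise InputError("a ligand needs at least one tooth")
        for t in self.teeth:
            if not 0 <= t < self.system.n_atoms:
                raise InputError(f"tooth serial {t} out of range")

    @property
    def denticity(self) -> int:
        return len(self.teeth)

    @property
    def n_atoms(self) -> int:
        return self.system.n_atoms

    def copy(self) -> "Ligand":
        return Ligand(self.system.copy(), self.teeth, self.charge, self.name)


def _refine_colors(ligands: list[Ligand]) -> list[dict[int, str]]:
    """Weisfeiler-Lehman refinement over the disjoint union of ligand graphs.

    Returns one {atom serial -> signature string} map per ligand.  Signatures
    are canonical (independent of atom serialization) because classes are
    renamed by sorted signature each round.
    """
    # node key: (ligand index, atom serial)
    labels: dict[tuple[int, int], str] = {}
    for li, lig in enumerate(ligands):
        for atom in lig.system.atoms:
            labels[(li, atom.serial)] = atom.element
    n_nodes = len(labels)
    n_classes = len(set(labels.values()))
    for _ in range(n_nodes):
        new_sig: dict[tuple[int, int], str] = {}
        for (li, a), lab in labels.items():
            lig = ligands[li]
            env = sorted(
                (repr(lig.system.topology.order(a, b)), labels[(li, b)])
                for b in lig.system.topology.adjacency(a)
            )
            new_sig[(li, a)] = lab + "|" + ";".join(f"{o}:{s}" for o, s in env)
        # canonical renaming keeps signatures bounded and serialization-free
        ranks = {s: f"c{r:03d}" for r, s in enumerate(sorted(set(new_sig.values())))}
        labels = {k: ranks[new_sig[k]] for k in new_sig}
        new_n = len(set(labels.values()))
        if new_n == n_classes:
            break
        n_classes = new_n
    out: list[dict[int, str]] = []
    for li, lig in enumerate(ligands):
        out.append({a.serial: labels[(li, a.serial)] for a in lig.system.atoms})
    return out


def assign_colors(ligands: list[Ligand]) -> list[dict[int, int]]:
    """Tooth colors by fixed-point environment refinement.

    Colors are positive integers, comparable across all ligands passed in one
    call; equal colors mean indistinguishable rooted chemical environments.
    Numbering is canonical (sorted by class signature), hence stable across
    runs and atom re-serializations.
    """
    sigs = _refine_colors(ligands)
    tooth_sigs = sorted(
        {sigs[li][t] for li, lig in enumerate(ligands) for t in lig.teeth}
    )
    color_of_sig = {s: i + 1 for i, s in enumerate(tooth_sigs)}
    return [
        {t: color_of_sig[sigs[li][t]] for t in lig.teeth}
        for li, lig in enumerate(ligands)
    ]


def ligand_type(lig: Ligand, colors: dict[int, int]) -> tuple[int, ...]:
    """Tuple of tooth colors in tooth-serial order."""
    return tuple(colors[t] for t in lig.teeth)


def _order_key(lig_type: tuple[int, ...], multiplicity: int) -> tuple:
    counts: dict[int, int] = {}
    for c in lig_type:
        counts[c] = counts.get(c, 0) + 1
    max_repeat = max(counts.values())
    return (
        len(lig_type),       # denticity ascending
        -max_repeat,         # identically-colored teeth descending
        -multiplicity,       # most-repeated ligand type first (notation order)
        min(lig_type),       # lowest color ascending
        tuple(sorted(lig_type)),
    )


def order_ligands(ligands: list[Ligand]) -> tuple[list[Ligand], list[dict[int, int]]]:
    """Canonical ligand ordering.

    Ascending denticity; within a denticity, descending number of
    identically-colored teeth, then most-repeated ligand type first (so the
    internal order matches the generic-formula notation), then ascending
    lowest color; the sort is stable, and identical ligands end up adjacent.
    Returns the reordered ligand list with their tooth-color maps.
    """
    color_maps = assign_colors(ligands)
    types = [ligand_type(ligands[i], color_maps[i]) for i in range(len(ligands))]
    multiplicity = {t: types.count(t) for t in set(types)}
    keyed = sorted(
        range(len(ligands)),
        key=lambda i: _order_key(types[i], multiplicity[types[i]]),
    )
    return [ligands[i] for i in keyed], [color_maps[i] for i in keyed]


@dataclass(frozen=True)
class Metal:
    element: str
    oxidation_state: int


@dataclass
class Complex:
    """A metal at the origin plus ordered ligands, as one molecular system."""

    metal: Metal
    ligands: list[Ligand]
    colors: list[dict[int, int]]  # per ligand: tooth serial -> color
    system: MolecularSystem = field(init=False)

    def __post_init__(self) -> None:
        atoms: list[Atom] = [Atom(0, self.metal.element)]
        topo = Topology()
        rows = [np.zeros((1, 3))]
        offset = 1
        for lig in self.ligands:
            for a in lig.system.atoms:
                atoms.append(Atom(offset + a.serial, a.element))
            for a, b, o in lig.system.topology.bonds():
                topo.set_bond(offset + a, offset + b, o)
            for t in lig.teeth:
                topo.set_bond(0, offset + t, 1)  # coordination bond
            rows.append(lig.system.X)
            offset += lig.system.n_atoms
        self.system = MolecularSystem(atoms, topo, np.vstack(rows))
        if self.coordination_number < 1:
            raise InputError("a complex needs at least one coordinate bond")

    # -- index bookkeeping -------------------------------------------------
    def ligand_offset(self, m: int) -> int:
        """Global serial of the first atom of ligand ``m`` (metal is row 0)."""
        return 1 + sum(self.ligands[n].n_atoms for n in range(m))

    def global_index(self, m: int, i: int) -> int:
        """Global serial of local atom ``i`` of ligand ``m``."""
        if not 0 <= m < len(self.ligands):
            raise InputError(f"ligand position {m} out of range")
        if not 0 <= i < self.ligands[m].n_atoms:
            raise InputError(f"atom serial {i} out of range for ligand {m}")
        return self.ligand_offset(m) + i

    def local_index(self, j: int) -> tuple[int, int]:
        """Inverse of :meth:`global_index` for non-metal atoms."""
        if not 1 <= j < self.system.n_atoms:
            raise InputError(f"global serial {j} is not a ligand atom")
        for m in range(len(self.ligands)):
            off = self.ligand_offset(m)
            if j < off + self.ligands[m].n_atoms:
                return m, j - off
        raise InputError(f"global serial {j} out of range")

    def ligand_rows(self, m: int) -> slice:
        off = self.ligand_offset(m)
        return slice(off, off + self.ligands[m].n_atoms)

    # -- coordinate system -------------------------------------------------
    @property
    def teeth_global(self) -> list[int]:
        """Global serials of all teeth, in ligand order then tooth order."""
        out = []
        for m, lig in enumerate(self.ligands):
            off = self.ligand_offset(m)
            out.extend(off + t for t in lig.teeth)
        return out

    @property
    def coordination_number(self) -> int:
        return len(self.teeth_global)

    @property
    def tooth_colors(self) -> list[int]:
        """Colors of the teeth, aligned with :attr:`teeth_global`."""
        out = []
        for m, lig in enumerate(self.ligands):
            out.extend(self.colors[m][t] for t in lig.teeth)
        return out

    @property
    def X(self) -> np.ndarray:
        return self.system.X

    @X.setter
    def X(self, value: np.ndarray) -> None:
        self.system.X = np.asarray(value, dtype=float)

    def ligand_barycenter(self, m: int) -> np.ndarray:
        return self.system.X[self.ligand_rows(m)].mean(axis=0)

    def generic_formula(self) -> "GenericFormula":
        """Generic formula derived from the ligand types."""
        mono: list[tuple[int, ...]] = []
        poly: list[tuple[int, ...]] = []
        for m, lig in enumerate(self.ligands):
            t = ligand_type(lig, self.colors[m])
            (mono if len(t) == 1 else poly).append(t)
        letters: dict[tuple[int, ...], str] = {}
        mono_terms: list[tuple[str, int]] = []
        for t in mono:
            if t not in letters:
                letters[t] = chr(ord("a") + len([k for k in letters if len(k) == 1]))
                mono_terms.append((letters[t], 0))
        poly_terms: list[tuple[str, int]] = []
        upper_used = 0
        color_letter: dict[int, str] = {}
        for t in poly:
            if t not in letters:
                sym = ""
                for c in t:
                    if c not in color_letter:
                        color_letter[c] = chr(ord("A") + upper_used)
                        upper_used += 1
                    sym += color_letter[c]
                letters[t] = sym
                poly_terms.append((sym, 0))
        mono_counts = {letters[t]: mono.count(t) for t in set(mono)}
        poly_counts = {letters[t]: poly.count(t) for t in set(poly)}
        return GenericFormula(
            metal=self.metal.element,
            monodentate=[(s, mono_counts[s]) for s, _ in mono_terms],
            polydentate=[(s, poly_counts[s]) for s, _ in poly_terms],
        )


def assemble_complex(metal: Metal, ligands: list[Ligand]) -> Complex:
    """Order the ligands canonically and assemble the complex."""
    ordered, colors = order_ligands(ligands)
    return Complex(metal, [lig.copy() for lig in ordered], colors)


# -- generic formula grammar ----------------------------------------------

_TERM_RE = re.compile(r"([a-z])(\d*)|\(([A-Z]+)\)(\d*)")

# metals commonly seen at the M position of a generic formula
_ELEMENT_SYMBOLS = frozenset(
    "Li Na K Rb Cs Be Mg Ca Sr Ba Sc Ti V Cr Mn Fe Co Ni Cu Zn Y Zr Nb Mo Tc "
    "Ru Rh Pd Ag Cd Hf Ta W Re Os Ir Pt Au Hg Al Ga In Sn Tl Pb Bi "
    "La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Th U".split()
)


@dataclass(frozen=True)
class GenericFormula:
    """Parsed generic complex formula, e.g. Ma3b(AB)2."""

    metal: str
    monodentate: list[tuple[str, int]]  # (letter, count)
    polydentate: list[tuple[str, int]]  # (letter string, count)

    @property
    def coordination_number(self) -> int:
        return sum(c for _, c in self.monodentate) + sum(
            len(s) * c for s, c in self.polydentate
        )

    @property
    def denticities(self) -> list[int]:
        out = [1] * sum(c for _, c in self.monodentate)
        for s, c in self.polydentate:
            out.extend([len(s)] * c)
        return out

    def text(self) -> str:
        """Formula text: monodentate terms then polydentate terms, in the
        stored (canonical ligand) order."""
        parts = [self.metal]
        for sym, count in self.monodentate:
            parts.append(sym + (str(count) if count > 1 else ""))
        for sym, count in self.polydentate:
            parts.append(f"({sym})" + (str(count) if count > 1 else ""))
        return "".join(parts)


def parse_formula(text: str) -> GenericFormula:
    """Parse a generic formula string.

    Raises :class:`InputError` with the offending position on malformed
    input.
    """
    if not text:
        raise InputError("empty formula")
    m = re.match(r"([A-Z][a-z]?)", text)
    if m is None or text[0].islower():
        raise InputError("formula must start with the metal symbol (position 0)")
    metal = m.group(1)
    pos = m.end()
    # 'M' is the generic metal; a two-letter prefix is kept only if it is a
    # real element symbol (otherwise the lower-case letter is a monodentate).
    if len(metal) == 2 and metal not in _ELEMENT_SYMBOLS:
        metal = metal[0]
        pos = 1
    mono: list[tuple[str, int]] = []
    poly: list[tuple[str, int]] = []
    while pos < len(text):
        m = _TERM_RE.match(text, pos)
        if m is None:
            raise InputError(f"cannot parse formula at position {pos}: {text[pos:]!r}")
        if m.group(1):
            count = int(m.group(2)) if m.group(2) else 1
            mono.append((m.group(1), count))
        else:
            count = int(m.group(4)) if m.group(4) else 1
            poly.append((m.group(3), count))
        pos = m.end()
    for sym, count in mono + poly:
        if count < 1:
            raise InputError(f"count for {sym!r} must be >= 1")
    seen = [s for s, _ in mono + poly]
    if len(seen) != len(set(seen)):
        raise InputError("repeated ligand symbol in formula")
    return GenericFormula(metal, mono, poly)
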