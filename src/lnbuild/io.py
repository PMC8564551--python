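"""Structure input/output.

Ligands are read from MDL MOL/SDF files (bond orders explicit; aromatic
bonds map to order 1.5) or from XYZ plus a plain-text bond-table sidecar.
Bond perception from coordinates is deliberately not performed: the
algorithms are topology-driven and the topology must be explicit.

Complexes are written as XYZ (metal first, then ligand blocks in canonical
order) or PDB (HETATM records, one residue per ligand, CONECT records for
the coordinate bonds).  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
from rdkit import Chem

from .complexes import Complex, Ligand
from .molgraph import Atom, InputError, MolecularSystem, Topology

__all__ = ["read_ligand", "read_xyz_points", "write_structure"]

_RDKIT_ORDERS = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 1.5,
    Chem.BondType.DATIVE: 1,
}


def _from_rdkit(mol: Chem.Mol, teeth, charge: int, name: str) -> Ligand:
    if mol.GetNumConformers() == 0:
        raise InputError("structure has no coordinates")
    conf = mol.GetConformer()
    atoms = [Atom(a.GetIdx(), a.GetSymbol()) for a in mol.GetAtoms()]
    X = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
          conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())]
    )
    topo = Topology()
    for b in mol.GetBonds():
        order = _RDKIT_ORDERS.get(b.GetBondType())
        if order is None:
            raise InputError(
                f"unsupported bond order {b.GetBondType()} between atoms "
                f"{b.GetBeginAtomIdx()} and {b.GetEndAtomIdx()}"
            )
        topo.set_bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order)
    return Ligand(MolecularSystem(atoms, topo, X), tuple(teeth), charge, name)


def _read_xyz_with_bonds(path: Path, teeth, charge: int) -> Ligand:
    sidecar = path.with_suffix(".bonds")
    if not sidecar.exists():
        raise InputError(
            f"XYZ input {path} requires a bond-table sidecar {sidecar.name} "
            "(lines: i j order, 1-based); bond perception from coordinates "
            "is not performed"
        )
    lines = path.read_text().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise InputError(f"{path}:1: bad atom count line") from exc
    elements, coords = [], []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise InputError(f"{path}:{ln}: expected 'element x y z'")
        elements.append(parts[0])
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError as exc:
            raise InputError(f"{path}:{ln}: bad coordinate") from exc
    if len(elements) != n:
        raise InputError(f"{path}: atom count {n} does not match body")
    topo = Topology()
    for ln, line in enumerate(sidecar.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise InputError(f"{sidecar}:{ln}: expected 'i j order'")
        try:
            i, j, order = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as exc:
            raise InputError(f"{sidecar}:{ln}: bad bond entry") from exc
        order = int(order) if order in (1.0, 2.0, 3.0) else order
        topo.set_bond(i - 1, j - 1, order)
    atoms = [Atom(i, el) for i, el in enumerate(elements)]
    return Ligand(
        MolecularSystem(atoms, topo, np.array(coords)), tuple(teeth), charge,
        path.stem,
    )


def read_ligand(
    path: str | Path, teeth, charge: int = 0, name: str | None = None
) -> Ligand:
    """Read a ligand structure with explicit bond orders.

    ``teeth`` are 0-based atom indices of the coordinating atoms (declared by
    the caller, never perceived).  MOL/SDF bond blocks supply the topology;
    XYZ files need a ``.bonds`` sidecar.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mol", ".sdf", ".mdl"):
        mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
        if mol is None:
            raise InputError(f"cannot parse MOL/SDF file {path}")
        return _from_rdkit(mol, teeth, charge, name or path.stem)
    if suffix == ".xyz":
        return _read_xyz_with_bonds(path, teeth, charge)
    raise InputError(f"unsupported structure format {suffix!r} (MOL/SDF/XYZ)")


def read_xyz_points(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Plain XYZ reader returning (symbols, coordinates)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    symbols, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    return symbols, np.array(coords)


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_structure(cx: Complex, path: str | Path, comment: str = "") -> None:
    """Write the complex as XYZ or PDB, chosen by file extension."""
    path = Path(path)
    X = cx.X
    if not np.all(np.isfinite(X)):
        raise InputError("non-finite coordinates; refusing to write")
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        lines = [str(cx.system.n_atoms), comment]
        for atom, row in zip(cx.system.atoms, X):
            lines.append(
                f"{atom.element:2s} {row[0]:14.8f} {row[1]:14.8f} {row[2]:14.8f}"
            )
        _atomic_write(path, "\n".join(lines) + "\n")
        return
    if suffix == ".pdb":
        lines = []
        serial = 1
        lines.append(
            f"HETATM{serial:5d} {cx.metal.element:<4s}MET A   1    "
            f"{X[0, 0]:8.3f}{X[0, 1]:8.3f}{X[0, 2]:8.3f}  1.00  0.00"
            f"          {cx.metal.element:>2s}"
        )
        for m, lig in enumerate(cx.ligands):
            res = m + 2
            for i in range(lig.n_atoms):
                serial += 1
                j = cx.global_index(m, i)
                el = cx.system.atoms[j].element
                lines.append(
                    f"HETATM{serial:5d} {el:<4s}LIG A{res:4d}    "
                    f"{X[j, 0]:8.3f}{X[j, 1]:8.3f}{X[j, 2]:8.3f}  1.00  0.00"
                    f"          {el:>2s}"
                )
        for tooth in cx.teeth_global:
            lines.append(f"CONECT{1:5d}{tooth + 1:5d}")
        lines.append("END")
        _atomic_write(path, "\n".join(lines) + "\n")
        return
    raise InputError(f"unsupported output format {suffix!r} (XYZ/PDB)")
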