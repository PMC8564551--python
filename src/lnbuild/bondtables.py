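"""Target coordinate bond lengths and effective ionic radii for lanthanoids.

Target lengths are median + MAD metal-tooth distances over a curated set of
crystallographic lanthanoid complexes, tabulated per (metal, oxidation state,
coordinating element) in picometers.  Pairs absent from the structural data
are filled by the ionic-radius shift rule

    r0[N, t] = r0[M, t] - rho[M] + rho[N]

which works across the series because lanthanoid-ligand bonding is essentially
electrostatic: the only systematic difference between ions of the same charge
is the effective ionic radius (lanthanide contraction).  Divalent radii
missing from the literature are completed by a quadratic fit in atomic number.

Internal geometry is in Angstrom; these tables are the single pm/Angstrom
boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "LANTHANOIDS",
    "ATOMIC_NUMBER",
    "ARGUMENT_IONS",
    "IonicRadiusTable",
    "BondTargetTable",
    "divalent_radius",
    "fit_divalent_radius_curve",
    "interpolate_length",
]

LANTHANOIDS = (
    "La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu".split()
)
ATOMIC_NUMBER = {m: 57 + i for i, m in enumerate(LANTHANOIDS)}

# argument ion used to fill missing trivalent pairs, per coordinating element
ARGUMENT_IONS = {
    "O": "Eu", "N": "Eu", "S": "Eu", "Cl": "Eu", "Br": "Eu",
    "P": "Dy", "I": "Dy", "F": "Pm",
}

# quadratic completion of the divalent radii (pm), fitted to the six
# literature divalent radii; see fit_divalent_radius_curve
_DIVALENT_QUADRATIC = (0.2097, -30.043, 1177.2)


class LookupError_(KeyError):
    """Missing table entry; message lists the supported keys."""


def _read_csv(name: str) -> list[dict[str, str]]:
    path = resources.files("lnbuild").joinpath("data").joinpath(name)
    with path.open() as fh:
        rows = [r for r in fh if not r.startswith("#")]
    return list(csv.DictReader(rows))


def _round_pm(x: float) -> int:
    """Round to nearest pm, halves away from zero (table convention)."""
    return int(np.floor(x + 0.5))


def divalent_radius(Z: int) -> float:
    """Effective divalent lanthanoid radius (pm) from the quadratic in Z."""
    if not 57 <= Z <= 71:
        raise LookupError_(f"atomic number {Z} outside the lanthanoid range 57-71")
    a, b, c = _DIVALENT_QUADRATIC
    return a * Z * Z + b * Z + c


def fit_divalent_radius_curve(
    points: list[tuple[int, float]],
) -> tuple[float, float, float, float]:
    """Ordinary least-squares quadratic radius(Z); returns (a, b, c, R^2)."""
    if len(points) < 3:
        raise ValueError("need at least three (Z, radius) points")
    Z = np.array([p[0] for p in points], dtype=float)
    r = np.array([p[1] for p in points], dtype=float)
    A = np.vstack([Z**2, Z, np.ones_like(Z)]).T
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("rank-deficient design (collinear Z values)")
    coef, *_ = np.linalg.lstsq(A, r, rcond=None)
    pred = A @ coef
    ss_res = float(np.sum((r - pred) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(coef[0]), float(coef[1]), float(coef[2]), r2


@dataclass(frozen=True)
class IonicRadiusTable:
    """(metal, oxidation state) -> effective ionic radius in pm."""

    radii: dict[tuple[str, int], float]
    provenance: dict[tuple[str, int], str]

    @classmethod
    def default(cls) -> "IonicRadiusTable":
        radii, prov = {}, {}
        for row in _read_csv("ionic_radii.csv"):
            key = (row["metal"], int(row["ox"]))
            radii[key] = float(row["radius_pm"])
            prov[key] = row["provenance"]
        return cls(radii, prov)

    def radius(self, metal: str, ox: int) -> float:
        try:
            return self.radii[(metal, ox)]
        except KeyError:
            known = sorted({m for m, _ in self.radii})
            raise LookupError_(
                f"no radius for {metal}({ox:+d}); known metals: {', '.join(known)}"
            ) from None


def interpolate_length(
    radii: IonicRadiusTable,
    result_ion: tuple[str, int],
    argument_ion: tuple[str, int],
    r0_argument_pm: float,
) -> float:
    """Ionic-radius shift rule: r0[N,t] = r0[M,t] - rho[M] + rho[N] (pm)."""
    if result_ion[1] != argument_ion[1]:
        raise ValueError(
            "argument and result ions must share the oxidation state "
            f"({argument_ion[1]:+d} vs {result_ion[1]:+d})"
        )
    return (
        r0_argument_pm
        - radii.radius(*argument_ion)
        + radii.radius(*result_ion)
    )


@dataclass(frozen=True)
class BondTargetTable:
    """(metal, ox, element) -> target coordinate bond length in pm."""

    entries: dict[tuple[str, int, str], float]
    provenance: dict[tuple[str, int, str], str]
    radii: IonicRadiusTable

    @classmethod
    def default(cls) -> "BondTargetTable":
        entries, prov = {}, {}
        for name, ox in (
            ("bond_lengths_trivalent.csv", 3),
            ("bond_lengths_divalent.csv", 2),
        ):
            for row in _read_csv(name):
                key = (row["metal"], ox, row["element"])
                entries[key] = float(row["length_pm"])
                prov[key] = row["provenance"]
        return cls(entries, prov, IonicRadiusTable.default())

    @classmethod
    def from_file(cls, path: str | Path, ox: int = 3) -> "BondTargetTable":
        """User override table in the same metal,element,length_pm layout."""
        base = cls.default()
        entries = dict(base.entries)
        prov = dict(base.provenance)
        with open(path) as fh:
            rows = [r for r in fh if not r.startswith("#")]
        for row in csv.DictReader(rows):
            key = (row["metal"], int(row.get("ox", ox)), row["element"])
            entries[key] = float(row["length_pm"])
            prov[key] = row.get("provenance", "user")
        return cls(entries, prov, base.radii)

    def target_length(self, metal: str, ox: int, element: str) -> float:
        """Target length in pm; fills unknown lanthanoid pairs by the shift
        rule when an argument ion for the element is tabulated."""
        key = (metal, ox, element)
        if key in self.entries:
            return self.entries[key]
        arg = ARGUMENT_IONS.get(element)
        if arg is not None and (arg, ox, element) in self.entries:
            return float(
                _round_pm(
                    interpolate_length(
                        self.radii,
                        (metal, ox),
                        (arg, ox),
                        self.entries[(arg, ox, element)],
                    )
                )
            )
        elements = sorted({e for _, _, e in self.entries})
        raise LookupError_(
            f"no target length for {metal}({ox:+d})-{element}; supported "
            f"coordinating elements: {', '.join(elements)}"
        )

    def target_length_angstrom(self, metal: str, ox: int, element: str) -> float:
        return self.target_length(metal, ox, element) / 100.0
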