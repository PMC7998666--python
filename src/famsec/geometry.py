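"""Structural diagnostics: distances, torsions, van-der-Waals contacts.

These are the geometric observables that accompany a mechanism narrative —
bond elongations on the way to a transition state, the signed dihedral a
substituent rotates through, and whether an inter-nuclear distance is short
enough (versus the van-der-Waals radii sum) to indicate overlapping electron
clouds rather than a mere near-contact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ResolutionError
from .iqa_io import Structure

__all__ = [
    "BONDI_RADII",
    "distance",
    "dihedral",
    "vdw_contact",
    "ContactResult",
    "geometry_change_report",
]

#: Van der Waals radii in Å (Bondi 1964 compilation, with the conventional
#: group-1/2 extensions). Swap in another table via the radii_table argument.
BONDI_RADII: Mapping[str, float] = {
    "H": 1.20, "He": 1.40,
    "Li": 1.81, "Be": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Br": 1.85, "I": 1.98,
}

_COLLINEAR_TOL = 1e-10  # cross-product norm below this (Å^2) is degenerate


def _pos(structure: Structure, label: str) -> np.ndarray:
    return np.asarray(structure.atom(label).position, dtype=float)


def distance(structure: Structure, label_a: str, label_b: str) -> float:
    """Euclidean inter-nuclear distance d(A,B) in Å."""
    return float(np.linalg.norm(_pos(structure, label_a) - _pos(structure, label_b)))


def dihedral(structure: Structure, a: str, b: str, c: str, d: str) -> float:
    """Signed torsion angle a-b-c-d in degrees, right-hand (IUPAC) convention.

    Returns a value in (-180, 180]; cis (eclipsed) is 0, trans is 180. The
    sign flips when the last atom is mirrored through the a-b-c plane.
    """
    if len({a, b, c, d}) != 4:
        raise DegenerateGeometryError("dihedral needs four distinct atoms")
    p1, p2, p3, p4 = (_pos(structure, lb) for lb in (a, b, c, d))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise DegenerateGeometryError(
            f"collinear atoms in dihedral {a}-{b}-{c}-{d}: torsion undefined"
        )
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:
        angle = 180.0
    return angle


@dataclass(frozen=True)
class ContactResult:
    """Outcome of a van-der-Waals contact test."""

    contact: bool
    margin: float  # (r_a + r_b) - d, Å; positive means inside the vdW sum
    distance: float
    radii_sum: float


def vdw_contact(
    structure: Structure,
    label_a: str,
    label_b: str,
    radii_table: Mapping[str, float] = BONDI_RADII,
) -> ContactResult:
    """Classify a pair as a vdW contact: contact iff d < r_a + r_b strictly."""
    d = distance(structure, label_a, label_b)
    radii = []
    for label in (label_a, label_b):
        element = structure.atom(label).element
        if element not in radii_table:
            raise ResolutionError(f"no van-der-Waals radius for element {element!r}")
        radii.append(radii_table[element])
    rsum = radii[0] + radii[1]
    return ContactResult(
        contact=d < rsum, margin=rsum - d, distance=d, radii_sum=rsum
    )


def geometry_change_report(
    snap_1: Structure,
    snap_2: Structure,
    distance_pairs: Sequence[tuple[str, str]] = (),
    dihedral_quads: Sequence[tuple[str, str, str, str]] = (),
) -> pd.DataFrame:
    """Tabulate distances/dihedrals in two structures and their changes.

    One row per requested item with value(snap_1), value(snap_2) and
    delta = value(snap_2) - value(snap_1).
    """
    rows = []
    for a, b in distance_pairs:
        v1 = distance(snap_1, a, b)
        v2 = distance(snap_2, a, b)
        rows.append(
            {"kind": "distance", "atoms": f"{a}-{b}", "value_1": v1, "value_2": v2, "delta": v2 - v1}
        )
    for quad in dihedral_quads:
        v1 = dihedral(snap_1, *quad)
        v2 = dihedral(snap_2, *quad)
        rows.append(
            {"kind": "dihedral", "atoms": "-".join(quad), "value_1": v1, "value_2": v2, "delta": v2 - v1}
        )
    out = pd.DataFrame(rows)
    out.attrs["labels"] = (snap_1.label, snap_2.label)
    return out
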