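"""A small backbone-independent rotamer library and side-chain builder.

Side chains are constructed from internal coordinates (ideal bond lengths
and angles, chi dihedrals at common staggered values) by the natural
extension reference frame (NeRF) construction.  The library is deliberately
compact — at most 81 candidates per residue type — because the consumer's
contract is *argmin by clash count*, not reproduction of any particular
published library.  Ring geometries are idealised planar approximations,
adequate for steric clash counting at the 2-3 Å scale.
"""

from __future__ import annotations

import math
from itertools import product
from typing import Mapping, Sequence

import numpy as np

__all__ = ["CHI_VALUES", "rotamer_chis", "build_side_chain", "place_atom", "dihedral"]


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d) as given."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


# Topology rows: (atom, ref1, ref2, ref3, bond Å, angle deg, dihedral spec).
# The dihedral spec is a float (fixed) or ("chiN", offset_deg).  CB is placed
# first for every type from the backbone N/C/CA frame.
# L-amino-acid chirality: dihedral(C, N, CA, CB) = -122.6 deg
_CB = ("CB", "C", "N", "CA", 1.53, 110.6, -122.6)

_SIDE_CHAINS: dict[str, list[tuple]] = {
    "ALA": [],
    "SER": [("OG", "N", "CA", "CB", 1.41, 110.5, ("chi1", 0))],
    "CYS": [("SG", "N", "CA", "CB", 1.81, 114.0, ("chi1", 0))],
    "THR": [("OG1", "N", "CA", "CB", 1.43, 109.5, ("chi1", 0)),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, ("chi1", -122.0))],
    "VAL": [("CG1", "N", "CA", "CB", 1.52, 110.5, ("chi1", 0)),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, ("chi1", 122.0))],
    "LEU": [("CG", "N", "CA", "CB", 1.53, 116.0, ("chi1", 0)),
            ("CD1", "CA", "CB", "CG", 1.52, 110.5, ("chi2", 0)),
            ("CD2", "CA", "CB", "CG", 1.52, 110.5, ("chi2", 122.0))],
    "ILE": [("CG1", "N", "CA", "CB", 1.53, 110.5, ("chi1", 0)),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, ("chi1", -122.0)),
            ("CD1", "CA", "CB", "CG1", 1.52, 113.0, ("chi2", 0))],
    "MET": [("CG", "N", "CA", "CB", 1.52, 114.0, ("chi1", 0)),
            ("SD", "CA", "CB", "CG", 1.81, 112.0, ("chi2", 0)),
            ("CE", "CB", "CG", "SD", 1.79, 100.0, ("chi3", 0))],
    "PRO": [("CG", "N", "CA", "CB", 1.50, 104.0, ("chi1", 0)),
            ("CD", "CA", "CB", "CG", 1.51, 105.0, ("chi2", 0))],
    "PHE": [("CG", "N", "CA", "CB", 1.51, 114.0, ("chi1", 0)),
            ("CD1", "CA", "CB", "CG", 1.39, 120.0, ("chi2", 0)),
            ("CD2", "CA", "CB", "CG", 1.39, 120.0, ("chi2", 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0)],
    "TYR": [("CG", "N", "CA", "CB", 1.51, 114.0, ("chi1", 0)),
            ("CD1", "CA", "CB", "CG", 1.39, 120.0, ("chi2", 0)),
            ("CD2", "CA", "CB", "CG", 1.39, 120.0, ("chi2", 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.38, 120.0, 180.0)],
    "TRP": [("CG", "N", "CA", "CB", 1.50, 114.0, ("chi1", 0)),
            ("CD1", "CA", "CB", "CG", 1.37, 127.0, ("chi2", 0)),
            ("CD2", "CA", "CB", "CG", 1.43, 127.0, ("chi2", 180.0)),
            ("NE1", "CB", "CG", "CD1", 1.37, 110.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.41, 107.0, 180.0),
            ("CE3", "CB", "CG", "CD2", 1.40, 133.0, 0.0),
            ("CZ2", "CG", "CD2", "CE2", 1.40, 122.0, 180.0),
            ("CZ3", "CG", "CD2", "CE3", 1.39, 119.0, 180.0),
            ("CH2", "CD2", "CE2", "CZ2", 1.37, 117.0, 0.0)],
    "ASP": [("CG", "N", "CA", "CB", 1.52, 112.0, ("chi1", 0)),
            ("OD1", "CA", "CB", "CG", 1.25, 119.0, ("chi2", 0)),
            ("OD2", "CA", "CB", "CG", 1.25, 119.0, ("chi2", 180.0))],
    "ASN": [("CG", "N", "CA", "CB", 1.52, 112.0, ("chi1", 0)),
            ("OD1", "CA", "CB", "CG", 1.23, 121.0, ("chi2", 0)),
            ("ND2", "CA", "CB", "CG", 1.33, 117.0, ("chi2", 180.0))],
    "GLU": [("CG", "N", "CA", "CB", 1.52, 114.0, ("chi1", 0)),
            ("CD", "CA", "CB", "CG", 1.52, 112.0, ("chi2", 0)),
            ("OE1", "CB", "CG", "CD", 1.25, 119.0, ("chi3", 0)),
            ("OE2", "CB", "CG", "CD", 1.25, 119.0, ("chi3", 180.0))],
    "GLN": [("CG", "N", "CA", "CB", 1.52, 114.0, ("chi1", 0)),
            ("CD", "CA", "CB", "CG", 1.52, 112.0, ("chi2", 0)),
            ("OE1", "CB", "CG", "CD", 1.23, 121.0, ("chi3", 0)),
            ("NE2", "CB", "CG", "CD", 1.33, 117.0, ("chi3", 180.0))],
    "LYS": [("CG", "N", "CA", "CB", 1.52, 114.0, ("chi1", 0)),
            ("CD", "CA", "CB", "CG", 1.52, 111.0, ("chi2", 0)),
            ("CE", "CB", "CG", "CD", 1.52, 111.0, ("chi3", 0)),
            ("NZ", "CG", "CD", "CE", 1.49, 112.0, ("chi4", 0))],
    "ARG": [("CG", "N", "CA", "CB", 1.52, 114.0, ("chi1", 0)),
            ("CD", "CA", "CB", "CG", 1.52, 111.0, ("chi2", 0)),
            ("NE", "CB", "CG", "CD", 1.46, 112.0, ("chi3", 0)),
            ("CZ", "CG", "CD", "NE", 1.33, 124.0, ("chi4", 0)),
            ("NH1", "CD", "NE", "CZ", 1.33, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.33, 120.0, 180.0)],
    "HIS": [("CG", "N", "CA", "CB", 1.50, 114.0, ("chi1", 0)),
            ("ND1", "CA", "CB", "CG", 1.38, 123.0, ("chi2", 0)),
            ("CD2", "CA", "CB", "CG", 1.36, 130.0, ("chi2", 180.0)),
            ("CE1", "CB", "CG", "ND1", 1.32, 109.0, 180.0),
            ("NE2", "CB", "CG", "CD2", 1.37, 107.0, 180.0)],
    "GLY": [],
}

_STAGGER = (-60.0, 60.0, 180.0)
_PLANAR2 = (-90.0, 90.0)

#: Chi-angle value grid per residue type; the Cartesian product defines the
#: candidate list, in deterministic order.
CHI_VALUES: dict[str, tuple[tuple[float, ...], ...]] = {
    "ALA": (), "GLY": (),
    "SER": (_STAGGER,), "CYS": (_STAGGER,), "THR": (_STAGGER,), "VAL": (_STAGGER,),
    "LEU": (_STAGGER, _STAGGER), "ILE": (_STAGGER, _STAGGER),
    "MET": (_STAGGER, _STAGGER, _STAGGER),
    "PRO": ((-25.0, 25.0), (37.0, -37.0)),
    "PHE": (_STAGGER, _PLANAR2), "TYR": (_STAGGER, _PLANAR2),
    "TRP": (_STAGGER, _PLANAR2), "HIS": (_STAGGER, _PLANAR2),
    "ASP": (_STAGGER, (0.0, 60.0, -60.0)), "ASN": (_STAGGER, (0.0, 90.0, 180.0)),
    "GLU": (_STAGGER, _STAGGER, (0.0, 60.0, -60.0)),
    "GLN": (_STAGGER, _STAGGER, (0.0, 90.0, 180.0)),
    "LYS": (_STAGGER, _STAGGER, _STAGGER, _STAGGER),
    "ARG": (_STAGGER, _STAGGER, _STAGGER, _STAGGER),
}


def rotamer_chis(res_name: str) -> list[tuple[float, ...]]:
    """All candidate chi tuples for a residue type, in library order."""
    if res_name not in _SIDE_CHAINS:
        raise KeyError(f"no side-chain topology for residue type {res_name!r}")
    grids = CHI_VALUES[res_name]
    if not grids:
        return [()]
    if res_name == "PRO":  # chi1/chi2 are coupled ring puckers, not a product
        return [(-25.0, 37.0), (25.0, -37.0)]
    return [tuple(c) for c in product(*grids)]


def build_side_chain(
    res_name: str,
    backbone: Mapping[str, np.ndarray],
    chis: Sequence[float],
) -> dict[str, np.ndarray]:
    """Side-chain atom positions (including CB) for one chi assignment.

    ``backbone`` must provide N, CA and C.  Glycine returns an empty dict.
    """
    if res_name == "GLY":
        return {}
    atoms: dict[str, np.ndarray] = {
        "N": np.asarray(backbone["N"], dtype=float),
        "CA": np.asarray(backbone["CA"], dtype=float),
        "C": np.asarray(backbone["C"], dtype=float),
    }
    chi_map = {f"chi{i + 1}": chi for i, chi in enumerate(chis)}
    rows = [_CB] + _SIDE_CHAINS[res_name]
    built: dict[str, np.ndarray] = {}
    for name, r1, r2, r3, bond, angle, dih_spec in rows:
        if isinstance(dih_spec, tuple):
            chi_name, offset = dih_spec
            if chi_name not in chi_map:
                raise ValueError(f"{res_name} requires {chi_name}, got chis={tuple(chis)}")
            dih = chi_map[chi_name] + offset
        else:
            dih = dih_spec
        pos = place_atom(atoms[r1], atoms[r2], atoms[r3], bond, angle, dih)
        atoms[name] = pos
        built[name] = pos
    return built
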