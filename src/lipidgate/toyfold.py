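"""Ideal-geometry peptide builders for tests and demonstrations.

Builds all-atom backbones from standard bond geometry and (phi, psi)
dihedrals via the NeRF construction, with side chains from the first
rotamer of the embedded library.  These are *synthetic* stand-ins for real
template structures — geometrically sound, but not derived from any
experimental model.
"""

from __future__ import annotations

import numpy as np

from . import rotamers
from .domains import THREE_TO_ONE
from .structio import Particle, Structure

__all__ = ["ideal_helix", "ideal_strand", "build_chain"]

_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Engh-Huber-like backbone geometry
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def build_chain(
    sequence: str,
    phi: float = -57.0,
    psi: float = -47.0,
    chain_id: str = "A",
    start_resnum: int = 1,
    with_side_chains: bool = True,
) -> Structure:
    """Peptide with uniform (phi, psi) and ideal bond geometry.

    Side chains (when requested) use the first library rotamer of each type.
    """
    sequence = sequence.upper()
    for c in sequence:
        if c not in _ONE_TO_THREE:
            raise ValueError(f"unknown amino-acid code {c!r}")
    # seed the first residue in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, len(sequence)):
        prev = backbone[-1]
        n = rotamers.place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca = rotamers.place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, 180.0)
        c = rotamers.place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        backbone.append({"N": n, "CA": ca, "C": c})
    particles: list[Particle] = []
    pid = 0
    for i, code in enumerate(sequence):
        res3 = _ONE_TO_THREE[code]
        resnum = start_resnum + i
        bb = backbone[i]
        # carbonyl O anti to the next N (or to psi for the C-terminal residue)
        if i + 1 < len(sequence):
            o = rotamers.place_atom(backbone[i + 1]["N"], bb["CA"], bb["C"],
                                    _B_C_O, _A_CA_C_O, 180.0)
        else:
            o = rotamers.place_atom(bb["N"], bb["CA"], bb["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        for name, pos in (("N", bb["N"]), ("CA", bb["CA"]), ("C", bb["C"]), ("O", o)):
            particles.append(Particle(pid, name, resnum, res3, chain_id, pos))
            pid += 1
        if with_side_chains and res3 != "GLY":
            chis = rotamers.rotamer_chis(res3)[0]
            for name, pos in rotamers.build_side_chain(res3, bb, chis).items():
                particles.append(Particle(pid, name, resnum, res3, chain_id, pos))
                pid += 1
    return Structure(particles)


def ideal_helix(sequence: str, chain_id: str = "A", start_resnum: int = 1,
                with_side_chains: bool = True) -> Structure:
    """Alpha-helical peptide (phi = -57°, psi = -47°)."""
    return build_chain(sequence, -57.0, -47.0, chain_id, start_resnum, with_side_chains)


def ideal_strand(sequence: str, chain_id: str = "A", start_resnum: int = 1,
                 with_side_chains: bool = True) -> Structure:
    """Extended peptide (phi = -120°, psi = 120°)."""
    return build_chain(sequence, -120.0, 120.0, chain_id, start_resnum, with_side_chains)
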