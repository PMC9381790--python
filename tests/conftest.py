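"""Shared fixtures: tiny hand-built structures and frames.

Everything here is generated in memory; no fixture files on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from lipidgate.structio import Frame, Particle, Structure, Trajectory


def make_lipid_sheet(z_per_lipid: dict[int, float]) -> Structure:
    """Minimal membrane topology: one PO4 bead per lipid at the given z.

    Lipids are laid out on an 8 Å grid in x/y; residue numbers are the dict
    keys (chain "L").
    """
    particles = []
    side = int(np.ceil(np.sqrt(len(z_per_lipid))))
    for i, (resnum, z) in enumerate(sorted(z_per_lipid.items())):
        x, y = (i % side) * 8.0, (i // side) * 8.0
        particles.append(Particle(i, "PO4", resnum, "POPC", "L", np.array([x, y, z])))
    return Structure(particles)


def sheet_frames(z_series: list[dict[int, float]], stride_ns: float = 5.0) -> Trajectory:
    """Trajectory over a lipid sheet whose per-lipid z varies by frame.

    All frames share the topology of the first frame's layout; x/y are fixed.
    """
    topo = make_lipid_sheet(z_series[0])
    base = topo.positions
    frames = []
    order = sorted(z_series[0])
    for t, zs in enumerate(z_series):
        pos = base.copy()
        for i, resnum in enumerate(order):
            pos[i, 2] = zs[resnum]
        frames.append(Frame(time_ns=t * stride_ns, positions=pos))
    return Trajectory(topo, frames)


@pytest.fixture
def toy_pdb_text() -> str:
    return (
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00\n"
        "ATOM      2  CA  ALA A   1       2.000   2.500   3.000  1.00  0.00\n"
        "ATOM      3  C   ALA A   1       3.200   1.900   3.100  1.00  0.00\n"
        "END\n"
    )


@pytest.fixture
def toy_gro_text() -> str:
    """Two 12-bead POPC lipids, GRO units (nm)."""
    beads = ["NC3", "PO4", "GL1", "GL2",
             "C1A", "C2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B"]
    lines = ["Two lipids, twelve beads each", " 24"]
    n = 1
    for res in (1, 2):
        for k, bead in enumerate(beads):
            x, y, z = 0.1 * res, 0.05 * k, 2.0 - 0.1 * k
            lines.append(f"{res:5d}{'POPC':<5s}{bead:>5s}{n:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
            n += 1
    lines.append("   6.40000   6.40000  10.00000")
    return "\n".join(lines) + "\n"
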