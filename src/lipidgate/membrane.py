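"""Per-frame membrane reference geometry.

All lipid-extraction measurements are heights above the membrane surface,
defined as the centre of mass of the *upper-leaflet* phosphate particles
(uniform mean — phosphate particles are identical, so mass weighting is a
no-op).  Inputs must be pre-oriented with z as the membrane normal; no
automatic normal detection is attempted.

Leaflets are assigned per frame by the median phosphate z, which stays
robust when lifted lipids pile into a mound above the surface.  Lipids
currently lifted far above the provisional surface are trimmed from the
reference plane in a single re-estimation pass, so that an extracted lipid
does not drag the reference upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .structio import Frame, Structure, StructureError

__all__ = [
    "LipidID",
    "LeafletAssignment",
    "MembranePlane",
    "phosphate_indices",
    "assign_leaflets",
    "reference_plane",
    "lipid_height",
]

#: Lipids are identified by (chain_id, residue_number).
LipidID = tuple[str, int]


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet label for one frame; labels partition the lipid set."""

    frame_index: int
    labels: dict[LipidID, str]  # "upper" | "lower"

    def upper(self) -> list[LipidID]:
        return sorted(l for l, lab in self.labels.items() if lab == "upper")

    def lower(self) -> list[LipidID]:
        return sorted(l for l, lab in self.labels.items() if lab == "lower")


@dataclass
class MembranePlane:
    """Reference z of the upper-leaflet phosphate centre of mass, one frame."""

    frame_index: int
    z0: float  # Å
    n_lipids: int
    n_excluded: int = 0


def phosphate_indices(
    topology: Structure,
    lipids: Sequence[LipidID],
    phosphate_name: str = "PO4",
) -> dict[LipidID, int]:
    """Particle index of each lipid's (single) phosphate particle."""
    out: dict[LipidID, int] = {}
    res_idx = topology.residue_particle_indices()
    for lipid in lipids:
        if lipid not in res_idx:
            raise StructureError(f"lipid {lipid} not in topology")
        hits = [i for i in res_idx[lipid] if topology.particles[i].name == phosphate_name]
        if len(hits) != 1:
            raise StructureError(
                f"lipid {lipid}: expected exactly one {phosphate_name!r} particle, "
                f"found {len(hits)}"
            )
        out[lipid] = hits[0]
    return out


def assign_leaflets(
    frame: Frame,
    topology: Structure,
    lipids: Sequence[LipidID],
    phosphate_name: str = "PO4",
    frame_index: int = 0,
) -> LeafletAssignment:
    """Label each lipid upper/lower by its phosphate z versus the median.

    A lipid is *upper* iff its phosphate z exceeds the median phosphate z of
    all lipids in the frame.  Deterministic and invariant to particle order.
    """
    pidx = phosphate_indices(topology, lipids, phosphate_name)
    lipids_sorted = sorted(pidx)
    zs = np.array([frame.positions[pidx[l], 2] for l in lipids_sorted])
    z_med = float(np.median(zs))
    labels = {
        l: ("upper" if z > z_med else "lower") for l, z in zip(lipids_sorted, zs)
    }
    return LeafletAssignment(frame_index=frame_index, labels=labels)


def reference_plane(
    frame: Frame,
    topology: Structure,
    assignment: LeafletAssignment,
    phosphate_name: str = "PO4",
    exclusion_height_A: float | None = 10.0,
) -> MembranePlane:
    """Upper-leaflet phosphate centre of mass, trimming lifted lipids once.

    A provisional surface height is taken as the *median* upper-leaflet
    phosphate z (robust: a handful of mound lipids cannot drag it upward the
    way a mean would); lipids more than ``exclusion_height_A`` above it are
    dropped and the plain mean of the rest is returned (one iteration).
    Pass ``exclusion_height_A=None`` for the untrimmed literal mean.
    """
    upper = assignment.upper()
    if not upper:
        raise StructureError("no upper-leaflet lipids; cannot define reference plane")
    pidx = phosphate_indices(topology, upper, phosphate_name)
    zs = np.array([frame.positions[pidx[l], 2] for l in upper])
    z_prov = float(np.median(zs))
    n_excluded = 0
    if exclusion_height_A is not None:
        # strict inequality: a lipid at exactly the exclusion height is
        # already "lifted" (the lift bins are left-closed at the same value)
        keep = zs < z_prov + exclusion_height_A
        n_excluded = int((~keep).sum())
        if not keep.any():
            raise StructureError("exclusion removed every upper-leaflet lipid")
        zs = zs[keep]
    return MembranePlane(
        frame_index=assignment.frame_index,
        z0=float(zs.mean()),
        n_lipids=len(zs),
        n_excluded=n_excluded,
    )


def lipid_height(
    frame: Frame,
    topology: Structure,
    lipid: LipidID,
    plane: MembranePlane,
    phosphate_name: str = "PO4",
) -> float:
    """Δz of a lipid's phosphate above the reference plane (may be negative)."""
    idx = phosphate_indices(topology, [lipid], phosphate_name)[lipid]
    return float(frame.positions[idx, 2] - plane.z0)
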