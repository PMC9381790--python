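"""Salt-bridge contacts, occupancies, and the sequential gateway ladder.

A salt bridge is scored when the minimum particle-pair distance between a
lipid headgroup moiety (choline or phosphate) and the side-chain particles
of a charged residue is <= 6 Å — the single cutoff that remains meaningful
for both coarse-grained beads and all-atom charged groups.  Occupancy is the
fraction of frames in a window with at least one such contact; replica
tables are always reported alongside the frame-weighted pooled value.

The *ladder* detector reads out the sequential extraction signature: the
height of the extracted lipid at its first sustained contact with each of
the acidic hand-off residues (D571, D575, E584, D585 — expected onsets
10, 12, 15 and 17 Å above the leaflet surface).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import ResidueSet, THREE_TO_ONE
from .lift import ExtractionTrace
from .structio import Frame, Structure, StructureError, Trajectory

__all__ = [
    "SaltBridgeContact",
    "LadderStep",
    "LadderReport",
    "MOIETY_BEADS",
    "side_chain_indices",
    "contacts_in_frame",
    "occupancy",
    "pool_replicas",
    "ladder",
]

#: Lipid headgroup moiety -> particle names, CG beads first, then the
#: all-atom headgroup atoms.
MOIETY_BEADS: dict[str, tuple[str, ...]] = {
    "choline": ("NC3", "N", "C13", "C14", "C15"),
    "phosphate": ("PO4", "P", "O11", "O12", "O13", "O14"),
}

#: Backbone particle names excluded from "side chain" in CG and AA modes.
_BACKBONE_NAMES = {"BB", "N", "CA", "C", "O", "OXT", "HA", "H"}

#: All-atom charged-group atoms per residue type (standard salt-bridge set).
_AA_CHARGED_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class SaltBridgeContact:
    frame_index: int
    residue: tuple[str, int]
    residue_code: str
    moiety: str
    min_distance: float


@dataclass
class LadderStep:
    residue: tuple[str, int]
    first_frame: int | None      # None = residue never sustained a contact
    dz_at_onset: float | None


@dataclass
class LadderReport:
    steps: list[LadderStep]                  # ordered by first sustained contact
    absent: list[tuple[str, int]]
    expected_order: list[tuple[str, int]]

    @property
    def observed_order(self) -> list[tuple[str, int]]:
        return [s.residue for s in self.steps]

    @property
    def matches_expected_order(self) -> bool:
        expected = [r for r in self.expected_order if r in set(self.observed_order)]
        return self.observed_order == expected and not self.absent


def side_chain_indices(
    topology: Structure,
    residue: tuple[str, int],
    mode: Literal["cg", "aa"] = "cg",
) -> list[int]:
    """Side-chain particle indices of a residue.

    CG mode: every non-backbone bead.  AA mode: the charged-group heavy
    atoms (NZ; NH1/NH2/NE; OD1/OD2; OE1/OE2).  A residue with no side-chain
    particles (glycine) is an error — it cannot form a salt bridge.
    """
    rows = topology.particles_of(*residue)
    res_name = topology.particles[rows[0]].residue_name
    if mode == "aa" and res_name in _AA_CHARGED_ATOMS:
        wanted = _AA_CHARGED_ATOMS[res_name]
        out = [i for i in rows if topology.particles[i].name in wanted]
    else:
        out = [i for i in rows if topology.particles[i].name not in _BACKBONE_NAMES]
    if not out:
        raise StructureError(
            f"residue {residue} ({res_name}) has no side-chain particles; "
            "it cannot form a salt bridge"
        )
    return out


def _moiety_indices(topology: Structure, lipid: tuple[str, int], moiety: str) -> list[int]:
    names = MOIETY_BEADS[moiety]
    rows = [i for i in topology.particles_of(*lipid)
            if topology.particles[i].name in names]
    if not rows:
        raise StructureError(f"lipid {lipid} has no {moiety} particles ({names})")
    return rows


def contacts_in_frame(
    frame: Frame,
    topology: Structure,
    lipid: tuple[str, int],
    residues: ResidueSet,
    cutoff_A: float = 6.0,
    mode: Literal["cg", "aa"] = "cg",
    frame_index: int = 0,
    include_noncontacts: bool = False,
) -> list[SaltBridgeContact]:
    """All (residue, moiety) contacts of one lipid in one frame.

    A contact is reported when the minimum particle-pair distance between
    the moiety particles and the residue's side-chain particles is
    <= ``cutoff_A``.  With ``include_noncontacts`` the distances for
    non-contact pairs are returned as well.
    """
    out = []
    for residue in sorted(residues.members):
        sc_rows = side_chain_indices(topology, residue, mode)
        sc = frame.positions[sc_rows]
        code = THREE_TO_ONE.get(
            topology.particles[sc_rows[0]].residue_name, "X"
        )
        for moiety in ("choline", "phosphate"):
            m_rows = _moiety_indices(topology, lipid, moiety)
            mp = frame.positions[m_rows]
            dmin = float(np.min(np.linalg.norm(sc[:, None, :] - mp[None, :, :], axis=-1)))
            if dmin <= cutoff_A or include_noncontacts:
                out.append(SaltBridgeContact(frame_index, residue, code, moiety, dmin))
    if not include_noncontacts:
        out = [c for c in out if c.min_distance <= cutoff_A]
    return out


def _contact_matrix(
    traj: Trajectory,
    lipids: Sequence[tuple[str, int]],
    residues: ResidueSet,
    cutoff_A: float,
    mode: str,
    window: Sequence[int],
) -> dict[tuple[tuple[str, int], str], np.ndarray]:
    """(residue, moiety) -> per-window-frame bool: any selected lipid in contact.

    Vectorised over frames: one (F, n_moiety, n_sc) distance block per
    (residue, moiety) pair.
    """
    stack = traj.position_stack()[list(window)]
    out: dict[tuple[tuple[str, int], str], np.ndarray] = {}
    moiety_rows = {
        moiety: [r for lipid in lipids for r in _moiety_indices(traj.topology, lipid, moiety)]
        for moiety in ("choline", "phosphate")
    }
    for residue in sorted(residues.members):
        sc_rows = side_chain_indices(traj.topology, residue, mode)
        sc = stack[:, sc_rows, :]
        for moiety, rows in moiety_rows.items():
            mp = stack[:, rows, :]
            d = np.linalg.norm(sc[:, :, None, :] - mp[:, None, :, :], axis=-1)
            out[(residue, moiety)] = d.min(axis=(1, 2)) <= cutoff_A
    return out


def occupancy(
    replicas: Trajectory | Sequence[Trajectory],
    residues: ResidueSet,
    lipids: Sequence[tuple[str, int]] | Literal["all"] = "all",
    cutoff_A: float = 6.0,
    frame_window: Sequence[int] | None = None,
    mode: Literal["cg", "aa"] = "cg",
) -> pd.DataFrame:
    """Occupancy table over one or more replica trajectories.

    One row per (replica, residue, moiety) with columns ``n_contact_frames``,
    ``n_frames`` and ``occupancy``; pooled rows (``replica == "pooled"``) are
    the frame-weighted means.  ``lipids`` selects the contact partners —
    ``"all"`` uses every lipid (the mound convention); pass the extracted
    lipid alone for the single-lipid trace convention.
    """
    if isinstance(replicas, Trajectory):
        replicas = [replicas]
    rows = []
    for rep_id, traj in enumerate(replicas):
        from .lift import lipids_of

        selected = lipids_of(traj.topology) if lipids == "all" else list(lipids)
        window = list(range(len(traj))) if frame_window is None else list(frame_window)
        if not window:
            raise ValueError("frame window is empty")
        mat = _contact_matrix(traj, selected, residues, cutoff_A, mode, window)
        for (residue, moiety), hits in mat.items():
            rows.append({
                "replica": str(rep_id),
                "chain": residue[0],
                "resnum": residue[1],
                "moiety": moiety,
                "n_contact_frames": int(hits.sum()),
                "n_frames": len(window),
                "occupancy": float(hits.mean()),
            })
    table = pd.DataFrame(rows)
    return pd.concat([table, pool_replicas(table)], ignore_index=True)


def pool_replicas(table: pd.DataFrame) -> pd.DataFrame:
    """Frame-weighted pooled occupancy per (residue, moiety)."""
    pooled = (
        table.groupby(["chain", "resnum", "moiety"], as_index=False)
        .agg(n_contact_frames=("n_contact_frames", "sum"), n_frames=("n_frames", "sum"))
    )
    pooled["occupancy"] = pooled["n_contact_frames"] / pooled["n_frames"]
    pooled.insert(0, "replica", "pooled")
    return pooled


def ladder(
    trace: ExtractionTrace,
    traj: Trajectory,
    residues: Sequence[tuple[str, int]] = (("A", 571), ("A", 575), ("A", 584), ("A", 585)),
    cutoff_A: float = 6.0,
    sustain_frames: int = 2,
    moiety: str = "choline",
    mode: Literal["cg", "aa"] = "cg",
) -> LadderReport:
    """Height of the extracted lipid at each residue's first sustained contact.

    For each residue the first frame beginning a run of >= ``sustain_frames``
    consecutive contact frames is found; the lipid's Δz at that frame is
    reported.  Residues that never sustain a contact are flagged absent.
    The report is ordered by onset frame; ``matches_expected_order`` compares
    against the order the residues were passed in.
    """
    if not trace.frame_indices:
        raise ValueError("extraction trace is empty")
    rset = ResidueSet("ladder", frozenset(residues))
    mat = _contact_matrix(traj, [trace.lipid], rset, cutoff_A, mode, trace.frame_indices)
    steps: list[LadderStep] = []
    absent: list[tuple[str, int]] = []
    for residue in residues:
        hits = mat[(residue, moiety)]
        onset = _first_sustained(hits, sustain_frames)
        if onset is None:
            absent.append(residue)
        else:
            steps.append(LadderStep(
                residue=residue,
                first_frame=trace.frame_indices[onset],
                dz_at_onset=trace.dz[onset],
            ))
    steps.sort(key=lambda s: s.first_frame)
    return LadderReport(steps=steps, absent=absent, expected_order=list(residues))


def _first_sustained(hits: np.ndarray, sustain: int) -> int | None:
    if sustain <= 1:
        nz = np.flatnonzero(hits)
        return int(nz[0]) if nz.size else None
    run = 0
    for i, h in enumerate(hits):
        run = run + 1 if h else 0
        if run >= sustain:
            return i - sustain + 1
    return None
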