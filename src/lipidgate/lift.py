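"""Quantifying lipid extraction above the membrane surface.

Three related measurements:

* the **lift histogram** — per frame, lipids in the transmembrane-tunnel
  region are binned by height above the upper-leaflet phosphate plane into
  six 1 Å bins spanning [10, 16) Å;
* **mound detection** — lifted lipids (Δz >= 10 Å) clustered by
  single-linkage in the membrane plane; a cluster of 3-5 lipids ~10 Å above
  the surface is the transient "membrane mound";
* **extraction tracking** — the single lipid that spends the most frames
  lifted, traced with its per-frame height and nearest gateway residue.

Heights use the lipid's phosphate particle, consistent with the phosphorus
reference plane.  Histogram bins are half-open [k, k+1): a lipid at exactly
16.0 Å is outside the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .domains import ResidueSet
from .membrane import (
    LipidID,
    MembranePlane,
    assign_leaflets,
    lipid_height,
    phosphate_indices,
    reference_plane,
)
from .structio import Frame, Structure, StructureError, Trajectory

__all__ = [
    "DEFAULT_BIN_EDGES",
    "LiftHistogram",
    "MoundRecord",
    "ExtractionTrace",
    "lipids_of",
    "tunnel_region",
    "lift_histogram",
    "detect_mound",
    "track_extracted",
]

#: Six 1 Å bins from 10 to 16 Å above the phosphate plane.
DEFAULT_BIN_EDGES = np.arange(10.0, 17.0, 1.0)


@dataclass
class LiftHistogram:
    """Aggregated counts of lifted lipids per 1 Å height bin."""

    bin_edges: np.ndarray          # length 7: [10, 11, ..., 16]
    counts: np.ndarray             # length 6, summed over frames
    per_frame: np.ndarray          # (n_frames, 6)
    n_frames: int

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must be one longer than counts")

    def to_tsv(self) -> str:
        lines = ["bin_lo\tbin_hi\tcount"]
        for lo, hi, c in zip(self.bin_edges[:-1], self.bin_edges[1:], self.counts):
            lines.append(f"{lo:g}\t{hi:g}\t{int(c)}")
        return "\n".join(lines) + "\n"


@dataclass
class MoundRecord:
    """A cluster of lifted lipids in one frame."""

    frame_index: int
    members: list[LipidID]
    mean_height: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ExtractionTrace:
    """The extracted lipid's per-frame height and nearest gateway residue."""

    lipid: LipidID
    frame_indices: list[int]
    dz: list[float]
    nearest_gateway: list[tuple[str, int]]
    n_lifted_frames: int


def lipids_of(topology: Structure, residue_name: str = "POPC") -> list[LipidID]:
    """All lipid residues (by residue name) in the topology."""
    out = []
    for (chain, resnum), indices in topology.residue_particle_indices().items():
        if topology.particles[indices[0]].residue_name == residue_name:
            out.append((chain, resnum))
    return sorted(out)


def tunnel_region(
    frame: Frame,
    topology: Structure,
    lipids: Sequence[LipidID],
    center_particle_indices: Sequence[int],
    lateral_radius_A: float = 15.0,
    phosphate_name: str = "PO4",
) -> list[LipidID]:
    """Lipids whose phosphate lies laterally within ``lateral_radius_A`` of
    the centroid of the given particles (typically the TMD helices)."""
    centroid = frame.positions[list(center_particle_indices), :2].mean(axis=0)
    pidx = phosphate_indices(topology, lipids, phosphate_name)
    out = []
    for lipid in lipids:
        xy = frame.positions[pidx[lipid], :2]
        if np.linalg.norm(xy - centroid) <= lateral_radius_A:
            out.append(lipid)
    return sorted(out)


def _planes(
    traj: Trajectory,
    lipids: Sequence[LipidID],
    phosphate_name: str,
    exclusion_height_A: float | None,
) -> list[MembranePlane]:
    planes = []
    for i, frame in enumerate(traj.frames):
        assignment = assign_leaflets(frame, traj.topology, lipids, phosphate_name, frame_index=i)
        planes.append(
            reference_plane(frame, traj.topology, assignment, phosphate_name, exclusion_height_A)
        )
    return planes


def lift_histogram(
    traj: Trajectory,
    selection: Sequence[LipidID] | Callable[[int, Frame], Sequence[LipidID]] | None = None,
    frame_window: Sequence[int] | None = None,
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
    phosphate_name: str = "PO4",
    lateral_radius_A: float = 15.0,
    center_particle_indices: Sequence[int] | None = None,
    exclusion_height_A: float | None = 10.0,
) -> LiftHistogram:
    """Count lifted lipids per height bin across a frame window.

    ``selection`` may be an explicit lipid list, a callable
    ``(frame_index, frame) -> lipids``, or ``None`` for the default
    tunnel-region selection (phosphate within ``lateral_radius_A`` of the
    protein-particle centroid; requires ``center_particle_indices`` or a
    protein chain to infer them from).
    """
    all_lipids = lipids_of(traj.topology)
    if not all_lipids:
        raise StructureError("no lipids in topology")
    window = list(range(len(traj))) if frame_window is None else list(frame_window)
    if not window:
        raise ValueError("frame window is empty")

    if selection is None:
        if center_particle_indices is None:
            center_particle_indices = [
                i for i, p in enumerate(traj.topology.particles)
                if p.residue_name != "POPC"
            ]
            if not center_particle_indices:
                raise StructureError("no protein particles to centre the tunnel region on")

        def selection(i: int, frame: Frame) -> Sequence[LipidID]:
            return tunnel_region(frame, traj.topology, all_lipids,
                                 center_particle_indices, lateral_radius_A, phosphate_name)

    bin_edges = np.asarray(bin_edges, dtype=float)
    per_frame = np.zeros((len(window), len(bin_edges) - 1), dtype=int)
    pidx_all = phosphate_indices(traj.topology, all_lipids, phosphate_name)
    planes = {}
    for row, i in enumerate(window):
        frame = traj.frames[i]
        assignment = assign_leaflets(frame, traj.topology, all_lipids, phosphate_name, frame_index=i)
        plane = reference_plane(frame, traj.topology, assignment, phosphate_name, exclusion_height_A)
        planes[i] = plane
        selected = selection(i, frame) if callable(selection) else selection
        if len(selected) == 0:
            raise ValueError(f"frame {i}: empty lipid selection")
        dz = np.array([frame.positions[pidx_all[l], 2] - plane.z0 for l in selected])
        # half-open bins [k, k+1): np.histogram's last bin would be closed,
        # so clip exact right-edge hits out explicitly
        in_range = (dz >= bin_edges[0]) & (dz < bin_edges[-1])
        per_frame[row], _ = np.histogram(dz[in_range], bins=bin_edges)
    return LiftHistogram(
        bin_edges=bin_edges,
        counts=per_frame.sum(axis=0),
        per_frame=per_frame,
        n_frames=len(window),
    )


def detect_mound(
    frame: Frame,
    topology: Structure,
    plane: MembranePlane,
    lipids: Sequence[LipidID] | None = None,
    min_height_A: float = 10.0,
    lateral_radius_A: float = 10.0,
    min_size: int = 3,
    frame_index: int = 0,
    phosphate_name: str = "PO4",
) -> MoundRecord | None:
    """Largest single-linkage cluster of lifted lipids, or ``None``.

    Lipids with Δz >= ``min_height_A`` are clustered by single linkage on
    their x/y phosphate positions at ``lateral_radius_A``; the largest
    cluster is returned if it has at least ``min_size`` members.  Absence of
    a mound is a valid result, not an error.
    """
    if lipids is None:
        lipids = lipids_of(topology)
    pidx = phosphate_indices(topology, lipids, phosphate_name)
    lifted = [l for l in lipids if frame.positions[pidx[l], 2] - plane.z0 >= min_height_A]
    if not lifted:
        return None
    xy = np.array([frame.positions[pidx[l], :2] for l in lifted])
    tree = cKDTree(xy)
    pairs = tree.query_pairs(lateral_radius_A, output_type="ndarray")
    n = len(lifted)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])) if len(pairs) else
        ((), ((), ())),
        shape=(n, n),
    )
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = int(sizes.argmax())
    if sizes[best] < min_size:
        return None
    members = sorted(l for l, lab in zip(lifted, labels) if lab == best)
    heights = [frame.positions[pidx[l], 2] - plane.z0 for l in members]
    return MoundRecord(frame_index=frame_index, members=members,
                       mean_height=float(np.mean(heights)))


def track_extracted(
    traj: Trajectory,
    gateway: ResidueSet,
    min_height_A: float = 10.0,
    frame_window: Sequence[int] | None = None,
    phosphate_name: str = "PO4",
    exclusion_height_A: float | None = 10.0,
) -> ExtractionTrace | None:
    """Trace the single extracted lipid, or ``None`` if nothing lifts.

    The lipid with the most frames at Δz >= ``min_height_A`` wins; ties are
    broken by larger mean Δz.  For every frame the nearest gateway residue
    (minimum particle-pair distance to any lipid particle) is recorded.
    """
    lipids = lipids_of(traj.topology)
    window = list(range(len(traj))) if frame_window is None else list(frame_window)
    pidx = phosphate_indices(traj.topology, lipids, phosphate_name)
    planes = {}
    dz = np.empty((len(window), len(lipids)))
    for row, i in enumerate(window):
        frame = traj.frames[i]
        assignment = assign_leaflets(frame, traj.topology, lipids, phosphate_name, frame_index=i)
        plane = reference_plane(frame, traj.topology, assignment, phosphate_name, exclusion_height_A)
        planes[i] = plane
        dz[row] = [frame.positions[pidx[l], 2] - plane.z0 for l in lipids]
    lifted_frames = (dz >= min_height_A).sum(axis=0)
    if lifted_frames.max() == 0:
        return None
    best_count = lifted_frames.max()
    tied = np.flatnonzero(lifted_frames == best_count)
    winner = int(tied[np.argmax(dz[:, tied].mean(axis=0))])
    lipid = lipids[winner]

    res_idx = traj.topology.residue_particle_indices()
    gw_members = sorted(gateway.members)
    gw_rows = [res_idx[m] for m in gw_members]
    lipid_rows = res_idx[lipid]
    nearest = []
    for row, i in enumerate(window):
        lp = traj.frames[i].positions[lipid_rows]
        dmins = [
            float(np.min(np.linalg.norm(
                traj.frames[i].positions[rows][:, None, :] - lp[None, :, :], axis=-1)))
            for rows in gw_rows
        ]
        nearest.append(gw_members[int(np.argmin(dmins))])
    return ExtractionTrace(
        lipid=lipid,
        frame_indices=window,
        dz=dz[:, winner].tolist(),
        nearest_gateway=nearest,
        n_lifted_frames=int(best_count),
    )
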