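"""Seeded synthetic bilayer + gateway trajectories with planted ground truth.

The generator emulates the *statistical structure* that the analysis stages
assume — two flat leaflets of 12-bead POPC-like lipids, a pseudo-protein
whose gateway loop carries author numbering (564-592), Bernoulli salt-bridge
contact schedules, and a z-lift schedule for one extracted lipid — without
any physical dynamics (no forces, no thermostat; simulation engines are out
of scope here).  Every planted event is recorded in a machine-readable
:class:`GroundTruth`, so each analysis stage can be tested against what was
actually planted.

Geometry guarantees (the *guard band*): on a planted contact frame the
moiety bead is placed 4-5 Å from the residue's side-chain bead (inside the
6 Å salt-bridge cutoff); on a non-contact frame 9-12 Å away (outside an 8 Å
guard), so positional noise of sigma <= 0.5 Å can never flip a planted label.
Planted residues are laid out at least ~14 Å apart so a bead planted on one
residue cannot create a spurious contact with another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .membrane import LipidID
from .structio import Frame, Particle, Structure, Trajectory

__all__ = [
    "ContactPlan",
    "SyntheticSpec",
    "GroundTruth",
    "build_bilayer",
    "simulate",
    "write_truth",
    "load_truth",
    "ladder_spec",
    "occupancy_spec",
    "flat_spec",
]

LIPID_CHAIN = "L"
PROTEIN_CHAIN = "A"
#: 12-bead pseudo-POPC: choline, phosphate, two glycerols, eight tail beads.
LIPID_BEADS = ("NC3", "PO4", "GL1", "GL2",
               "C1A", "C2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B")
#: Bead offsets relative to the phosphate, upper leaflet (head up), Å.
_BEAD_OFFSETS = {
    "NC3": (0.0, 0.0, 2.0), "PO4": (0.0, 0.0, 0.0),
    "GL1": (0.0, 0.0, -2.0), "GL2": (0.8, 0.0, -3.0),
    "C1A": (0.5, 0.3, -5.0), "C2A": (0.5, 0.3, -8.0),
    "C3A": (0.5, 0.3, -11.0), "C4A": (0.5, 0.3, -14.0),
    "C1B": (-0.5, -0.3, -5.0), "C2B": (-0.5, -0.3, -8.0),
    "C3B": (-0.5, -0.3, -11.0), "C4B": (-0.5, -0.3, -14.0),
}

GATEWAY_RANGE = range(564, 593)
#: Codes for the gateway pseudo-protein: the 11 charged residues plus the
#: aromatic cluster and G572; everything else alanine.
_GATEWAY_CODES = {
    564: "GLU", 565: "ARG", 568: "LYS", 570: "LYS", 571: "ASP", 575: "ASP",
    579: "ARG", 581: "ASP", 584: "GLU", 585: "ASP", 587: "ARG",
    572: "GLY", 573: "TYR", 574: "TRP", 583: "PHE", 590: "TRP",
}
_TMD_RESIDUES = range(900, 908)

_GRID_SPACING = 8.0  # Å between lipid grid slots


@dataclass(frozen=True)
class ContactPlan:
    """A planted salt-bridge schedule for one (residue, moiety) pair.

    Either ``p`` (independent Bernoulli draw per frame) or ``frames`` (an
    explicit frame set) drives the schedule.  ``lipid`` selects whether a
    dedicated mound lipid or the single extracted lipid carries the moiety.
    ``z_above_plane`` positions the residue's side-chain bead that high above
    the upper-leaflet surface.
    """

    residue_number: int
    moiety: Literal["choline", "phosphate"]
    p: float | None = None
    frames: tuple[int, ...] | None = None
    lipid: Literal["dedicated", "extracted"] = "dedicated"
    z_above_plane: float = 12.0

    def __post_init__(self) -> None:
        if (self.p is None) == (self.frames is None):
            raise ValueError("exactly one of p / frames must be given")
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"contact probability must be in [0, 1], got {self.p}")
        if self.moiety not in ("choline", "phosphate"):
            raise ValueError(f"unknown moiety {self.moiety!r}")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic trajectory.

    Defaults are the desk-scale study conditions: 128 lipids, 1000 frames
    saved every 5 ns, positional noise sigma 0.5 Å.  ``paper_scale=True``
    selects the full-size system (792 lipids, 2000 frames of a 10 µs run).
    """

    n_lipids: int = 128
    box_xy: float | None = None
    leaflet_gap: float = 38.0
    noise_sigma: float = 0.5
    n_frames: int = 1000
    frame_stride_ns: float = 5.0
    seed: int = 0
    planted_contacts: tuple[ContactPlan, ...] = ()
    #: (start_frame, stop_frame_exclusive, target Δz in Å) for the extracted lipid.
    lift_schedule: tuple[tuple[int, int, float], ...] = ()
    #: plant a membrane mound: this many lipids held ``mound_height`` Å above
    #: the surface, laterally clustered on a 5 Å circle at the tunnel axis.
    #: The default height sits at the top of the observed 10-12 Å band so
    #: sigma-level noise cannot push a member below the 10 Å detection floor.
    mound_lipids: int = 0
    mound_height: float = 12.0

    def __post_init__(self) -> None:
        if self.n_lipids % 2 != 0 or self.n_lipids < 2:
            raise ValueError("n_lipids must be even and >= 2")
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        for start, stop, dz in self.lift_schedule:
            if dz < 0:
                raise ValueError(f"lift schedule Δz must be >= 0, got {dz}")
            if not 0 <= start < stop:
                raise ValueError(f"bad lift window ({start}, {stop})")
        if self.mound_lipids < 0 or self.mound_height < 0:
            raise ValueError("mound_lipids and mound_height must be >= 0")

    @property
    def per_leaflet(self) -> int:
        return self.n_lipids // 2

    @property
    def grid_side(self) -> int:
        return math.ceil(math.sqrt(self.per_leaflet))

    @property
    def resolved_box_xy(self) -> float:
        return self.box_xy if self.box_xy is not None else self.grid_side * _GRID_SPACING

    def validate_box(self) -> None:
        if self.resolved_box_xy < self.grid_side * _GRID_SPACING - 1e-9:
            raise ValueError(
                f"box_xy={self.resolved_box_xy:.1f} Å too small for "
                f"{self.n_lipids} lipids at {_GRID_SPACING:.0f} Å spacing"
            )


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    leaflet_labels: dict[LipidID, str]
    extracted_lipid: LipidID | None
    #: key "<resnum>:<moiety>" -> per-frame planted contact indicator
    contacts: dict[str, list[bool]]
    #: dedicated lipid carrying each planted pair (same keys as ``contacts``)
    contact_lipids: dict[str, LipidID]
    true_dz: list[float] | None
    plane_z0: list[float]
    n_frames: int
    mound_members: list[LipidID] = field(default_factory=list)


def _gateway_layout(spec: SyntheticSpec) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Base positions (BB, SC) per gateway residue.

    Planted residues sit on an inner circle (radius 16 Å) at equal angles —
    mutually >= ~14 Å apart — at their requested height above the upper
    leaflet; the rest of the loop arcs along an outer circle (radius 22 Å).
    """
    cx = cy = spec.resolved_box_xy / 2.0
    z_upper = spec.leaflet_gap / 2.0
    planted = sorted({pl.residue_number for pl in spec.planted_contacts})
    heights = {
        pl.residue_number: pl.z_above_plane for pl in spec.planted_contacts
    }
    layout: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if planted:
        step = 2 * math.pi / len(planted)
        min_sep = 2 * 16.0 * math.sin(step / 2.0) if len(planted) > 1 else np.inf
        if min_sep < 14.0:
            raise ValueError(
                f"{len(planted)} planted residues cannot be separated by >= 14 Å "
                "on the gateway layout; plant fewer residues"
            )
        for k, resnum in enumerate(planted):
            ang = k * step
            z = z_upper + heights[resnum]
            sc = np.array([cx + 16.0 * math.cos(ang), cy + 16.0 * math.sin(ang), z])
            bb = np.array([cx + 19.0 * math.cos(ang), cy + 19.0 * math.sin(ang), z + 1.0])
            layout[resnum] = (bb, sc)
    # non-planted loop residues arc along an outer circle, high enough
    # (>= 14 Å above the leaflet) that resting lipid headgroups can never
    # reach the 6 Å contact cutoff
    others = [r for r in GATEWAY_RANGE if r not in layout]
    for k, resnum in enumerate(others):
        ang = k * 2 * math.pi / len(others)
        z = z_upper + 14.0 + 0.3 * k
        sc = np.array([cx + 21.0 * math.cos(ang), cy + 21.0 * math.sin(ang), z])
        bb = np.array([cx + 22.0 * math.cos(ang), cy + 22.0 * math.sin(ang), z + 1.0])
        layout[resnum] = (bb, sc)
    return layout


def _grid_slots(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered (per_leaflet, 2) xy grid, sorted by distance to the box centre."""
    side = spec.grid_side
    spacing = spec.resolved_box_xy / side
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    slots = np.stack([(xs + 0.5) * spacing, (ys + 0.5) * spacing], axis=-1).reshape(-1, 2)
    slots = slots[: spec.per_leaflet]
    slots = slots + rng.uniform(-0.5, 0.5, size=slots.shape)
    centre = np.array([spec.resolved_box_xy / 2.0] * 2)
    order = np.argsort(np.linalg.norm(slots - centre, axis=1), kind="stable")
    return slots[order]


def _special_lipids(
    spec: SyntheticSpec,
) -> tuple[LipidID | None, dict[str, LipidID], list[LipidID]]:
    """Extracted lipid, contact-plan carriers, and mound members."""
    extracted = (LIPID_CHAIN, 1) if (spec.lift_schedule or any(
        pl.lipid == "extracted" for pl in spec.planted_contacts)) else None
    carriers: dict[str, LipidID] = {}
    next_resnum = 2
    for pl in spec.planted_contacts:
        key = f"{pl.residue_number}:{pl.moiety}"
        if pl.lipid == "extracted":
            if extracted is None:
                raise ValueError("extracted-lipid contact plan without lift schedule")
            carriers[key] = extracted
        else:
            if next_resnum > spec.per_leaflet:
                raise ValueError("not enough upper-leaflet lipids for planted contacts")
            carriers[key] = (LIPID_CHAIN, next_resnum)
            next_resnum += 1
    mound: list[LipidID] = []
    for _ in range(spec.mound_lipids):
        if next_resnum > spec.per_leaflet:
            raise ValueError("not enough upper-leaflet lipids for the planted mound")
        mound.append((LIPID_CHAIN, next_resnum))
        next_resnum += 1
    return extracted, carriers, mound


def build_bilayer(spec: SyntheticSpec) -> Structure:
    """Deterministic base geometry: bilayer grid plus gateway pseudo-protein.

    Lipid residues 1..n/2 form the upper leaflet, n/2+1..n the lower one.
    Residue 1 (closest grid slot to the centre) is the extracted lipid when
    a lift schedule is planted; the following residues carry the dedicated
    contact plans and sit directly beneath their residues' side chains.
    """
    spec.validate_box()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed).spawn(2)[0]))
    slots = _grid_slots(spec, rng)
    z_upper = spec.leaflet_gap / 2.0
    cx = cy = spec.resolved_box_xy / 2.0
    layout = _gateway_layout(spec)
    _, carriers, mound = _special_lipids(spec)
    carrier_xy = {
        lipid: layout[int(key.split(":")[0])][1][:2]
        for key, lipid in carriers.items()
        if lipid[1] != 1
    }
    # mound members sit on a 5 Å circle at the tunnel axis: pairwise <= 10 Å,
    # so single linkage at the default radius keeps them one cluster
    for k, lipid in enumerate(mound):
        ang = k * 2 * math.pi / max(len(mound), 1)
        carrier_xy[lipid] = np.array([cx + 5.0 * math.cos(ang), cy + 5.0 * math.sin(ang)])

    particles: list[Particle] = []
    pid = 0
    for leaflet, z_sign in (("upper", +1), ("lower", -1)):
        for k in range(spec.per_leaflet):
            resnum = k + 1 if leaflet == "upper" else spec.per_leaflet + k + 1
            xy = slots[k]
            if leaflet == "upper" and (LIPID_CHAIN, resnum) in carrier_xy:
                xy = carrier_xy[(LIPID_CHAIN, resnum)]
            for bead in LIPID_BEADS:
                dx, dy, dz = _BEAD_OFFSETS[bead]
                # mirror in z for the lower leaflet (heads point down)
                z = z_upper + dz if z_sign > 0 else -z_upper - dz
                pos = np.array([xy[0] + dx, xy[1] + dy, z])
                particles.append(Particle(pid, bead, resnum, "POPC", LIPID_CHAIN, pos))
                pid += 1
    # TMD anchor beads: a pseudo-helix bundle at the box centre spanning the
    # membrane; they define the tunnel centroid for lateral lipid selection.
    for i, resnum in enumerate(_TMD_RESIDUES):
        ang = i * 2 * math.pi / len(_TMD_RESIDUES)
        pos = np.array([cx + 4.0 * math.cos(ang), cy + 4.0 * math.sin(ang),
                        -10.0 + 20.0 * i / (len(_TMD_RESIDUES) - 1)])
        particles.append(Particle(pid, "BB", resnum, "ALA", PROTEIN_CHAIN, pos))
        pid += 1
    for resnum in GATEWAY_RANGE:
        bb, sc = layout[resnum]
        code3 = _GATEWAY_CODES.get(resnum, "ALA")
        particles.append(Particle(pid, "BB", resnum, code3, PROTEIN_CHAIN, bb))
        pid += 1
        if code3 != "GLY":
            particles.append(Particle(pid, "SC1", resnum, code3, PROTEIN_CHAIN, sc))
            pid += 1
    box = np.array([spec.resolved_box_xy, spec.resolved_box_xy, spec.leaflet_gap + 60.0])
    return Structure(particles, box=box)


def _dz_targets(spec: SyntheticSpec) -> np.ndarray:
    dz = np.zeros(spec.n_frames)
    for start, stop, target in spec.lift_schedule:
        dz[start:min(stop, spec.n_frames)] = target
    return dz


def simulate(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate the trajectory and its ground truth.

    Per frame: lipid beads = base + N(0, sigma) noise; the extracted lipid is
    rigidly shifted by the scheduled Δz; each planted (residue, moiety, p)
    pair draws an independent Bernoulli(p) and places the moiety bead 4-5 Å
    (success) or 9-12 Å (failure) from the residue's side-chain bead.
    Identical seeds give identical output.
    """
    topology = build_bilayer(spec)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed).spawn(2)[1]))
    F = spec.n_frames
    N = len(topology)
    base = topology.positions
    cx = cy = spec.resolved_box_xy / 2.0

    n_lipid_particles = spec.n_lipids * len(LIPID_BEADS)
    pos = np.broadcast_to(base, (F, N, 3)).copy()
    pos[:, :n_lipid_particles, :] += rng.normal(0.0, spec.noise_sigma, (F, n_lipid_particles, 3))

    extracted, carriers, mound = _special_lipids(spec)
    res_idx = topology.residue_particle_indices()

    dz = _dz_targets(spec)
    if extracted is not None:
        lift_rows = res_idx[extracted]
        pos[:, lift_rows, 2] += dz[:, None]
    for lipid in mound:
        pos[:, res_idx[lipid], 2] += spec.mound_height

    # Planted contacts: override moiety bead positions exactly (no extra
    # noise, so the 6 Å / >8 Å guard band holds deterministically).  Several
    # plans may share one bead (the extracted lipid's choline climbing the
    # ladder) as long as their success frames never overlap.
    contacts: dict[str, np.ndarray] = {}
    slots: dict[tuple[LipidID, str], list[ContactPlan]] = {}
    for pl in spec.planted_contacts:
        key = f"{pl.residue_number}:{pl.moiety}"
        slots.setdefault((carriers[key], pl.moiety), []).append(pl)
    for (lipid, moiety), plans in slots.items():
        bead_name = "NC3" if moiety == "choline" else "PO4"
        bead_row = topology.index_of(lipid[0], lipid[1], bead_name)
        success_any = np.zeros(F, dtype=bool)
        for pl in plans:
            key = f"{pl.residue_number}:{pl.moiety}"
            sc = base[topology.index_of(PROTEIN_CHAIN, pl.residue_number, "SC1")]
            inward = np.array([cx, cy, sc[2]]) - sc
            inward /= np.linalg.norm(inward)
            if pl.p is not None:
                success = rng.random(F) < pl.p
            else:
                success = np.zeros(F, dtype=bool)
                success[[f for f in pl.frames if f < F]] = True
            clash = success & success_any
            if clash.any():
                raise ValueError(
                    f"conflicting contact plans for lipid {lipid} moiety {moiety} "
                    f"at frame {int(np.flatnonzero(clash)[0])}"
                )
            success_any |= success
            dist = 4.0 + rng.uniform(0.0, 1.0, F)
            pos[success, bead_row, :] = (
                sc[None, :] + inward[None, :] * dist[:, None]
            )[success]
            contacts[key] = success
        idle = ~success_any
        if idle.any():
            if len(plans) == 1:
                # stay 9-12 Å from the single planted residue, inward
                sc = base[topology.index_of(PROTEIN_CHAIN, plans[0].residue_number, "SC1")]
                inward = np.array([cx, cy, sc[2]]) - sc
                inward /= np.linalg.norm(inward)
                dist = 9.0 + rng.uniform(0.0, 3.0, F)
                pos[idle, bead_row, :] = (sc[None, :] + inward[None, :] * dist[:, None])[idle]
            else:
                # neutral park position on the tunnel axis, >= 8 Å from every
                # planted residue (planted residues sit at radius 16)
                park = np.array([cx, cy, spec.leaflet_gap / 2.0 + 2.0])
                pos[idle, bead_row, :] = park[None, :] + rng.normal(0.0, 0.3, (F, 3))[idle]

    # ground-truth reference plane: clean upper phosphates
    # (no extracted lipid, no plan carriers, no mound members)
    special = {extracted} | set(carriers.values()) | set(mound)
    clean_rows = [
        topology.index_of(LIPID_CHAIN, r, "PO4")
        for r in range(1, spec.per_leaflet + 1)
        if (LIPID_CHAIN, r) not in special
    ]
    if not clean_rows:
        raise ValueError("no clean upper-leaflet lipids left for the reference plane")
    plane_z0 = pos[:, clean_rows, 2].mean(axis=1) if F else np.zeros(0)

    true_dz = None
    if extracted is not None and F:
        ext_phos = topology.index_of(extracted[0], extracted[1], "PO4")
        true_dz = (pos[:, ext_phos, 2] - plane_z0).tolist()

    frames = [
        Frame(time_ns=i * spec.frame_stride_ns, positions=pos[i], box=topology.box)
        for i in range(F)
    ]
    labels: dict[LipidID, str] = {}
    for r in range(1, spec.n_lipids + 1):
        labels[(LIPID_CHAIN, r)] = "upper" if r <= spec.per_leaflet else "lower"
    truth = GroundTruth(
        leaflet_labels=labels,
        extracted_lipid=extracted,
        contacts={k: v.tolist() for k, v in contacts.items()},
        contact_lipids=carriers,
        true_dz=true_dz,
        plane_z0=plane_z0.tolist(),
        n_frames=F,
        mound_members=mound,
    )
    return Trajectory(topology, frames), truth


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write ground truth as JSON (loadable by :func:`load_truth`)."""
    payload = {
        "n_frames": truth.n_frames,
        "leaflet_labels": {f"{c}:{r}": lab for (c, r), lab in truth.leaflet_labels.items()},
        "extracted_lipid": None if truth.extracted_lipid is None
        else list(truth.extracted_lipid),
        "contacts": {k: [bool(b) for b in v] for k, v in truth.contacts.items()},
        "contact_lipids": {k: list(v) for k, v in truth.contact_lipids.items()},
        "true_dz": truth.true_dz,
        "plane_z0": truth.plane_z0,
        "mound_members": [list(m) for m in truth.mound_members],
    }
    Path(path).write_text(json.dumps(payload))


def load_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        leaflet_labels={
            (k.split(":")[0], int(k.split(":")[1])): v
            for k, v in payload["leaflet_labels"].items()
        },
        extracted_lipid=None if payload["extracted_lipid"] is None
        else (payload["extracted_lipid"][0], int(payload["extracted_lipid"][1])),
        contacts=payload["contacts"],
        contact_lipids={k: (v[0], int(v[1])) for k, v in payload["contact_lipids"].items()},
        true_dz=payload["true_dz"],
        plane_z0=payload["plane_z0"],
        n_frames=payload["n_frames"],
        mound_members=[(m[0], int(m[1])) for m in payload.get("mound_members", [])],
    )


# ---------------------------------------------------------------------------
# Presets: the study conditions used throughout the tests and examples
# ---------------------------------------------------------------------------

def occupancy_spec(
    seed: int = 0,
    n_frames: int = 1000,
    n_lipids: int = 128,
    p_k568_phosphate: float = 0.77,
    p_d571_choline: float = 0.39,
) -> SyntheticSpec:
    """Bernoulli contact schedules for the two headline occupancies.

    K568 binds the lipid phosphate 77% of frames and D571 the choline 39% —
    the wild-type gateway statistics the occupancy estimator must recover.
    """
    return SyntheticSpec(
        n_lipids=n_lipids,
        n_frames=n_frames,
        seed=seed,
        planted_contacts=(
            ContactPlan(568, "phosphate", p=p_k568_phosphate),
            ContactPlan(571, "choline", p=p_d571_choline),
        ),
    )


def ladder_spec(seed: int = 0, n_frames: int = 400, n_lipids: int = 64) -> SyntheticSpec:
    """The sequential-extraction ladder: one lipid climbs 10/12/15/17 Å while
    forming successive salt bridges with D571, D575, E584 and D585."""
    if n_frames < 40:
        raise ValueError("ladder preset needs at least 40 frames")
    edges = [round(f * n_frames) for f in (0.125, 0.375, 0.625, 0.825, 1.0)]
    heights = (10.0, 12.0, 15.0, 17.0)
    residues = (571, 575, 584, 585)
    windows = [
        (res, edges[i], edges[i + 1], heights[i])
        for i, res in enumerate(residues)
    ]
    plans = tuple(
        ContactPlan(res, "choline", frames=tuple(range(a, b)),
                    lipid="extracted", z_above_plane=dzt)
        for res, a, b, dzt in windows
    )
    schedule = tuple((a, b, dzt) for _, a, b, dzt in windows)
    return SyntheticSpec(
        n_lipids=n_lipids, n_frames=n_frames, seed=seed,
        planted_contacts=plans, lift_schedule=schedule,
    )


def mound_spec(
    seed: int = 0,
    n_frames: int = 200,
    n_lipids: int = 64,
    n_mound: int = 5,
    height: float = 12.0,
) -> SyntheticSpec:
    """A planted membrane mound: ``n_mound`` lipids held ~10-12 Å above the
    surface, laterally clustered inside the outward-open cavity."""
    return SyntheticSpec(
        n_lipids=n_lipids, n_frames=n_frames, seed=seed,
        mound_lipids=n_mound, mound_height=height,
    )


def flat_spec(seed: int = 0, n_frames: int = 200, n_lipids: int = 64) -> SyntheticSpec:
    """A flat bilayer with nothing planted: the fully charge-neutralised
    (11CmutA-like) null condition — no salt bridges, no extraction."""
    return SyntheticSpec(n_lipids=n_lipids, n_frames=n_frames, seed=seed)


def paper_scale_spec(seed: int = 0) -> SyntheticSpec:
    """Full-size preset: 792 lipids, 2000 frames saved every 5 ns (10 µs)."""
    return occupancy_spec(seed=seed, n_frames=2000, n_lipids=792)
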