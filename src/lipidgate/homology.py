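"""Template-based model building by threading and least-clash rotamers.

The procedure models one ABCA transporter on the backbone of a homologous
structure in a different conformational state (the motivating case: ABCA1
threaded onto ATP-bound ABCA4 to obtain the outward-closed state):

1. a pairwise alignment maps target residues onto template residues;
   target insertions without a template counterpart are dropped;
2. the template backbone is copied *verbatim* (aligned Cα positions are
   template positions, exactly) and renumbered to the target;
3. at substituted positions, the target side chain is rebuilt from a small
   rotamer library, choosing the candidate with the fewest steric clashes
   against the rest of the model (ties go to library order);
4. conformational readouts (Cα distances, aperture changes between two
   models) quantify the resulting state, e.g. the I74-I371 separation of
   the annulus-orifice helices.

Energy minimisation and loop building are out of scope; residues without a
template counterpart are omitted and listed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import rotamers
from .domains import THREE_TO_ONE
from .structio import Particle, Structure, StructureError

__all__ = [
    "AlignmentMap",
    "RotamerCandidate",
    "ThreadedModel",
    "map_alignment",
    "thread_backbone",
    "place_side_chain",
    "place_all_side_chains",
    "ca_distance",
    "aperture_change",
    "clash_report_tsv",
]

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
_BACKBONE = ("N", "CA", "C", "O")


@dataclass
class AlignmentMap:
    """Residue-number pairing between target and template sequences."""

    pairs: list[tuple[int, int]]                 # (target_resnum, template_resnum)
    dropped_target_insertions: list[int]

    def __post_init__(self) -> None:
        tmpl = [t for _, t in self.pairs]
        if any(b <= a for a, b in zip(tmpl, tmpl[1:])):
            raise ValueError("template residue numbers must be strictly increasing")
        tgt = [t for t, _ in self.pairs]
        if len(set(tgt)) != len(tgt):
            raise ValueError("a target residue is mapped twice")

    def target_of(self) -> dict[int, int]:
        return {tmpl: tgt for tgt, tmpl in self.pairs}


@dataclass
class RotamerCandidate:
    residue: tuple[str, int]
    chis: tuple[float, ...]
    positions: dict[str, np.ndarray]
    clash_count: int


@dataclass
class ThreadedModel:
    """Target sequence on template backbone, with rotamer bookkeeping."""

    structure: Structure
    substitutions: list[tuple[str, int]]          # target numbering, side chain pending
    dropped_target_insertions: list[int]
    unaligned_template: list[tuple[str, int]]
    chosen: dict[tuple[str, int], RotamerCandidate] = field(default_factory=dict)

    @property
    def pending(self) -> list[tuple[str, int]]:
        return [r for r in self.substitutions if r not in self.chosen]


def _read_aligned_fasta(source: str | Path) -> tuple[str, str]:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(source), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 aligned sequences, found {len(records)}")
    return str(records[0].seq).upper(), str(records[1].seq).upper()


def map_alignment(
    alignment: str | Path | tuple[str, str],
    target_numbering: Sequence[int] | None = None,
    template_numbering: Sequence[int] | None = None,
) -> AlignmentMap:
    """Column-walk a 2-sequence alignment (target first, template second).

    Columns occupied in both rows become pairs; target-only columns are
    recorded as dropped insertions (they have no template backbone to sit
    on); template-only columns are skipped.  Numbering defaults to 1..n over
    the ungapped residues of each row.
    """
    if isinstance(alignment, tuple):
        target, template = alignment
    else:
        target, template = _read_aligned_fasta(alignment)
    if len(target) != len(template):
        raise ValueError(
            f"aligned lengths differ: target {len(target)} vs template {len(template)}"
        )
    n_tgt = sum(1 for c in target if c != "-")
    n_tmpl = sum(1 for c in template if c != "-")
    tgt_nums = list(range(1, n_tgt + 1)) if target_numbering is None else list(target_numbering)
    tmpl_nums = list(range(1, n_tmpl + 1)) if template_numbering is None else list(template_numbering)
    if len(tgt_nums) != n_tgt or len(tmpl_nums) != n_tmpl:
        raise ValueError("numbering length must equal the ungapped sequence length")
    pairs: list[tuple[int, int]] = []
    dropped: list[int] = []
    it, jt = 0, 0
    for a, b in zip(target, template):
        if a != "-" and b != "-":
            pairs.append((tgt_nums[it], tmpl_nums[jt]))
        elif a != "-":
            dropped.append(tgt_nums[it])
        if a != "-":
            it += 1
        if b != "-":
            jt += 1
    return AlignmentMap(pairs=pairs, dropped_target_insertions=dropped)


def thread_backbone(
    template: Structure,
    amap: AlignmentMap,
    target_sequence: Mapping[int, str],
    chain_id: str = "A",
) -> ThreadedModel:
    """Copy the template backbone onto the target numbering.

    Aligned residues keep their template backbone coordinates exactly;
    identical residues keep the full template side chain; substitutions are
    left with bare backbone and flagged for rotamer placement.  Template
    residues outside the alignment are omitted and listed.
    """
    tmpl_residues = template.residue_particle_indices()
    tmpl_by_num: dict[int, tuple[str, int]] = {}
    for (c, r) in tmpl_residues:
        tmpl_by_num.setdefault(r, (c, r))
    particles: list[Particle] = []
    substitutions: list[tuple[str, int]] = []
    pid = 0
    aligned_tmpl: set[tuple[str, int]] = set()
    for tgt_num, tmpl_num in amap.pairs:
        if tmpl_num not in tmpl_by_num:
            continue  # aligned residue not resolved in the template structure
        key = tmpl_by_num[tmpl_num]
        aligned_tmpl.add(key)
        rows = tmpl_residues[key]
        names = {template.particles[i].name for i in rows}
        is_cg = "BB" in names
        backbone_names = ("BB",) if is_cg else _BACKBONE
        missing = [n for n in backbone_names if n not in names and n != "O"]
        if missing:
            raise StructureError(
                f"template residue {key} lacks backbone particles {missing}"
            )
        tmpl_code = THREE_TO_ONE.get(template.particles[rows[0]].residue_name, "X")
        tgt_code = target_sequence[tgt_num].upper()
        identical = tgt_code == tmpl_code
        new_resname = ONE_TO_THREE.get(tgt_code, "UNK")
        for i in rows:
            p = template.particles[i]
            if p.name in backbone_names or p.name == "O" or identical:
                particles.append(Particle(pid, p.name, tgt_num,
                                          new_resname if not identical else p.residue_name,
                                          chain_id, p.position))
                pid += 1
        if not identical:
            substitutions.append((chain_id, tgt_num))
    unaligned = sorted(set(tmpl_residues) - aligned_tmpl)
    structure = Structure(particles, box=template.box)
    return ThreadedModel(
        structure=structure,
        substitutions=substitutions,
        dropped_target_insertions=list(amap.dropped_target_insertions),
        unaligned_template=unaligned,
    )


def place_side_chain(
    model: ThreadedModel,
    residue: tuple[str, int],
    clash_cutoff_A: float = 2.5,
    library: Mapping[str, list[tuple[float, ...]]] | None = None,
) -> RotamerCandidate:
    """Choose and install the least-clash rotamer for one substitution.

    The clash count of a candidate is the number of (candidate side-chain
    atom, other-residue atom) pairs closer than ``clash_cutoff_A``; the
    candidate with the minimum count wins, ties broken by library order.
    The model structure is updated in place with the chosen side chain.
    """
    if residue not in model.substitutions:
        raise ValueError(f"residue {residue} is not flagged as a substitution")
    struct = model.structure
    rows = struct.particles_of(*residue)
    res_name = struct.particles[rows[0]].residue_name
    try:
        backbone = {n: struct.positions[struct.index_of(residue[0], residue[1], n)]
                    for n in ("N", "CA", "C")}
    except StructureError:
        raise StructureError(
            f"residue {residue}: all-atom backbone (N, CA, C) required for "
            "rotamer placement"
        ) from None
    chis_list = (library[res_name] if library is not None
                 else rotamers.rotamer_chis(res_name))
    if not chis_list:
        raise ValueError(f"empty rotamer library for type {res_name}")

    own = set(rows)
    other_pos = np.array([p.position for i, p in enumerate(struct.particles)
                          if i not in own])
    tree = cKDTree(other_pos) if len(other_pos) else None
    best: RotamerCandidate | None = None
    for chis in chis_list:
        positions = rotamers.build_side_chain(res_name, backbone, chis)
        if positions and tree is not None:
            pts = np.array(list(positions.values()))
            clashes = sum(len(hits) for hits in tree.query_ball_point(pts, clash_cutoff_A))
        else:
            clashes = 0
        if best is None or clashes < best.clash_count:
            best = RotamerCandidate(residue, tuple(chis), positions, int(clashes))
            if clashes == 0:
                break  # no candidate can do better; library order tie-break holds
    assert best is not None

    # install: drop any previously placed side chain, append the new one
    keep = [p for i, p in enumerate(struct.particles)
            if i not in own or p.name in ("N", "CA", "C", "O", "BB")]
    particles = [Particle(i, p.name, p.residue_number, p.residue_name, p.chain_id, p.position)
                 for i, p in enumerate(keep)]
    pid = len(particles)
    for name, pos in best.positions.items():
        particles.append(Particle(pid, name, residue[1], res_name, residue[0], pos))
        pid += 1
    model.structure = Structure(particles, box=struct.box)
    model.chosen[residue] = best
    return best


def place_all_side_chains(
    model: ThreadedModel,
    clash_cutoff_A: float = 2.5,
    library: Mapping[str, list[tuple[float, ...]]] | None = None,
) -> dict[tuple[str, int], RotamerCandidate]:
    """Place every pending substitution, in residue order."""
    for residue in sorted(model.pending, key=lambda r: r[1]):
        place_side_chain(model, residue, clash_cutoff_A, library)
    return model.chosen


def ca_distance(
    structure: Structure,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
) -> float:
    """Euclidean Cα-Cα (or backbone-bead) distance in Å."""
    def _ca(res: tuple[str, int]) -> np.ndarray:
        for name in ("CA", "BB"):
            try:
                return structure.particles[structure.index_of(res[0], res[1], name)].position
            except StructureError:
                continue
        raise StructureError(f"residue {res} has no CA or BB particle")

    return float(np.linalg.norm(_ca(residue_a) - _ca(residue_b)))


def aperture_change(
    model_a: Structure,
    model_b: Structure,
    residue_pair: tuple[tuple[str, int], tuple[str, int]],
) -> float:
    """Signed Cα-distance change of a residue pair between two models.

    Positive means the pair moved apart in ``model_b`` — e.g. the two
    annulus-orifice helices opening on ATP binding.
    """
    ra, rb = residue_pair
    return ca_distance(model_b, ra, rb) - ca_distance(model_a, ra, rb)


def clash_report_tsv(model: ThreadedModel) -> str:
    """Per-substitution rotamer choice as TSV (residue, chis, clashes, n)."""
    lines = ["chain\tresnum\tres_name\tchis_deg\tclash_count\tn_candidates"]
    for residue in sorted(model.chosen, key=lambda r: r[1]):
        cand = model.chosen[residue]
        rows = model.structure.particles_of(*residue)
        res_name = model.structure.particles[rows[0]].residue_name
        chis = ",".join(f"{c:g}" for c in cand.chis) or "-"
        n = len(rotamers.rotamer_chis(res_name))
        lines.append(f"{residue[0]}\t{residue[1]}\t{res_name}\t{chis}\t{cand.clash_count}\t{n}")
    return "\n".join(lines) + "\n"
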