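"""Structural domains of the ABCA1 lipid-export pathway.

ABCA1 extracts phospholipid from the outer membrane leaflet through a series
of named domains: the *gateway* (a 29-residue charged loop, residues
564-592, of extracellular domain 1), the *annulus* (the ring of
tunnel-lining residues within 10 Å of any gateway residue: 69, 71-80, 363,
368-379), and the *annulus orifice* (the small central opening of the
annulus).  This module represents such domains as residue sets, derives the
proximity-defined ones from coordinates, and computes residue-class censuses
(basic/acidic/aromatic/... composition) of any set.

The tunnel-lining residue set is an *input* (it comes from a cavity-detection
tool upstream); only the proximity derivation is performed here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure, StructureError

__all__ = [
    "ResidueSet",
    "DEFAULT_SCHEME",
    "THREE_TO_ONE",
    "GATEWAY",
    "ANNULUS",
    "ORIFICE_FIG1",
    "ORIFICE_RESULTS",
    "CHARGED_GATEWAY",
    "CHARGED_GATEWAY_CODES",
    "parse_range_string",
    "classify_residue",
    "census",
    "derive_proximity_domain",
    "union_size",
    "intramembrane_basic_census",
]

# 1-letter -> class.  Chosen so that the 11 charged gateway residues split
# 5 basic / 6 acidic, and histidine counts as neutral (it is tallied
# separately from the basic cluster census of flippase TMDs).
DEFAULT_SCHEME: dict[str, str] = {
    "K": "basic", "R": "basic",
    "D": "acidic", "E": "acidic",
    "F": "aromatic", "W": "aromatic", "Y": "aromatic",
    "P": "proline",
    "G": "glycine",
    "A": "hydrophobic", "V": "hydrophobic", "L": "hydrophobic",
    "I": "hydrophobic", "M": "hydrophobic", "C": "hydrophobic",
    "S": "neutral", "T": "neutral", "N": "neutral", "Q": "neutral",
    "H": "neutral",
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

CLASSES = ("basic", "acidic", "aromatic", "hydrophobic", "proline", "glycine", "neutral")


@dataclass(frozen=True)
class ResidueSet:
    """A named set of (chain_id, residue_number) members."""

    name: str
    members: frozenset[tuple[str, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: tuple[str, int]) -> bool:
        return item in self.members

    def __or__(self, other: "ResidueSet") -> "ResidueSet":
        return ResidueSet(f"{self.name}|{other.name}", self.members | other.members)

    def __and__(self, other: "ResidueSet") -> "ResidueSet":
        return ResidueSet(f"{self.name}&{other.name}", self.members & other.members)

    def issubset(self, other: "ResidueSet") -> bool:
        return self.members <= other.members

    def residue_numbers(self) -> list[int]:
        return sorted(r for _, r in self.members)

    def to_tsv(self) -> str:
        lines = ["chain\tresnum"]
        lines += [f"{c}\t{r}" for c, r in sorted(self.members)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, name: str, text: str) -> "ResidueSet":
        members = set()
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            chain, resnum = line.split("\t")
            members.add((chain, int(resnum)))
        return cls(name, frozenset(members))


def parse_range_string(spec: str, chain_id: str = "A", name: str = "") -> ResidueSet:
    """Parse a compact range string such as ``"564-592;69;71-80"``."""
    members: set[tuple[str, int]] = set()
    for token in spec.split(";"):
        token = token.strip()
        if not token:
            continue
        if "-" in token:
            lo, hi = token.split("-")
            members.update((chain_id, r) for r in range(int(lo), int(hi) + 1))
        else:
            members.add((chain_id, int(token)))
    return ResidueSet(name or spec, frozenset(members))


# Named presets, author numbering on chain "A".
GATEWAY = parse_range_string("564-592", name="gateway")
ANNULUS = parse_range_string("69;71-80;363;368-379", name="annulus")
#: Orifice membership is reported in two variants in the source structure
#: description; both are shipped and neither is canonical.
ORIFICE_FIG1 = parse_range_string("73-75;77;78;371;375", name="orifice_fig1")
ORIFICE_RESULTS = parse_range_string("73-74;77;371;375", name="orifice_results")

#: The 11 charged gateway residues, with their amino-acid codes.
CHARGED_GATEWAY_CODES: dict[int, str] = {
    564: "E", 565: "R", 568: "K", 570: "K", 571: "D", 575: "D",
    579: "R", 581: "D", 584: "E", 585: "D", 587: "R",
}
CHARGED_GATEWAY = ResidueSet(
    "charged_gateway", frozenset(("A", r) for r in CHARGED_GATEWAY_CODES)
)


def classify_residue(code: str, scheme: Mapping[str, str] = DEFAULT_SCHEME) -> str:
    """Class of a 1-letter amino-acid code under a residue-class scheme."""
    code = code.upper()
    if code not in scheme:
        raise KeyError(f"nonstandard amino-acid code {code!r}")
    return scheme[code]


def census(
    residues: ResidueSet,
    sequence: Mapping[tuple[str, int], str] | Mapping[int, str],
    scheme: Mapping[str, str] = DEFAULT_SCHEME,
) -> Counter:
    """Count residues of a set per class.

    ``sequence`` maps residue identifiers to 1-letter codes; plain residue
    numbers are accepted when chains are unambiguous.  The counts always
    partition the set.
    """
    counts: Counter = Counter({c: 0 for c in CLASSES})
    for chain, resnum in residues.members:
        code = None
        if (chain, resnum) in sequence:          # type: ignore[operator]
            code = sequence[(chain, resnum)]     # type: ignore[index]
        elif resnum in sequence:                 # type: ignore[operator]
            code = sequence[resnum]              # type: ignore[index]
        if code is None:
            raise KeyError(f"no amino-acid code for residue {chain}/{resnum}")
        counts[classify_residue(code, scheme)] += 1
    return counts


def union_size(a: ResidueSet, b: ResidueSet) -> int:
    """|a ∪ b| — e.g. gateway ∪ annulus is the 53-residue export complex."""
    return len(a.members | b.members)


def derive_proximity_domain(
    structure: Structure,
    source: ResidueSet,
    candidates: ResidueSet,
    cutoff_A: float = 10.0,
    name: str | None = None,
) -> ResidueSet:
    """Candidate residues with any particle within ``cutoff_A`` of the source.

    This is the operation that defines the annulus: tunnel-lining residues
    within 10 Å of any gateway residue.  All particles of a residue
    participate, not just backbone, and the result is deterministic.
    """
    res_idx = structure.residue_particle_indices()
    for rs in (source, candidates):
        missing = [m for m in rs.members if m not in res_idx]
        if missing:
            raise StructureError(f"residues not in structure: {sorted(missing)}")
    pos = structure.positions
    src_indices = [i for m in source.members for i in res_idx[m]]
    tree = cKDTree(pos[src_indices])
    kept: set[tuple[str, int]] = set()
    for member in candidates.members:
        cand_pos = pos[res_idx[member]]
        dmin = tree.query(cand_pos, k=1)[0].min()
        if dmin <= cutoff_A:
            kept.add(member)
    return ResidueSet(name or f"{candidates.name}@{cutoff_A:g}A_of_{source.name}", frozenset(kept))


def intramembrane_basic_census(
    structure: Structure,
    z_lower: float,
    z_upper: float,
    scheme: Mapping[str, str] = DEFAULT_SCHEME,
) -> tuple[Counter, dict[str, list[tuple[str, int]]]]:
    """Residue-class counts for residues with any particle inside a z slab.

    Used to ask whether a transporter carries charged residues in the middle
    of its transmembrane domain (flippases do; ABCA1 does not).  Returns the
    per-class counts and the residue identities per class.  An empty slab
    yields zero counts.
    """
    if z_lower > z_upper:
        raise ValueError(f"slab bounds out of order: [{z_lower}, {z_upper}]")
    counts: Counter = Counter({c: 0 for c in CLASSES})
    identities: dict[str, list[tuple[str, int]]] = {c: [] for c in CLASSES}
    for member, indices in structure.residue_particle_indices().items():
        res_name = structure.particles[indices[0]].residue_name
        code = THREE_TO_ONE.get(res_name)
        if code is None:
            continue  # lipids / non-protein residues are not censused
        zs = np.array([structure.particles[i].position[2] for i in indices])
        if np.any((zs >= z_lower) & (zs <= z_upper)):
            cls = classify_residue(code, scheme)
            counts[cls] += 1
            identities[cls].append(member)
    for v in identities.values():
        v.sort()
    return counts, identities
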