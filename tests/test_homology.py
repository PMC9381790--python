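"""Alignment mapping, backbone threading, rotamer placement, Cα metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidgate import homology, rotamers
from lipidgate.homology import (
    AlignmentMap,
    aperture_change,
    ca_distance,
    map_alignment,
    place_all_side_chains,
    place_side_chain,
    thread_backbone,
)
from lipidgate.structio import Particle, Structure
from lipidgate.toyfold import ideal_helix, ideal_strand


# ---------------------------------------------------------------------------
# alignment mapping
# ---------------------------------------------------------------------------

def test_template_insertion_is_skipped():
    amap = map_alignment(("AK-L", "AKML"))
    assert amap.pairs == [(1, 1), (2, 2), (3, 4)]
    assert amap.dropped_target_insertions == []


def test_target_insertion_is_dropped():
    amap = map_alignment(("AKML", "AK-L"))
    assert amap.pairs == [(1, 1), (2, 2), (4, 3)]
    assert amap.dropped_target_insertions == [3]


def test_identity_alignment_maps_everything():
    n = 17
    seq = "A" * n
    amap = map_alignment((seq, seq))
    assert amap.pairs == [(i, i) for i in range(1, n + 1)]
    assert amap.dropped_target_insertions == []


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="lengths differ"):
        map_alignment(("AK", "AKL"))


def test_duplicate_target_mapping_rejected():
    with pytest.raises(ValueError, match="twice"):
        AlignmentMap(pairs=[(1, 1), (1, 2)], dropped_target_insertions=[])


@settings(max_examples=30, deadline=None)
@given(st.lists(st.sampled_from(["MM", "M-", "-M"]), min_size=1, max_size=30))
def test_alignment_round_trip_reconstructs_kept_columns(cols):
    target = "".join(c[0] for c in cols)
    template = "".join(c[1] for c in cols)
    amap = map_alignment((target, template))
    # rebuild the both-occupied columns from the map
    tgt_nums = [i + 1 for i, c in enumerate(t for t in target if t != "-")]
    kept = [(t, m) for t, m in amap.pairs]
    expect = []
    it = jt = 0
    for a, b in zip(target, template):
        ti = it + 1 if a != "-" else None
        tj = jt + 1 if b != "-" else None
        if a != "-":
            it += 1
        if b != "-":
            jt += 1
        if ti and tj:
            expect.append((ti, tj))
    assert kept == expect
    assert len(amap.dropped_target_insertions) == sum(
        1 for a, b in zip(target, template) if a != "-" and b == "-")


def test_aligned_fasta_is_read(tmp_path):
    p = tmp_path / "aln.fasta"
    p.write_text(">target\nAKML\n>template\nAK-L\n")
    amap = map_alignment(p)
    assert amap.pairs == [(1, 1), (2, 2), (4, 3)]


# ---------------------------------------------------------------------------
# threading
# ---------------------------------------------------------------------------

def test_identity_threading_reproduces_template_exactly():
    seq = "AKLAVELAKG"
    tmpl = ideal_helix(seq, chain_id="T")
    amap = map_alignment((seq, seq))
    model = thread_backbone(tmpl, amap, {i + 1: c for i, c in enumerate(seq)})
    assert model.substitutions == []
    np.testing.assert_array_equal(model.structure.positions, tmpl.positions)


def test_single_substitution_keeps_backbone_and_flags_residue():
    tmpl_seq = "AALAA"
    tgt_seq = "AAVAA"
    tmpl = ideal_helix(tmpl_seq, chain_id="T")
    amap = map_alignment((tgt_seq, tmpl_seq))
    model = thread_backbone(tmpl, amap, {i + 1: c for i, c in enumerate(tgt_seq)})
    assert model.substitutions == [("A", 3)]
    for name in ("N", "CA", "C", "O"):
        a = model.structure.particles[model.structure.index_of("A", 3, name)].position
        b = tmpl.particles[tmpl.index_of("T", 3, name)].position
        np.testing.assert_array_equal(a, b)


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_threading_never_moves_aligned_backbone(seed):
    rng = np.random.default_rng(seed)
    codes = "ACDEFGHIKLMNPQRSTVWY"
    tmpl_seq = "".join(rng.choice(list(codes), 8))
    tgt_seq = "".join(rng.choice(list(codes), 8))
    tmpl = ideal_strand(tmpl_seq, chain_id="T")
    amap = map_alignment((tgt_seq, tmpl_seq))
    model = thread_backbone(tmpl, amap, {i + 1: c for i, c in enumerate(tgt_seq)})
    for i in range(1, 9):
        for name in ("N", "CA", "C"):
            a = model.structure.particles[model.structure.index_of("A", i, name)].position
            b = tmpl.particles[tmpl.index_of("T", i, name)].position
            assert np.array_equal(a, b)


def test_unaligned_template_residues_are_omitted_and_listed():
    tmpl = ideal_helix("AKLAV", chain_id="T")
    amap = map_alignment(("AKL--", "AKLAV"))
    model = thread_backbone(tmpl, amap, {1: "A", 2: "K", 3: "L"})
    assert model.unaligned_template == [("T", 4), ("T", 5)]
    assert ("A", 4) not in model.structure.residue_particle_indices()


# ---------------------------------------------------------------------------
# rotamer placement
# ---------------------------------------------------------------------------

def _oracle_clashes(struct: Structure, residue, positions, cutoff=2.5) -> int:
    own = set(struct.particles_of(*residue))
    count = 0
    for pos in positions.values():
        for i, p in enumerate(struct.particles):
            if i in own:
                continue
            if np.linalg.norm(p.position - pos) < cutoff:
                count += 1
    return count


def test_isolated_residue_takes_first_library_rotamer():
    tmpl = ideal_strand("GAG", chain_id="T")  # glycines leave V unobstructed
    amap = map_alignment(("GVG", "GAG"))
    model = thread_backbone(tmpl, amap, {1: "G", 2: "V", 3: "G"})
    cand = place_side_chain(model, ("A", 2))
    assert cand.clash_count == 0
    assert cand.chis == rotamers.rotamer_chis("VAL")[0]


def test_planted_obstruction_forces_other_rotamer():
    tmpl = ideal_strand("GAG", chain_id="T")
    amap = map_alignment(("GSG", "GAG"))
    target = {1: "G", 2: "S", 3: "G"}

    def _with_blocker(chi):
        model = thread_backbone(tmpl, amap, target)
        bb = {n: model.structure.positions[model.structure.index_of("A", 2, n)]
              for n in ("N", "CA", "C")}
        og = rotamers.build_side_chain("SER", bb, (chi,))["OG"]
        parts = list(model.structure.particles)
        parts.append(Particle(len(parts), "X", 999, "UNK", "Z", og))
        model.structure = Structure(parts)
        return model

    first_chi = rotamers.rotamer_chis("SER")[0][0]
    model = _with_blocker(first_chi)  # blocker sits exactly on the rotamer-1 OG
    # OG positions of adjacent rotamers are only ~2.4 Å apart, so use a
    # tighter overlap cutoff that penalises rotamer 1 alone
    cand = place_side_chain(model, ("A", 2), clash_cutoff_A=1.0)
    assert cand.chis[0] != first_chi
    assert cand.clash_count == 0


@pytest.mark.parametrize("res", ["SER", "LEU", "PHE", "LYS", "ARG", "TRP"])
def test_chosen_rotamer_is_argmin_of_oracle(res):
    rng = np.random.default_rng(hash(res) % 2**31)
    code1 = {"SER": "S", "LEU": "L", "PHE": "F", "LYS": "K", "ARG": "R", "TRP": "W"}[res]
    for trial in range(5):
        tmpl = ideal_strand("GAG", chain_id="T")
        amap = map_alignment((f"G{code1}G", "GAG"))
        model = thread_backbone(tmpl, amap, {1: "G", 2: code1, 3: "G"})
        # scatter random obstruction atoms near the residue
        parts = list(model.structure.particles)
        ca = model.structure.positions[model.structure.index_of("A", 2, "CA")]
        for k in range(6):
            parts.append(Particle(len(parts), "X", 900 + k, "UNK", "Z",
                                  ca + rng.uniform(-5, 5, 3)))
        model.structure = Structure(parts)
        cand = place_side_chain(model, ("A", 2))
        # exhaustive oracle over the full library, on the pre-placement model
        pre = thread_backbone(tmpl, amap, {1: "G", 2: code1, 3: "G"})
        pre_parts = list(pre.structure.particles)
        for k in range(6):
            pre_parts.append(parts[len(parts) - 6 + k])
        pre_struct = Structure(pre_parts)
        bb = {n: pre_struct.positions[pre_struct.index_of("A", 2, n)]
              for n in ("N", "CA", "C")}
        best = min(
            _oracle_clashes(pre_struct, ("A", 2),
                            rotamers.build_side_chain(res, bb, chis))
            for chis in rotamers.rotamer_chis(res)
        )
        assert cand.clash_count == best


def test_place_all_side_chains_clears_pending():
    tmpl = ideal_helix("AAAAA", chain_id="T")
    amap = map_alignment(("AKLSA", "AAAAA"))
    model = thread_backbone(tmpl, amap, {1: "A", 2: "K", 3: "L", 4: "S", 5: "A"})
    place_all_side_chains(model)
    assert model.pending == []
    assert set(model.chosen) == {("A", 2), ("A", 3), ("A", 4)}


# ---------------------------------------------------------------------------
# Cα metrics
# ---------------------------------------------------------------------------

def _two_ca(d):
    return Structure([
        Particle(0, "CA", 74, "ILE", "A", np.zeros(3)),
        Particle(1, "CA", 371, "ILE", "A", np.array([d, 0.0, 0.0])),
    ])


def test_ca_distance_same_residue_is_zero():
    s = _two_ca(5.0)
    assert ca_distance(s, ("A", 74), ("A", 74)) == 0.0


def test_ca_distance_three_four_five():
    s = Structure([
        Particle(0, "CA", 1, "ALA", "A", np.zeros(3)),
        Particle(1, "CA", 2, "ALA", "A", np.array([3.0, 4.0, 0.0])),
    ])
    assert ca_distance(s, ("A", 1), ("A", 2)) == pytest.approx(5.0)


def test_aperture_change_between_closed_and_open_states():
    closed, open_ = _two_ca(8.1), _two_ca(13.8)
    assert aperture_change(closed, open_, (("A", 74), ("A", 371))) == pytest.approx(5.7)
    assert aperture_change(closed, closed, (("A", 74), ("A", 371))) == 0.0
    assert aperture_change(open_, closed, (("A", 74), ("A", 371))) == pytest.approx(-5.7)


def test_dihedral_and_place_atom_are_consistent():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a, b, c = rng.uniform(-5, 5, (3, 3))
        want = float(rng.uniform(-179, 179))
        d = rotamers.place_atom(a, b, c, 1.5, 109.5, want)
        assert rotamers.dihedral(a, b, c, d) == pytest.approx(want, abs=1e-6)
        assert np.linalg.norm(d - c) == pytest.approx(1.5, abs=1e-9)
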