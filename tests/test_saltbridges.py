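"""Salt-bridge contacts, occupancy statistics, and the extraction ladder."""

import dataclasses
import itertools

import numpy as np
import pytest

from lipidgate.domains import CHARGED_GATEWAY, GATEWAY, ResidueSet
from lipidgate.lift import track_extracted
from lipidgate.saltbridges import (
    MOIETY_BEADS,
    contacts_in_frame,
    ladder,
    occupancy,
    pool_replicas,
    side_chain_indices,
)
from lipidgate.structio import Frame, Particle, Structure, StructureError, Trajectory
from lipidgate.synth import ContactPlan, SyntheticSpec, ladder_spec, simulate


def _toy_system(d_choline: float, d_phosphate: float = 20.0) -> tuple[Structure, Frame]:
    """One ASP side-chain bead at origin; lipid moiety beads at given distances."""
    particles = [
        Particle(0, "BB", 571, "ASP", "A", np.array([0.0, 0.0, 5.0])),
        Particle(1, "SC1", 571, "ASP", "A", np.zeros(3)),
        Particle(2, "NC3", 1, "POPC", "L", np.array([d_choline, 0.0, 0.0])),
        Particle(3, "PO4", 1, "POPC", "L", np.array([0.0, d_phosphate, 0.0])),
    ]
    s = Structure(particles)
    return s, Frame(0.0, s.positions)


def test_contact_at_5p9_angstrom():
    topo, frame = _toy_system(5.9)
    got = contacts_in_frame(frame, topo, ("L", 1), ResidueSet("r", frozenset({("A", 571)})))
    assert [(c.residue, c.moiety) for c in got] == [(("A", 571), "choline")]
    assert got[0].min_distance == pytest.approx(5.9)


def test_no_contact_at_6p1_angstrom():
    topo, frame = _toy_system(6.1)
    got = contacts_in_frame(frame, topo, ("L", 1), ResidueSet("r", frozenset({("A", 571)})))
    assert got == []


def test_glycine_in_residue_set_is_error():
    traj, _ = simulate(SyntheticSpec(n_lipids=4, n_frames=1, seed=0))
    gly = ResidueSet("g", frozenset({("A", 572)}))  # G572 has no side-chain bead
    with pytest.raises(StructureError, match="572"):
        contacts_in_frame(traj.frames[0], traj.topology, ("L", 1), gly)


def _random_frame(rng, n_res=10):
    particles = []
    pid = 0
    for r in range(n_res):
        for name in ("BB", "SC1", "SC2"):
            particles.append(Particle(pid, name, 100 + r, "GLU", "A",
                                      rng.uniform(0, 25, 3)))
            pid += 1
    for name in ("NC3", "PO4"):
        particles.append(Particle(pid, name, 1, "POPC", "L", rng.uniform(0, 25, 3)))
        pid += 1
    topo = Structure(particles)
    return topo, Frame(0.0, topo.positions)


def _oracle_contacts(topo, frame, lipid, residues, cutoff):
    """O(N^2) scan over every (side-chain particle, moiety particle) pair."""
    hits = set()
    for residue in residues.members:
        sc = [i for i in topo.particles_of(*residue)
              if topo.particles[i].name not in ("BB",)]
        for moiety, names in (("choline", MOIETY_BEADS["choline"]),
                              ("phosphate", MOIETY_BEADS["phosphate"])):
            mrows = [i for i in topo.particles_of(*lipid)
                     if topo.particles[i].name in names]
            for i, j in itertools.product(sc, mrows):
                d = np.linalg.norm(frame.positions[i] - frame.positions[j])
                if d <= cutoff:
                    hits.add((residue, moiety))
    return hits


def test_contacts_match_brute_force_oracle_on_random_frames():
    rng = np.random.default_rng(20)
    residues = ResidueSet("r", frozenset(("A", 100 + r) for r in range(10)))
    for _ in range(30):
        topo, frame = _random_frame(rng)
        got = {(c.residue, c.moiety)
               for c in contacts_in_frame(frame, topo, ("L", 1), residues)}
        assert got == _oracle_contacts(topo, frame, ("L", 1), residues, 6.0)


def test_planted_zero_probability_gives_zero_occupancy():
    spec = SyntheticSpec(n_lipids=16, n_frames=50, seed=2,
                         planted_contacts=(ContactPlan(568, "phosphate", p=0.0),))
    traj, _ = simulate(spec)
    tab = occupancy(traj, CHARGED_GATEWAY)
    assert (tab["occupancy"] == 0).all()


def test_occupancy_recovers_planted_schedule_exactly():
    # deterministic frame plants: occupancy is a frame count, recovered exactly
    frames = tuple(range(0, 30))
    spec = SyntheticSpec(n_lipids=16, n_frames=60, seed=3,
                         planted_contacts=(ContactPlan(571, "choline", frames=frames),))
    traj, truth = simulate(spec)
    tab = occupancy(traj, CHARGED_GATEWAY)
    row = tab[(tab.replica == "pooled") & (tab.resnum == 571) & (tab.moiety == "choline")]
    assert float(row.occupancy.iloc[0]) == pytest.approx(0.5)
    assert int(row.n_contact_frames.iloc[0]) == sum(truth.contacts["571:choline"])


def test_pooled_occupancy_is_frame_weighted_mean():
    def _rep(seed, n_contact, n_frames):
        spec = SyntheticSpec(
            n_lipids=16, n_frames=n_frames, seed=seed,
            planted_contacts=(ContactPlan(568, "phosphate",
                                          frames=tuple(range(n_contact))),))
        return simulate(spec)[0]

    reps = [_rep(0, 60, 100), _rep(1, 90, 100)]
    tab = occupancy(reps, ResidueSet("k", frozenset({("A", 568)})))
    by = tab[(tab.resnum == 568) & (tab.moiety == "phosphate")].set_index("replica")
    assert by.loc["0", "occupancy"] == pytest.approx(0.6)
    assert by.loc["1", "occupancy"] == pytest.approx(0.9)
    assert by.loc["pooled", "occupancy"] == pytest.approx(0.75)


def test_occupancy_invariant_to_frame_order_within_window():
    spec = SyntheticSpec(n_lipids=16, n_frames=40, seed=5,
                         planted_contacts=(ContactPlan(568, "phosphate", p=0.6),))
    traj, _ = simulate(spec)
    rset = ResidueSet("k", frozenset({("A", 568)}))
    fwd = occupancy(traj, rset, frame_window=list(range(40)))
    rng = np.random.default_rng(0)
    perm = rng.permutation(40).tolist()
    shuf = occupancy(traj, rset, frame_window=perm)
    f = fwd[fwd.replica == "pooled"].sort_values(["resnum", "moiety"]).occupancy.tolist()
    s = shuf[shuf.replica == "pooled"].sort_values(["resnum", "moiety"]).occupancy.tolist()
    assert f == s


def test_occupancy_estimator_nearly_unbiased_over_seeds():
    p = 0.6
    n_frames = 400
    errs = []
    for seed in range(10):
        spec = SyntheticSpec(n_lipids=8, n_frames=n_frames, seed=seed,
                             planted_contacts=(ContactPlan(568, "phosphate", p=p),))
        traj, _ = simulate(spec)
        tab = occupancy(traj, ResidueSet("k", frozenset({("A", 568)})))
        row = tab[(tab.replica == "pooled") & (tab.moiety == "phosphate")]
        errs.append(float(row.occupancy.iloc[0]) - p)
    assert abs(np.mean(errs)) < 2 * np.sqrt(p * (1 - p) / (n_frames * 10))


def test_ladder_reproduces_planted_onsets_in_order():
    traj, _ = simulate(ladder_spec(seed=11))
    trace = track_extracted(traj, GATEWAY)
    rep = ladder(trace, traj)
    assert [r for _, r in [(s.residue[0], s.residue[1]) for s in rep.steps]] == \
           [571, 575, 584, 585]
    for step, target in zip(rep.steps, (10.0, 12.0, 15.0, 17.0)):
        assert step.dz_at_onset == pytest.approx(target, abs=1.5)
    assert rep.matches_expected_order
    assert rep.absent == []


def test_ladder_flags_absent_residues_when_nothing_planted():
    spec = SyntheticSpec(n_lipids=32, n_frames=50, seed=12,
                         lift_schedule=((0, 50, 12.0),))
    traj, _ = simulate(spec)
    trace = track_extracted(traj, GATEWAY)
    rep = ladder(trace, traj)
    assert rep.steps == []
    assert len(rep.absent) == 4
    assert not rep.matches_expected_order


def test_ladder_out_of_order_plant_is_reported_and_flagged():
    # E584 contacts before D575
    base = ladder_spec(seed=13)
    plans = []
    for pl in base.planted_contacts:
        if pl.residue_number == 575:
            plans.append(dataclasses.replace(pl, residue_number=584))
        elif pl.residue_number == 584:
            plans.append(dataclasses.replace(pl, residue_number=575))
        else:
            plans.append(pl)
    spec = dataclasses.replace(base, planted_contacts=tuple(plans))
    traj, _ = simulate(spec)
    trace = track_extracted(traj, GATEWAY)
    rep = ladder(trace, traj)
    assert [s.residue[1] for s in rep.steps] == [571, 584, 575, 585]
    assert not rep.matches_expected_order


def test_side_chain_indices_cg_excludes_backbone():
    traj, _ = simulate(SyntheticSpec(n_lipids=4, n_frames=1, seed=0))
    rows = side_chain_indices(traj.topology, ("A", 568))
    assert all(traj.topology.particles[i].name == "SC1" for i in rows)
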