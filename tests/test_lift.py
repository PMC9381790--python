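"""Lift histogram, mound detection, and extraction tracking."""

import dataclasses

import numpy as np
import pytest

from lipidgate.domains import GATEWAY
from lipidgate.lift import (
    DEFAULT_BIN_EDGES,
    detect_mound,
    lift_histogram,
    lipids_of,
    track_extracted,
    tunnel_region,
)
from lipidgate.membrane import MembranePlane, assign_leaflets, reference_plane
from lipidgate.synth import (
    SyntheticSpec,
    flat_spec,
    ladder_spec,
    mound_spec,
    simulate,
)

from conftest import make_lipid_sheet, sheet_frames


def _flat_sheet_with(extra: dict[int, float]) -> dict[int, float]:
    """A flat reference sheet plus upper-leaflet extras.

    One lower-leaflet lipid is added per extra so the leaflets stay balanced
    (the median split assumes equally populated monolayers).
    """
    base = {101: 20.0, 102: 20.0, 103: 20.0}
    base.update({111 + i: -20.0 for i in range(3 + len(extra))})
    base.update(extra)
    return base


def test_histogram_counts_single_lifted_lipid():
    zs = _flat_sheet_with({1: 30.5})  # Δz = 10.5 for 3 frames
    traj = sheet_frames([zs, zs, zs])
    h = lift_histogram(traj, selection=[("L", 1)])
    assert h.counts.tolist() == [3, 0, 0, 0, 0, 0]
    assert h.n_frames == 3


def test_histogram_half_open_boundaries_exclude_9p9_and_16():
    zs = _flat_sheet_with({1: 29.9, 2: 36.0})  # Δz = 9.9 and 16.0
    traj = sheet_frames([zs])
    h = lift_histogram(traj, selection=[("L", 1), ("L", 2)], exclusion_height_A=5.0)
    assert h.counts.sum() == 0


def test_histogram_has_six_one_angstrom_bins():
    assert len(DEFAULT_BIN_EDGES) == 7
    np.testing.assert_allclose(np.diff(DEFAULT_BIN_EDGES), 1.0)
    assert DEFAULT_BIN_EDGES[0] == 10.0 and DEFAULT_BIN_EDGES[-1] == 16.0


def test_histogram_matches_oracle_binning_of_planted_ladder():
    # noise-free plant: measured heights equal the planted schedule exactly
    spec = dataclasses.replace(ladder_spec(seed=6, n_frames=100), noise_sigma=0.0)
    traj, truth = simulate(spec)
    h = lift_histogram(traj, selection=[truth.extracted_lipid])
    oracle = [0] * 6
    for dz in truth.true_dz:
        if 10.0 <= dz < 16.0:
            oracle[int(dz - 10.0)] += 1
    assert h.counts.tolist() == oracle


def test_histogram_total_bounded_by_frames_times_selection():
    traj, truth = simulate(ladder_spec(seed=2, n_frames=80))
    h = lift_histogram(traj, selection=[truth.extracted_lipid])
    assert h.counts.sum() <= h.n_frames * 1


def test_histogram_empty_selection_is_error():
    traj, _ = simulate(flat_spec(seed=0, n_frames=2, n_lipids=8))
    with pytest.raises(ValueError, match="empty"):
        lift_histogram(traj, selection=[])


def test_tunnel_region_selects_lipids_near_centroid():
    traj, _ = simulate(flat_spec(seed=0, n_frames=1, n_lipids=64))
    topo = traj.topology
    centre_rows = [i for i, p in enumerate(topo.particles) if p.residue_name != "POPC"]
    near = tunnel_region(traj.frames[0], topo, lipids_of(topo), centre_rows, 15.0)
    allsel = tunnel_region(traj.frames[0], topo, lipids_of(topo), centre_rows, 1e6)
    assert 0 < len(near) < len(allsel) == 64


def _plane(traj, frame_index=0):
    lipids = lipids_of(traj.topology)
    frame = traj.frames[frame_index]
    asg = assign_leaflets(frame, traj.topology, lipids, frame_index=frame_index)
    return reference_plane(frame, traj.topology, asg)


def test_no_lifted_lipids_no_mound():
    traj, _ = simulate(flat_spec(seed=1, n_frames=1))
    assert detect_mound(traj.frames[0], traj.topology, _plane(traj)) is None


def test_planted_five_lipid_mound_recovered():
    traj, truth = simulate(mound_spec(seed=3, n_frames=1, n_mound=5))
    rec = detect_mound(traj.frames[0], traj.topology, _plane(traj))
    assert rec is not None
    assert rec.size == 5
    assert sorted(rec.members) == sorted(truth.mound_members)
    assert rec.mean_height == pytest.approx(12.0, abs=1.0)


def test_distant_lifted_lipids_form_singletons():
    # two lifted lipids 40 Å apart laterally
    zs = _flat_sheet_with({})
    topo_zs = dict(zs)
    traj = sheet_frames([topo_zs])
    topo = traj.topology
    frame = traj.frames[0]
    pos = frame.positions.copy()
    # lift lipids 101 and 103 (grid x = 0 and 16) and separate them to 40 Å
    order = sorted(topo_zs)
    i101, i103 = order.index(101), order.index(103)
    pos[i101, :] = [0.0, 0.0, 31.0]
    pos[i103, :] = [40.0, 0.0, 31.0]
    frame = dataclasses.replace(frame, positions=pos)
    plane = MembranePlane(frame_index=0, z0=20.0, n_lipids=3)
    rec = detect_mound(frame, topo, plane, lateral_radius_A=10.0, min_size=3)
    assert rec is None
    rec1 = detect_mound(frame, topo, plane, lateral_radius_A=10.0, min_size=1)
    assert rec1 is not None and rec1.size == 1


def test_track_extracted_identifies_planted_lipid():
    traj, truth = simulate(ladder_spec(seed=7, n_frames=120))
    trace = track_extracted(traj, GATEWAY)
    assert trace is not None
    assert trace.lipid == truth.extracted_lipid


def test_track_extracted_prefers_longer_lift():
    # lipid 1 lifted 70 frames, lipid 2 lifted 30 frames
    series = []
    for t in range(100):
        zs = _flat_sheet_with({1: 32.0 if t < 70 else 20.0,
                               2: 32.0 if t < 30 else 20.0})
        series.append(zs)
    traj = sheet_frames(series)
    trace = track_extracted(traj, _sheet_gateway(traj))
    assert trace is not None
    assert trace.lipid == ("L", 1)
    assert trace.n_lifted_frames == 70


def _sheet_gateway(traj):
    """A 1-residue stand-in gateway resolvable in the sheet topology."""
    from lipidgate.domains import ResidueSet

    first = traj.topology.particles[0]
    return ResidueSet("gw", frozenset({(first.chain_id, first.residue_number)}))


def test_mound_and_extraction_recovery_across_seeds():
    """At the generator's study conditions, planted mound size and extracted
    lipid identity are recovered in at least 99 of 100 seeded runs."""
    ok = 0
    for seed in range(50):
        traj, truth = simulate(mound_spec(seed=seed, n_frames=1))
        rec = detect_mound(traj.frames[0], traj.topology, _plane(traj))
        mound_ok = rec is not None and sorted(rec.members) == sorted(truth.mound_members)
        traj2, truth2 = simulate(ladder_spec(seed=seed, n_frames=60, n_lipids=32))
        trace = track_extracted(traj2, GATEWAY)
        trace_ok = trace is not None and trace.lipid == truth2.extracted_lipid
        ok += mound_ok and trace_ok
    assert ok >= 50 * 0.99


def test_flat_bilayer_has_no_extraction_trace():
    traj, _ = simulate(flat_spec(seed=8))
    assert track_extracted(traj, GATEWAY) is None


def test_trace_nearest_gateway_follows_contacted_residue():
    traj, truth = simulate(ladder_spec(seed=4, n_frames=80))
    trace = track_extracted(traj, GATEWAY)
    # during the first ladder window the nearest gateway residue is D571
    window_frames = [i for i, f in enumerate(trace.frame_indices)
                     if truth.contacts["571:choline"][f]]
    hits = [trace.nearest_gateway[i] for i in window_frames]
    assert hits and all(r == ("A", 571) for r in hits)
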