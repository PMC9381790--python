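"""Salt-bridge occupancy over three replica trajectories.

Simulates three seeded replicas with planted Bernoulli contact schedules
(K568 binds the lipid phosphate 77% of frames, D571 the choline 39%), then
recovers the occupancies with the 6 Å minimum-distance criterion and pools
them frame-weighted, replicating the replica-pooling convention used for
long coarse-grained runs.
"""

from lipidgate import CHARGED_GATEWAY, occupancy, occupancy_spec, simulate

replicas = [simulate(occupancy_spec(seed=s, n_frames=500))[0] for s in (0, 1, 2)]
table = occupancy(replicas, CHARGED_GATEWAY, cutoff_A=6.0)

pooled = table[(table.replica == "pooled") & (table.occupancy > 0)]
print(pooled.to_string(index=False))
print()
for _, row in pooled.iterrows():
    print(f"residue {row.resnum}/{row.moiety}: salt bridge in "
          f"{100 * row.occupancy:.1f}% of {row.n_frames} pooled frames")
# The recovered percentages match the planted 77% / 39% to binomial noise;
# every other (residue, moiety) pair stays at zero.
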