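# lipidgate

Trajectory analysis of gateway-mediated phospholipid extraction by the ABC
transporter ABCA1.

ABCA1 exports phospholipid from the plasma membrane to apolipoprotein A-I,
the first step of HDL biogenesis.  Structural and simulation work indicates
that it does so as an *extracellular translocase*: a 29-residue charged loop
("gateway", residues 564–592) grips lipid headgroups in the outer leaflet,
lifts a small cluster of lipids (~10–12 Å, the "membrane mound") into the
outward-open cavity, and hands a single lipid up a ladder of acidic
residues (D571 → D575 → E584 → D585 at 10, 12, 15, 17 Å) toward a
ring-shaped "annulus" — the tunnel-lining residues within 10 Å of the
gateway — whose central orifice opens into an elongated hydrophobic tunnel.

`lipidgate` is the measurement toolkit for that picture.  For anyone with
membrane-protein trajectories (coarse-grained beads or all atoms), it
computes:

* **salt-bridge occupancy** — fraction of frames with a ≤ 6 Å
  minimum-distance contact between a charged side chain and a lipid
  choline/phosphate group, per replica and pooled:
  occ(r, m) = |{t : min‖xᵢ(t) − xⱼ(t)‖ ≤ 6 Å}| / T;
* **lipid lift statistics** — heights Δz above the upper-leaflet phosphate
  plane, binned into six 1 Å bins over [10, 16); mound detection by
  single-linkage clustering; tracking of the single extracted lipid and
  its sequential contact ladder;
* **proximity-defined domains** — e.g. the annulus from "within 10 Å of
  any gateway residue" — with residue-class censuses (basic/acidic/
  aromatic/…);
* **cross-state homology threading** — target sequence on a template
  backbone (copied verbatim), substituted side chains placed from an
  embedded rotamer library by least clash count, with Cα aperture metrics;
* **a seeded synthetic generator** — bilayer + gateway pseudo-protein with
  planted Bernoulli contact schedules, lift schedules and mounds, plus
  machine-readable ground truth, so every stage is testable without any
  downloads.

It is a library first (`import lipidgate`), with narrative scripts in
`examples/` and a thin `lipidgate` CLI over the config-driven pipeline.

## Worked example

```python
from lipidgate import (CHARGED_GATEWAY, occupancy, occupancy_spec, simulate)

replicas = [simulate(occupancy_spec(seed=s, n_frames=500))[0] for s in (0, 1, 2)]
table = occupancy(replicas, CHARGED_GATEWAY, cutoff_A=6.0)
print(table[(table.replica == "pooled") & (table.occupancy > 0)].to_string(index=False))
```

prints

```
replica chain  resnum    moiety  n_contact_frames  n_frames  occupancy
 pooled     A     568 phosphate              1128      1500   0.752000
 pooled     A     571   choline               592      1500   0.394667
```

— K568 holds the lipid phosphate in 75.2% of the 1500 pooled frames and
D571 the choline in 39.5%, recovering the planted 77%/39% schedules to
binomial noise, while every other charged gateway residue stays at zero.
Running `python examples/04_ladder_and_lift.py` follows the single
extracted lipid instead:

```
extracted lipid     : ('L', 1) (planted: ('L', 1)), lifted 291 frames
residue 571: first sustained contact at frame 50, lipid 10.5 Å above the surface
residue 575: first sustained contact at frame 150, lipid 12.1 Å above the surface
residue 584: first sustained contact at frame 250, lipid 14.0 Å above the surface
residue 585: first sustained contact at frame 330, lipid 17.9 Å above the surface
expected hand-off order respected: True
```

i.e. the ladder detector recovers the planted 10/12/15/17 Å rungs in order.
The remaining examples cover the synthetic generator, the domain set
arithmetic (29-residue gateway, 53-residue gateway∪annulus complex,
5 basic + 6 acidic charged residues), and threading.

## Command line

```bash
lipidgate all --preset occupancy --n-frames 1000 --n-replicas 3 --seed 1 \
    --window last:0.5 --outdir out/
```

writes occupancy and lift-histogram TSVs, mound/ladder/trace JSON, domain
tables, a threaded model PDB with clash report, and a run log; every report
carries the config hash, and identical configs reproduce byte-identical
reports.

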