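# Methods

## Scope and model

`lipidgate` analyses how an ABC transporter's *gateway* — a charged
extracellular loop (ABCA1 residues 564–592) sitting at the base of an
elongated hydrophobic tunnel — extracts phosphatidylcholine from the outer
leaflet of a membrane.  The package implements the measurement side of that
study: given coordinates (coarse-grained beads or all-atom), it computes

1. **membrane reference geometry** — per-frame leaflet assignment and the
   height reference plane;
2. **lipid lift statistics** — a 6-bin histogram of lipid heights over
   [10, 16) Å, detection of the transient *membrane mound* (a 3–5 lipid
   cluster ~10–12 Å above the surface), and tracking of the single
   extracted lipid;
3. **salt-bridge occupancies** — the fraction of frames in which a charged
   residue's side chain lies within 6 Å of a lipid choline or phosphate
   group, per replica and pooled;
4. **the extraction ladder** — the lipid's height at its first sustained
   contact with each acidic hand-off residue (D571, D575, E584, D585;
   expected rungs 10, 12, 15, 17 Å);
5. **proximity-defined domains** — e.g. the annulus as the tunnel-lining
   residues within 10 Å of any gateway residue — and residue-class
   censuses;
6. **cross-state homology threading** — target sequence on template
   backbone with least-clash rotamer side-chain placement, plus Cα
   aperture metrics.

Molecular dynamics itself (force fields, thermostats, steered pulling) is
out of scope; the package consumes trajectories, it does not produce
physical ones.

## Membrane reference frame

The membrane normal is assumed to be z; inputs must be pre-oriented.
Leaflets are assigned per frame: a lipid is *upper* iff its phosphate z
exceeds the median phosphate z of all lipids in that frame.  The median
split presumes roughly balanced leaflets, which holds for intact bilayers;
it is re-evaluated every frame so lipids that leave the surface stay
correctly labelled.

The height reference plane z₀ is the unweighted mean z of upper-leaflet
phosphate particles (phosphate particles are identical, so mass weighting
would change nothing).  Lifted lipids must not drag the reference upward,
so the plane is trimmed once: a provisional surface height is taken as the
*median* upper-leaflet phosphate z — robust against a handful of mound
lipids, where a provisional mean demonstrably fails (three surface
phosphates at 20/21/22 Å plus one extracted at 33 Å have mean 24, leaving
the extracted lipid inside a 10 Å band; the median 21.5 excludes it and
returns the intended 21) — and lipids at or above `exclusion_height_A`
(default 10 Å) over that provisional value are excluded from the final
mean.  The boundary is strict (a lipid at exactly +10 Å is excluded)
so that a lipid on the first histogram edge is measured against a clean
plane; `exclusion_height_A=None` gives the untrimmed literal mean.

All heights Δz are phosphate z minus z₀, signed.

## Lift histogram, mound, extraction trace

The histogram uses six half-open 1 Å bins [k, k+1) from 10 to 16 Å;
a lipid at exactly 16.0 Å is outside.  The default lipid selection is the
*tunnel region*: lipids whose phosphate lies within 15 Å laterally of the
centroid of the protein particles in that frame (an explicit selection or
callable overrides this).

A mound is the largest single-linkage cluster (x/y phosphate positions,
default linkage radius 10 Å) of lipids with Δz ≥ 10 Å, reported when it has
≥ 3 members (the observed mound size is 3–5).  Absence is a result, not an
error.

The extracted lipid is the one with the most frames at Δz ≥ 10 Å in the
window, ties broken by larger mean Δz; its per-frame nearest gateway
residue (minimum particle-pair distance) is recorded.

## Salt bridges and the ladder

A contact is scored when the minimum particle-pair distance between a
moiety particle set (choline: NC3 bead or N/C13–C15 atoms; phosphate: PO4
bead or P/O11–O14 atoms) and a residue's side-chain particles is ≤ 6 Å.
Side chains are the non-backbone beads in CG mode and the charged-group
heavy atoms (NZ; NH1/NH2/NE; OD1/OD2; OE1/OE2) in all-atom mode.  Minimum
distance — not centre of mass — is the only convention under which one
cutoff is meaningful across both resolutions.  Glycine in a residue set is
an error: it has nothing to bridge with.

Occupancy is the fraction of window frames with ≥ 1 contact for the
(residue, moiety) pair, computed per replica and pooled frame-weighted.
Both moiety cross-tables are always emitted; nothing restricts acidic
residues to choline a priori.

The ladder detector requires contacts to persist for ≥ `sustain_frames`
consecutive saved frames (default 2, suppressing single-frame flicker;
set 1 for a literal first-contact reading) and reports the lipid's Δz at
each onset, ordered by onset frame, with never-contacting residues flagged
absent and an explicit comparison against the expected hand-off order.

## Domains and censuses

Residue sets carry (chain, residue number) members with author numbering
preserved verbatim.  The proximity derivation keeps every candidate residue
with any particle within the cutoff (default 10 Å) of any source-residue
particle — atom-level, not Cα-level, and monotone in the cutoff.  The
tunnel-lining set is an input (it comes from cavity detection upstream).

The residue-class scheme is: basic {K, R}; acidic {D, E}; aromatic
{F, W, Y}; proline {P}; glycine {G}; hydrophobic {A, V, L, I, M, C};
neutral {S, T, N, Q, H}.  Histidine is deliberately neutral: it is counted
separately from the basic clusters when censusing transmembrane charge.
This scheme reproduces the 5 basic / 6 acidic split of the 11 charged
gateway residues (E564, R565, K568, K570, D571, D575, R579, D581, E584,
D585, R587).  Two orifice presets are shipped (73–75, 77, 78, 371, 375 and
73–74, 77, 371, 375) because the source descriptions differ; neither is
canonical here.

## Homology threading

Alignment mapping is a column walk over a two-row alignment: both-occupied
columns pair target to template residue numbers, target-only columns are
dropped insertions (no backbone to sit on), template-only columns are
skipped.  Template residue numbers must increase strictly along the pairs.

Threading copies the aligned template backbone *verbatim* — aligned Cα
positions are bitwise template positions — renumbered to the target;
identical residues keep their template side chains, substitutions are left
as bare backbone and flagged.  Template residues outside the alignment are
omitted and listed; no loop building is attempted.

Substituted side chains are rebuilt from a compact embedded
backbone-independent rotamer library: ideal bond lengths/angles, chi
dihedrals on staggered grids (≤ 81 candidates per type), idealised planar
rings, NeRF construction, L-chirality (dihedral C–N–CA–CB = −122.6°).  The
candidate minimising the clash count — pairs of (candidate side-chain atom,
any atom of another residue) closer than `clash_cutoff_A` (default 2.5 Å)
— wins; ties go to library order.  The contract is argmin-by-clash, not
reproduction of a published library, and the delivered model is
unminimised, with a per-substitution clash report.  Conformational
readouts are plain Cα–Cα distances and their signed change between two
models (the annulus-orifice aperture metric).

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
no physical dynamics: two flat leaflets of 12-bead POPC-like lipids
(choline, phosphate, two glycerol, eight tail beads) on a jittered grid,
a static pseudo-protein whose gateway loop carries numbering 564–592 (the
charged residues with their real identities, G572 with no side-chain bead),
i.i.d. Gaussian positional noise per frame, and three kinds of plants:

* **contact schedules** — per (residue, moiety), Bernoulli(p) per frame or
  an explicit frame set; on success the moiety bead is placed 4–5 Å from
  the residue's side-chain bead, on failure 9–12 Å away.  The 6 Å-contact
  / > 8 Å-non-contact *guard band* means σ ≤ 0.5 Å noise can never flip a
  planted label, so expected test outcomes are deterministic.  Planted
  residues are laid out ≥ 14 Å apart so a bead on one residue cannot touch
  another; a generator-side check rejects layouts that violate this.
* **a lift schedule** — one extracted lipid rigidly shifted by a piecewise
  Δz target (the ladder preset steps 10/12/15/17 Å with matching contact
  windows on the extracted lipid's choline).
* **a mound** — n lipids held at a fixed height (default 12 Å, the top of
  the observed 10–12 Å band, leaving ≥ 4σ margin above the 10 Å detection
  floor at the default noise) on a 5 Å circle at the tunnel axis.

Defaults are the desk-scale study conditions: 128 lipids, 1000 frames
saved every 5 ns, noise σ = 0.5 Å, three seeded replicas pooled to 3000
frames where replica statistics are needed; a full-size preset (792
lipids, 2000 frames) exists.  Every plant is recorded in a JSON-serialisable
ground truth (leaflet labels, contact indicators, extracted lipid id,
realised Δz, clean-plane z₀), identical seeds give bitwise-identical
output, and derived seeds stay below 2³¹.

What the generator does **not** emulate: membrane undulations and
curvature, lipid diffusion, correlated contact kinetics, protein
flexibility, and the free-energy barriers of extraction.  Passing tests
therefore demonstrate that the estimators recover planted statistics under
idealised geometry — not that the biological conclusions hold on real
trajectories, which the same code can consume but which are not shipped.

## Numerical choices and degenerate inputs

* Bins are left-closed; the plane-exclusion boundary is strict at the same
  value, keeping a lipid at exactly 10 Å consistently "lifted" in both.
* Occupancy over an empty frame window is an error; a mound or trace that
  does not exist is `None`, not an error.
* The occupancy estimator is the plain binomial MLE; pooled rows are
  frame-weighted, so pooling is invariant to how frames are split into
  replicas.
* Trajectory text formats: multi-model PDB (fixed-width, four-character
  lipid residue names in columns 18–21, positions good to 10⁻³ Å) and an
  extended XYZ dialect with a `Lattice=`/`Time=` comment (10⁻⁶ Å, times
  preserved exactly).  PDB carries no time metadata; frames are numbered
  at a configurable stride (default 5 ns) on read.
* Config-driven runs hash the analysis-relevant configuration (everything
  but the output directory) into every report, and identical config +
  inputs + seed reproduce reports byte-identically.

## Problem sizes used in the shipped checks

Set arithmetic is exact and instant.  Occupancy recovery uses 3 × 1000
frames at 16 lipids (the planted Bernoulli schedule, not the bilayer size,
determines the estimator's statistics) and a 100-seed sweep of the same
size; the ladder and histogram use 400 and 200 frames at 64 lipids; the
oracle-equivalence checks use 100 random frames and 50 random rotamer
placements; the null condition uses 200 flat frames.  The full suite runs
in well under a minute on one CPU.

## Known limitations

* The median leaflet split assumes balanced leaflets; strongly asymmetric
  membranes would need an explicit assignment.
* No periodic-boundary handling in x/y: lipids are taken as already
  whole and imaged; z-unwrapping is likewise not performed.
* The rotamer library is intentionally small; it ranks sterics only and
  will not reproduce fine side-chain energetics.
* GRO files are read through biotite, which emits harmless element-guess
  warnings for CG bead names.
* All-atom moiety/side-chain particle names follow CHARMM-style
  conventions; other naming schemes need explicit name lists.
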