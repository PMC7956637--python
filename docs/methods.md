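# Methods

This note documents the analysis definitions, the numerical choices behind
them, what the synthetic generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Analysis definitions

**Contacts and occupancy.** A molecule is *bound* to a residue region in a
frame when the minimum heavy-atom–heavy-atom distance between molecule and
region is ≤ the cutoff (boundary inclusive). Defaults: 5.0 Å for
cholesterol–region contacts, 4.5 Å for ligand–residue contacts, 3.5 Å for
the distance-only hydrogen-bond criterion. Region occupancy is reported as
percent of frames with ≥ 1 bound molecule, and as the mean number of bound
molecules per frame. A molecule bound to several regions in one frame
contributes one event per region to per-region statistics, but a single
event to system totals (used for the apo/holo bound-event ratio); this keeps
the two kinds of statistic independent, and reports state the frame count
and stride because percentages are meaningless without them.

**Simultaneous vs bridging motif occupancy.** For a motif pair (e.g. CRAC
and CARC), a frame is *simultaneous* when there exist distinct molecules
`a ≠ b` with `a` bound to the first motif and `b` to the second — a system
of distinct representatives. With two motifs this reduces to: both occupied,
and not by one single molecule alone; that last case is *bridged_only* and is
excluded from simultaneous counts. This is the weakest rule consistent with
requiring "two different molecules", and it handles mixed cases (a bridger
plus a partner counts as simultaneous, because a distinct pair exists).
The classifier is verified against exhaustive enumeration of all
≤ 3-molecule configurations.

**Binder classification.** Contact fraction ≥ 0.90 → constant; ≥ 0.75 →
frequent; > 0 → transient; 0 → none. Both boundaries are closed on the left
so the two thresholds follow a single convention; reports state this.
Windowed fingerprints (e.g. before/after a ligand pose change) are supported;
disjoint windows average, frame-weighted, to the full-trajectory fraction.

**Superposition metrics.** Kabsch superposition is the closed-form SVD
solution with reflection correction (determinant forced to +1); degenerate
inputs (< 3 points, collinear clouds) are rejected. RMSD series superpose
every frame onto a reference — the first analysed frame by default, since a
plateau-relative reference is a per-study choice — on the same selection the
RMSD is evaluated on (default: backbone heavy atoms of the structured core,
residues 5–158 for the bundled numbering). RMSF superposes the window frames
onto their average structure with two iterative passes (fit → re-average →
refit), then takes per-atom root-mean-square deviation from the mean; the
default window starts at the 400 ns equilibration point. PCA runs on Cα
coordinates of the same core (backbone available by flag), after the same
two-pass superposition; the 3N × 3N covariance (ddof = 1) is
eigendecomposed, eigenvalues descending. Because six rigid degrees of
freedom are fitted out, superposed fluctuations sit slightly below the raw
ones (a ~6/(3N) variance effect); tests therefore check the RMSF estimator
against its closed form without superposition and check shape preservation
with it.

**Helix bend profiles.** The Cα trace is smoothed with a sliding-window
centroid of 7 residues — two helical turns, which cancels the Cα spiral's
wobble to a residual radius of ~0.075 Å, where a 4-residue window would
leave ~0.26 Å and several degrees of spurious axis wobble. A local axis is
the principal direction of 4 consecutive centroids (configurable 3–6); the
bend angle at a split position is the angle between the axes fitted just
before the split and just after a 7-centroid gap. The gap skips centroids
whose smoothing window straddles the split, so a sharp kink is recovered at
its full inter-axis angle: numerically, constructed kinks of
5/10/15/20/30/51° read back as 5.3/10.2/15.2/20.1/30.1/51.4° with an
ideal-helix residual of 0.45°. Angles are binned at 6/12/18/24°
(blue/cyan/green/yellow/red). Both the instantaneous angle and the change
relative to the first frame are reported, since either reading of "angle
changes along the helix" can be wanted. The minimum helix length under the
defaults is 21 residues. No claim is made of numerical agreement with any
particular visualization plugin; correctness is defined by the synthetic
kink ground truth.

**Sequence analyses.** Motif patterns are anchor/gap instances (e.g.
L–X(2)–F–X(3)–R), not generic consensus definitions, because only concrete
instances are asserted for this protein family; arbitrary user patterns,
including variable gaps (every distinct anchor placement is a distinct hit),
are supported and checked against a regular-expression oracle. Pairwise
identity uses global dynamic-programming alignment with affine gaps
(BLOSUM62, open 10, extend 0.5 — configurable, since published identity
percentages rarely state their convention and can shift by 1–2 % across
programs); identity = identical aligned positions / alignment columns,
excluding terminal-gap overhangs. The aligner is verified against exhaustive
enumeration of all alignments of short pairs.

**Periodic boundaries.** Minimum-image distances are applied only when box
dimensions are present; the synthetic fixtures are non-periodic and use
plain Euclidean distances. Leaflet assignment compares each lipid's
reference atom (cholesterol hydroxyl oxygen, phospholipid phosphorus)
against the midplane defined as the mean z of all lipid reference atoms —
robust to membrane drift, unlike the box centre.

## The synthetic generator

The generator emulates the features of a membrane-protein trajectory that
the analyses actually measure, with exact ground truth:

* **Geometry.** Five ideal α-helices (1.5 Å rise, 100° twist per residue;
  backbone N/CA/C/O plus two pseudo side-chain heavy atoms per residue)
  on a 14 Å circle in the clockwise order TM I–II–V–IV–III, numbered like
  the bundled region table so the same region definitions apply. Kinks join
  two ideal segments at an exact inter-axis angle. Pseudo-molecules carry
  just enough structure to exercise every rule: cholesterol is a 5-atom,
  18 Å rigid rod with a designated hydroxyl oxygen; the ligand an 8-atom
  rigid body with a designated carbonyl oxygen; phospholipids 4-atom chains
  with a phosphorus head. The default lipid population is 30:30:10
  POPC:POPE:cholesterol (the 3:3:1 mitochondrial-membrane-like mixture).
* **Schedules.** Cholesterol–region contacts follow explicit frame lists, a
  two-state Markov chain (per-frame transition probabilities, started from
  stationarity), or bridging placements touching two motifs at once. Bound
  molecules are placed with minimum distance cutoff − 1 Å; unbound ones are
  parked beyond cutoff + 2 Å. The ligand follows a per-frame pose schedule
  (target residue or away); when the pose targets the hydrogen-bond donor
  residue the carbonyl oxygen is pinned at 2.5 Å from the donor.
* **Noise and drift.** Thermal noise is isotropic Gaussian (default
  σ = 0.15 Å, scalar or per-residue) with every per-atom displacement
  norm-clipped at 0.45 Å. Since a pairwise distance can then change by at
  most 0.9 Å, any pre-noise molecule–region distance outside the band
  (cutoff − 0.9, cutoff + 0.9) keeps its label with certainty. The generator
  measures all pre-noise frames with an all-pairs scan, **refuses to emit**
  any frame with a distance inside that band, and re-measures the emitted
  noisy frames to assert the table is reproduced — "ground truth by
  construction" is an enforced postcondition. σ ≥ 0.4 Å is rejected
  outright. Rigid drift (translation plus rotation about the membrane
  normal) is applied to the whole system and leaves all contact statistics
  invariant while exercising the superposition code.
* **Ground truth.** Contact tables, occupancy fractions, mean bound counts,
  bound-event totals, ligand per-residue contact fractions (measured on the
  emitted frames with an independent per-residue scan), hydrogen-bond
  occupancy, parked-lipid leaflet labels, kink angles and per-residue noise
  σ. Demo specs realise the emulated apo/holo study conditions (per-helix
  occupancies 32/51/23/27/100 % and 47/26/19/15/48 %, mean 1.5 cholesterol
  per frame on TM V, a 1.5 apo:holo bound-event ratio, simultaneous
  CRAC+CARC binding only in the apo system, a 51° TM I kink in the apo
  system, a ligand posed on residue 53 for 90 % of frames).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no force field, no realistic side-chain packing or
lipid conformations, no loops between helices (loop regions resolve to no
atoms and are skipped), no diffusive binding kinetics beyond two-state
on/off, no periodic images, and contact geometries chosen to be noise-proof
rather than marginal. Tests demonstrate that the analysis definitions are
computed correctly, not that any biological conclusion transfers.

## Problem sizes

The default demo trajectories are 1000 frames at 1 ns stride — the grid on
which per-mille occupancy statistics are naturally quoted — with ~1100 atoms
per frame; unit tests use 20–400-frame versions of the same conditions, and
the Markov recovery checks use 1500–2000 frames so that three standard
errors of the stationary fraction are a few percent.

## Known limitations

* Element inference from atom names is heuristic when a file lacks an
  element column; two-letter elements are recognised only for common ions.
* The PDB writer emits orthorhombic boxes only; trajectory writing beyond
  multi-MODEL PDB (and reading beyond what MDAnalysis or a user adapter
  supplies) is out of scope, as are bond perception and force-field typing.
* `pairwise_identity` reports one optimal alignment's identity; co-optimal
  alignments can differ by fractions of a percent.
* Bend profiles need ≥ 21 residues under the default windows; shorter
  helices raise rather than degrade silently.
* Interaction typing (π-stacking, cation-π), binding free energies,
  residence-time kinetics beyond on/off fractions, and 3D density maps are
  out of scope.
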