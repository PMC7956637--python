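# memtraj

Membrane-protein trajectory analysis for cholesterol- and ligand-interaction
studies: motif geography, distance-cutoff contact occupancy, ligand
interaction fingerprints and structural-stability metrics, exercised
end-to-end against a synthetic trajectory generator with exact ground truth.

## The problem

The 18 kDa translocator protein (TSPO) is a five-transmembrane-helix bundle
in the outer mitochondrial membrane, a binding partner of cholesterol and of
high-affinity ligands such as the PET tracer PK11195. Molecular-dynamics
studies of such systems ask a recurring set of questions:

* **Where are the cholesterol-recognition motifs?** CRAC
  (`L–X–Y–X(3)–R`-type instances), its inverse CARC, CRAC-like variants, the
  LAF tripeptide, plus the oligomerization motifs GXXXG and WXPXF.
* **How often is each helix or motif in contact with cholesterol?** A
  cholesterol counts as *bound* to a region when any of its heavy atoms lies
  within 5 Å of any heavy atom of the region's residues. Per-region
  occupancy is `100 × (frames with ≥ 1 bound molecule) / frames`; the mean
  count per frame is `Σ_f N_bound(f) / frames`. Two motifs are occupied
  *simultaneously* only when two **different** molecules bind them at once —
  a lone molecule bridging both is excluded (formally: a system of distinct
  representatives must exist).
* **Which residues hold the ligand?** A residue is in contact when it has a
  heavy atom within 4.5 Å of any ligand heavy atom; residues binding ≥ 90 %
  of frames are *constant* binders, ≥ 75 % *frequent*. Hydrogen bonds are
  scored with the 3.5 Å distance criterion.
* **How stable is the fold?** Backbone RMSD after least-squares (Kabsch)
  superposition, Cα RMSF about the equilibrated-window average, PCA of the
  coordinate covariance, and per-helix bend-angle profiles binned at
  6/12/18/24°.

Real microsecond trajectories of such systems are cluster-scale artefacts;
`memtraj` therefore ships a generator that emulates their analytically
relevant features (a 5-helix bundle in a 3:3:1 POPC:POPE:cholesterol-like
bilayer slab, scheduled or Markovian cholesterol contacts, a posed ligand,
kinks, rigid drift and clipped thermal noise) with ground truth exact by
construction, so every stage of the pipeline is verifiable.

## Worked example

```python
import memtraj as mt
from memtraj.pipeline import resolvable_regions

seq = mt.read_fasta(mt.motifs.bundled_sequence_path())[0]   # human TSPO, P30536
regions = mt.RegionDefinition.default_htspo()
hits = mt.find_named_motifs(seq, regions)
for name in ("CRAC", "CARC", "CRAC-like"):
    h = hits[name][0]
    anchors = "/".join(f"{aa}{p}" for p, aa in h.anchor_positions)
    print(f"{name:10s} {h.start}-{h.end}  anchors {anchors}  in {h.region}")

apo, truth = mt.synthesize_trajectory(mt.demo_apo_spec(1000), seed=1)
series = mt.region_contact_series(apo, resolvable_regions(apo, regions), cutoff=5.0)
for helix in ("TM I", "TM II", "TM III", "TM IV", "TM V"):
    print(f"{helix:7s} occupancy {mt.occupancy_percent(series, helix):5.1f} %"
          f"   mean bound {mt.mean_bound_per_frame(series, helix):.2f}")
labels, totals = mt.motif_occupancy_classes(series, "CRAC", "CARC")
print("simultaneous CRAC+CARC frames:", totals["simultaneous"])
print(f"TM I max bend: {mt.bend_profile(apo, (5, 25)).max_angle():.1f} deg")
```

prints

```
CRAC       150-156  anchors L150/Y152/R156  in TM V
CARC       135-141  anchors R135/Y138/L141  in TM V
CRAC-like  17-24  anchors L17/F20/R24  in TM I
TM I    occupancy  32.0 %   mean bound 0.32
TM II   occupancy  51.0 %   mean bound 0.51
TM III  occupancy  23.0 %   mean bound 0.23
TM IV   occupancy  27.0 %   mean bound 0.27
TM V    occupancy 100.0 %   mean bound 1.50
simultaneous CRAC+CARC frames: 500
TM I max bend: 53.9 deg
```

The motif scanner locates the three cholesterol-binding motifs at their
canonical human-TSPO coordinates. The ligand-free demo trajectory realises
its scheduled study conditions exactly: TM V is cholesterol-occupied in every
frame with 1.5 molecules bound on average, two distinct molecules occupy
CRAC and CARC simultaneously for 500 of 1000 frames, and the TM I helix
carries its built-in 51° proline-kink analogue (read back at 53.9° — the
maximum over 1000 thermally noisy frames slightly exceeds the construction
angle).

A `memtraj` console script exposes the same stages
(`memtraj scan-motifs`, `simulate`, `contacts`, `fingerprint`, `metrics`,
`run`) with flags mirroring the analysis parameters
(`--chl-cutoff 5.0 --lig-cutoff 4.5 --hbond-cutoff 3.5 --constant 0.90
--frequent 0.75 --equil-start 400`).

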