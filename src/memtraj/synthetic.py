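"""Synthetic membrane-protein trajectory generator with exact ground truth.

Real microsecond membrane-protein trajectories are cluster-scale artefacts;
this module emulates their analytically relevant features with known ground
truth so every downstream statistic can be verified.  The generated system is
a five-helix transmembrane bundle (ideal alpha-helices: 1.5 A rise and 100
degree twist per residue; backbone N/CA/C/O plus two pseudo side-chain heavy
atoms per residue) standing in an implicit bilayer slab, surrounded by a
3:3:1 POPC:POPE:cholesterol-like pseudo-lipid population, with optional bound
ligand and helix kinks.

Cholesterol molecules enter and leave 5 A contact with named residue regions
on a prescribed (frame-list) or stochastic (two-state Markov) schedule.  When
"bound" a molecule is placed with its nearest heavy atom at cutoff - 1 A from
the region; when "unbound" it is parked far beyond cutoff + 2 A.  Thermal
noise is Gaussian with per-atom displacements norm-clipped at 0.45 A (below
half the bound-side margin), so a molecule-region minimum distance can change
by at most 0.9 A between the placed and emitted frames; rigid-body drift
(translation + rotation about the membrane normal) is applied to the whole
system and leaves all internal distances invariant.

The ground-truth contact table is measured from the pre-noise frames with an
all-pairs distance scan.  Any molecule-region distance inside the ambiguous
band (cutoff +- 2 x clip) would let noise flip a label, so the generator
raises instead of emitting such a frame; by default it also re-measures the
noisy frames and asserts the table is reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .system import MolecularSystem, RegionDefinition, classify_molecules

RISE = 1.5  # A per residue
TWIST = 100.0  # degrees per residue
CA_RADIUS = 2.3  # A

# per-residue heavy atoms: (name, element, radius, phase offset deg, dz)
RESIDUE_ATOMS = (
    ("N", "N", 1.66, -26.0, -0.76),
    ("CA", "C", 2.30, 0.0, 0.00),
    ("C", "C", 2.02, 26.0, 0.75),
    ("O", "O", 2.45, 40.0, 1.10),
    ("CB", "C", 3.35, -6.0, -0.50),
    ("CG", "C", 4.55, -12.0, -0.60),
)

CHOL_SPACING = 4.5  # A between rod atoms; 5 atoms span ~18 A like cholesterol
CHOL_ATOMS = (("O3", "O"), ("C1", "C"), ("C2", "C"), ("C3", "C"), ("C4", "C"))
LIPID_ATOMS = (("P", "P"), ("C1", "C"), ("C2", "C"), ("C3", "C"))
LIGAND_ATOMS = (
    ("O1", "O"), ("C1", "C"), ("C2", "C"), ("C3", "C"),
    ("C4", "C"), ("C5", "C"), ("C6", "C"), ("C7", "C"),
)
# compact two-row ligand body in its local frame (+x = placement direction)
LIGAND_LOCAL = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.4, 0.0, 0.0],
        [2.8, 0.0, 0.0],
        [4.2, 0.0, 0.0],
        [0.7, 1.3, 0.0],
        [2.1, 1.3, 0.0],
        [3.5, 1.3, 0.0],
        [1.4, 0.0, 1.4],
    ]
)


@dataclass(frozen=True)
class HelixSpec:
    """One transmembrane helix: residue range, bundle position, direction, kink."""

    resid_start: int
    length: int
    direction: int = 1  # +1: N-terminus at the bottom (inner leaflet side)
    angle_deg: float = 0.0  # angular position on the bundle circle
    kink_resid: int | None = None
    kink_angle_deg: float = 0.0

    @property
    def resid_end(self) -> int:
        return self.resid_start + self.length - 1


@dataclass(frozen=True)
class ScheduleEntry:
    """Contact schedule for one cholesterol slot.

    ``region`` is a region name, or a ``(region_a, region_b)`` pair for a
    bridging placement touching both.  Either ``frames`` (explicit frame
    indices) or Markov rates ``k_on``/``k_off`` (per-frame transition
    probabilities; the initial state is drawn from the stationary
    distribution) must be given.  ``anchor_resids`` optionally narrows the
    residue range used to anchor the placement inside the region;
    ``angle_offset_deg`` rotates the placement direction so several molecules
    can occupy one region simultaneously without overlapping.
    """

    molecule: int  # cholesterol slot index (0-based)
    region: object
    frames: object = None
    k_on: float | None = None
    k_off: float | None = None
    anchor_resids: tuple | None = None
    angle_offset_deg: float = 0.0


@dataclass
class SyntheticSpec:
    """Generator parameters; the defaults are the emulated study conditions.

    1000 frames at 1 ns stride (the microsecond-trajectory analysis grid), a
    3:3:1 POPC:POPE:cholesterol population (30:30:10), 5 A cholesterol and
    4.5 A ligand cutoffs with (-1, +2) A bound/unbound placement margins, and
    0.15 A thermal positional noise (norm-clipped at 0.45 A so occupancy
    labels are exact).  ``sigma`` may be a ``{resid: sigma}`` mapping to give
    protein residues individual fluctuation amplitudes.
    """

    helices: tuple = ()
    bundle_radius: float = 14.0
    n_frames: int = 1000
    stride_ns: float = 1.0
    sigma: object = 0.15
    cutoff: float = 5.0
    ligand_cutoff: float = 4.5
    hbond_cutoff: float = 3.5
    bound_margin: float = 1.0
    unbound_margin: float = 2.0
    noise_clip: float = 0.45
    n_popc: int = 30
    n_pope: int = 30
    n_chol: int = 10
    chol_schedule: tuple = ()
    ligand: bool = False
    ligand_pose_schedule: tuple = ()  # (target resid | None, frame_start, frame_stop)
    hbond_donor: tuple | None = None  # (resid, atom name); acceptor = ligand O1
    drift_translation: tuple = (0.005, 0.003, 0.004)  # A per frame
    drift_rotation_deg: float = 0.01  # about z, per frame
    membrane_half_thickness: float = 15.0
    lipid_ring_radius: float = 32.0
    park_radius: float = 42.0

    def __post_init__(self) -> None:
        if not self.helices:
            self.helices = default_helices()
        sig = self.sigma if np.isscalar(self.sigma) else max(self.sigma.values(), default=0.0)
        if sig >= 0.4:
            raise ValueError(
                f"noise sigma {sig} too large for the placement margins "
                f"(-{self.bound_margin}/+{self.unbound_margin} A); need sigma < 0.4"
            )
        if self.noise_clip > min(self.bound_margin, self.unbound_margin) / 2.0:
            raise ValueError("noise_clip must not exceed half the smallest margin")


@dataclass
class GroundTruth:
    """Exact expected statistics for every downstream analysis stage."""

    region_names: list
    chol_molecule_ids: list
    contact_table: np.ndarray  # (n_frames, n_chol, n_regions) bool
    occupancy_fraction: dict  # region -> fraction of frames occupied
    mean_bound: dict  # region -> mean bound molecules per frame
    bound_events: int  # (frame, molecule) pairs with >= 1 region contact
    ligand_fractions: dict  # resid -> contact fraction (measured on emitted frames)
    hbond_fraction: float | None
    parked_leaflets: dict  # molecule_id -> upper/lower (static lipids + parked chol)
    kink_angles: dict  # helix index -> true kink angle (deg)
    rmsf_sigma: dict  # resid -> per-coordinate noise sigma (A)


def default_helices() -> tuple:
    """hTSPO-like bundle: TM I-II-V-IV-III clockwise, UniProt-style numbering."""
    return (
        HelixSpec(5, 21, +1, 0.0),       # TM I
        HelixSpec(47, 21, -1, -72.0),    # TM II
        HelixSpec(134, 24, +1, -144.0),  # TM V
        HelixSpec(110, 24, -1, -216.0),  # TM IV
        HelixSpec(79, 23, +1, -288.0),   # TM III
    )


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


def _rotation_about_axis(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def ideal_helix_ca(n_res: int, rise: float = RISE, twist: float = TWIST,
                   radius: float = CA_RADIUS) -> np.ndarray:
    """Calpha trace of an ideal alpha-helix along +z, first residue at z = 0."""
    i = np.arange(n_res)
    ph = np.deg2rad(twist * i)
    return np.column_stack([radius * np.cos(ph), radius * np.sin(ph), rise * i])


def make_kinked_helix(n_res: int, kink_position: int, kink_angle_deg: float) -> np.ndarray:
    """Calpha trace of a helix kinked at ``kink_position`` by ``kink_angle_deg``.

    Residues with 0-based index >= ``kink_position`` form the second ideal
    helical segment, whose axis makes exactly the given angle with the first.
    A kink angle of 0 reproduces the ideal helix.
    """
    if not 0 < kink_position < n_res:
        raise ValueError(f"kink_position {kink_position} outside (0, {n_res})")
    if not 0 <= kink_angle_deg < 90:
        raise ValueError(f"kink angle {kink_angle_deg} outside [0, 90) degrees")
    ca = ideal_helix_ca(n_res)
    pivot = np.array([0.0, 0.0, RISE * (kink_position - 0.5)])
    R = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), kink_angle_deg)
    ca[kink_position:] = (ca[kink_position:] - pivot) @ R.T + pivot
    return ca


def _helix_atoms(helix: HelixSpec, bundle_radius: float):
    """All heavy atoms of one placed helix: (names, elements, resids, xyz)."""
    n = helix.length
    names, elements, resids, xyz = [], [], [], []
    zc = RISE * (n - 1) / 2.0
    for i in range(n):
        ph = np.deg2rad(TWIST * i)
        z = RISE * i - zc
        if helix.direction < 0:
            z = -z
        for name, el, r, dphi, dz in RESIDUE_ATOMS:
            a = ph + np.deg2rad(dphi)
            names.append(name)
            elements.append(el)
            resids.append(helix.resid_start + i)
            xyz.append([r * np.cos(a), r * np.sin(a), z + dz])
    xyz = np.array(xyz)
    resids = np.array(resids)
    if helix.kink_resid is not None and helix.kink_angle_deg:
        if not helix.resid_start < helix.kink_resid <= helix.resid_end:
            raise ValueError(f"kink residue {helix.kink_resid} outside helix")
        local = helix.kink_resid - helix.resid_start
        zj = RISE * local - zc - RISE / 2.0
        if helix.direction < 0:
            zj = -zj
        pivot = np.array([0.0, 0.0, zj])
        # tilt the far segment outward, away from the bundle centre
        tangent = _rot_z(helix.angle_deg) @ np.array([0.0, 1.0, 0.0])
        R = _rotation_about_axis(tangent, helix.kink_angle_deg * np.sign(helix.direction))
        mask = resids >= helix.kink_resid
        xyz[mask] = (xyz[mask] - pivot) @ R.T + pivot
    centre = bundle_radius * np.array(
        [np.cos(np.deg2rad(helix.angle_deg)), np.sin(np.deg2rad(helix.angle_deg)), 0.0]
    )
    return names, elements, resids, xyz + centre


def build_bundle(spec: SyntheticSpec) -> MolecularSystem:
    """Build the protein bundle as a single-frame system (protein atoms only)."""
    names, elements, resids = [], [], []
    per_helix = []
    for helix in spec.helices:
        hn, he, hr, hx = _helix_atoms(helix, spec.bundle_radius)
        names += hn
        elements += he
        resids += list(hr)
        per_helix.append(hx)
    for i in range(len(per_helix)):
        for j in range(i + 1, len(per_helix)):
            if cdist(per_helix[i], per_helix[j]).min() < 2.0:
                raise ValueError(f"helices {i} and {j} overlap (inter-atom distance < 2 A)")
    xyz = np.vstack(per_helix)
    n = len(names)
    system = MolecularSystem(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(["ALA"] * n, dtype=object),
        molecule_ids=np.zeros(n, dtype=int),
        coords=xyz[None, :, :].copy(),
        times=np.array([0.0]),
    )
    classify_molecules(system)
    return system


# ---------------------------------------------------------------------------
# schedules


def _markov_frames(n_frames: int, k_on: float, k_off: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Bound-frame indices of a two-state chain started from stationarity."""
    if not (0 <= k_on <= 1 and 0 <= k_off <= 1) or k_on + k_off == 0:
        raise ValueError("k_on/k_off must be probabilities, not both zero")
    p_stat = k_on / (k_on + k_off)
    state = rng.random() < p_stat
    out = []
    for f in range(n_frames):
        if state:
            out.append(f)
        if rng.random() < (k_off if state else k_on):
            state = not state
    return np.asarray(out, dtype=int)


def _resolve_schedule(spec: SyntheticSpec, rng: np.random.Generator):
    """Per-frame placement entry (or None) for every cholesterol slot."""
    assign = [[None] * spec.n_frames for _ in range(spec.n_chol)]
    for entry in spec.chol_schedule:
        if not 0 <= entry.molecule < spec.n_chol:
            raise ValueError(f"schedule references cholesterol slot {entry.molecule}")
        if entry.frames is not None:
            frames = np.asarray(list(entry.frames), dtype=int)
        elif entry.k_on is not None and entry.k_off is not None:
            frames = _markov_frames(spec.n_frames, entry.k_on, entry.k_off, rng)
        else:
            raise ValueError("schedule entry needs frames or k_on/k_off")
        for f in frames:
            if not 0 <= f < spec.n_frames:
                raise ValueError(f"schedule frame {f} outside trajectory")
            if assign[entry.molecule][f] is not None:
                raise ValueError(
                    f"cholesterol slot {entry.molecule} double-booked at frame {f}"
                )
            assign[entry.molecule][f] = entry
    return assign


def _resolve_ligand_pose(spec: SyntheticSpec):
    """Per-frame ligand pose target: a resid, or None for the away position."""
    targets = [None] * spec.n_frames
    for resid, start, stop in spec.ligand_pose_schedule:
        for f in range(start, stop):
            if not 0 <= f < spec.n_frames:
                raise ValueError(f"ligand pose frame {f} outside trajectory")
            targets[f] = resid
    return targets


# ---------------------------------------------------------------------------
# placement geometry


def _outward_direction(points: np.ndarray, offset_deg: float = 0.0) -> np.ndarray:
    """Horizontal unit vector from the bundle axis through the point centroid."""
    u = points[:, :2].mean(axis=0)
    u = np.array([u[0], u[1], 0.0])
    u /= np.linalg.norm(u)
    return _rot_z(offset_deg) @ u if offset_deg else u


def _place_chol_rod(anchor_xyz: np.ndarray, target: float, offset_deg: float) -> np.ndarray:
    """Radially outward rod whose min distance to the anchor atoms is ``target``."""
    u = _outward_direction(anchor_xyz, offset_deg)
    z = anchor_xyz[:, 2].mean()
    nearest = anchor_xyz[np.argmax(anchor_xyz @ u)]
    pos0 = np.array([nearest[0], nearest[1], z]) + u * target
    rod = pos0 + np.outer(np.arange(5) * CHOL_SPACING, u)
    for _ in range(12):
        d = cdist(rod, anchor_xyz).min()
        if abs(d - target) < 1e-9:
            break
        rod += u * (target - d)
    return rod


def _place_chol_bridge(xyz_a: np.ndarray, xyz_b: np.ndarray, target: float,
                       offset_deg: float) -> np.ndarray:
    """Vertical rod spanning two stacked regions, both ends within ``target``."""
    both = np.vstack([xyz_a, xyz_b])
    u = _outward_direction(both, offset_deg)
    za, zb = xyz_a[:, 2].mean(), xyz_b[:, 2].mean()
    zc = 0.5 * (za + zb)
    direction = 1.0 if zb >= za else -1.0
    zs = zc + direction * (np.arange(5) - 2) * CHOL_SPACING
    radial = max(float((xyz_a @ u).max()), float((xyz_b @ u).max())) + target
    for _ in range(25):
        rod = np.column_stack([radial * u[0] * np.ones(5), radial * u[1] * np.ones(5), zs])
        worst = max(cdist(rod, xyz_a).min(), cdist(rod, xyz_b).min())
        if abs(worst - target) < 1e-9:
            break
        radial += target - worst
    return rod


def _park_position(slot: int, spec: SyntheticSpec, leaflet: str) -> np.ndarray:
    ang = np.deg2rad(360.0 * slot / max(spec.n_chol, 1) + 7.0)
    z = spec.membrane_half_thickness - 3.0
    if leaflet == "lower":
        z = -z
    head = spec.park_radius * np.array([np.cos(ang), np.sin(ang), 0.0]) + np.array([0, 0, z])
    tail = np.array([0.0, 0.0, -1.0 if leaflet == "upper" else 1.0])
    return head + np.outer(np.arange(5) * 2.0, tail)  # compact parked conformer


def _lipid_positions(spec: SyntheticSpec):
    """Static pseudo-phospholipid coordinates and intended leaflet labels."""
    names, elements, resnames, resids, xyz, leaflets = [], [], [], [], [], []
    for resname, count, resid_base in (
        ("POPC", spec.n_popc, 2000),
        ("POPE", spec.n_pope, 2500),
    ):
        for k in range(count):
            leaflet = "upper" if k % 2 == 0 else "lower"
            ang = np.deg2rad(360.0 * k / max(count, 1) + (13.0 if resname == "POPE" else 0.0))
            radius = spec.lipid_ring_radius + (3.0 if resname == "POPE" else 0.0)
            z = spec.membrane_half_thickness if leaflet == "upper" else -spec.membrane_half_thickness
            head = radius * np.array([np.cos(ang), np.sin(ang), 0.0]) + np.array([0, 0, z])
            tail = np.array([0.0, 0.0, -1.0 if leaflet == "upper" else 1.0])
            for j, (name, el) in enumerate(LIPID_ATOMS):
                names.append(name)
                elements.append(el)
                resnames.append(resname)
                resids.append(resid_base + k)
                xyz.append(head + tail * (2.5 * j))
            leaflets.append((resid_base + k, leaflet))
    xyz = np.array(xyz) if xyz else np.empty((0, 3))
    return names, elements, resnames, resids, xyz, leaflets


def _molecule_ids(resnames, resids) -> np.ndarray:
    from .system import STANDARD_AA

    ids = np.empty(len(resnames), dtype=int)
    mol_map: dict = {}
    next_id = 0
    for i, (rn, ri) in enumerate(zip(resnames, resids)):
        key = ("protein",) if rn in STANDARD_AA else (rn, ri)
        if key not in mol_map:
            mol_map[key] = next_id
            next_id += 1
        ids[i] = mol_map[key]
    return ids


# ---------------------------------------------------------------------------
# trajectory synthesis


def synthesize_trajectory(
    spec: SyntheticSpec,
    seed: int = 0,
    regions: RegionDefinition | None = None,
    verify: bool = True,
):
    """Generate a trajectory realizing the contact schedules, plus ground truth.

    Returns ``(system, truth)``.  Raises if the schedule geometry is not
    noise-proof (some molecule-region distance inside the ambiguous band
    around the cutoff) or if a scheduled contact could not be realized.
    """
    rng = np.random.default_rng(seed)
    regions = regions or RegionDefinition.default_htspo()

    protein = build_bundle(spec)
    prot_xyz = protein.coords[0]
    n_prot = protein.n_atoms
    prot_resids = protein.resids
    built_resids = set(int(r) for r in prot_resids)

    usable = [
        regions[name]
        for name in regions.names()
        if all(r in built_resids for r in range(regions[name].start, regions[name].end + 1))
    ]
    if not usable:
        raise ValueError("no region is resolvable on the synthetic bundle")
    region_names = [r.name for r in usable]
    region_xyz = {
        r.name: prot_xyz[(prot_resids >= r.start) & (prot_resids <= r.end)]
        for r in usable
    }

    def anchor_xyz(entry: ScheduleEntry, region_name: str) -> np.ndarray:
        if entry.anchor_resids is None:
            return region_xyz[region_name]
        lo, hi = entry.anchor_resids
        return prot_xyz[(prot_resids >= lo) & (prot_resids <= hi)]

    assign = _resolve_schedule(spec, rng)
    pose_targets = _resolve_ligand_pose(spec) if spec.ligand else []

    # --- static topology ----------------------------------------------------
    names = list(protein.names)
    elements = list(protein.elements)
    resnames = list(protein.resnames)
    resids = list(prot_resids)

    chol_slices = []
    for slot in range(spec.n_chol):
        start = len(names)
        for name, el in CHOL_ATOMS:
            names.append(name)
            elements.append(el)
            resnames.append("CHL")
            resids.append(1000 + slot)
        chol_slices.append(slice(start, len(names)))

    lip_names, lip_el, lip_resnames, lip_resids, lip_xyz, lip_leaflets = _lipid_positions(spec)
    lipid_slice = slice(len(names), len(names) + len(lip_names))
    names += lip_names
    elements += lip_el
    resnames += lip_resnames
    resids += lip_resids

    lig_slice = None
    if spec.ligand:
        start = len(names)
        for name, el in LIGAND_ATOMS:
            names.append(name)
            elements.append(el)
            resnames.append("PK1")
            resids.append(3000)
        lig_slice = slice(start, len(names))

    n_atoms = len(names)
    target_bound = spec.cutoff - spec.bound_margin
    chol_park = {slot: ("upper" if slot % 2 == 0 else "lower") for slot in range(spec.n_chol)}

    donor_idx = None
    if spec.ligand and spec.hbond_donor is not None:
        dres, dname = spec.hbond_donor
        hits = np.flatnonzero((prot_resids == dres) & (protein.names == dname))
        if not len(hits):
            raise ValueError(f"H-bond donor atom {dname!r} of residue {dres} not found")
        donor_idx = int(hits[0])

    lig_target = spec.ligand_cutoff - spec.bound_margin

    def ligand_pose(target_resid) -> np.ndarray:
        if target_resid is None:
            return LIGAND_LOCAL + np.array([60.0, 60.0, 40.0])
        res_xyz = prot_xyz[prot_resids == target_resid]
        if not len(res_xyz):
            raise ValueError(f"ligand pose target residue {target_resid} not in bundle")
        u_in = -_outward_direction(res_xyz)  # toward the bundle centre
        basis = np.column_stack([u_in, np.cross([0.0, 0.0, 1.0], u_in), [0.0, 0.0, 1.0]])
        if donor_idx is not None and int(prot_resids[donor_idx]) == target_resid:
            # pin the carbonyl oxygen at hbond_cutoff - 1 A from the donor
            anchor = prot_xyz[donor_idx] + u_in * (spec.hbond_cutoff - 1.0)
            return anchor + LIGAND_LOCAL @ basis.T
        nearest = res_xyz[np.argmax(res_xyz @ u_in)]
        body = nearest + u_in * lig_target + LIGAND_LOCAL @ basis.T
        for _ in range(12):
            d = cdist(body, res_xyz).min()
            if abs(d - lig_target) < 1e-9:
                break
            body += u_in * (lig_target - d)
        return body

    # --- per-frame placed coordinates (pre-drift, pre-noise) -----------------
    base = np.empty((spec.n_frames, n_atoms, 3))
    cache: dict = {}
    parked_leaflet_by_resid: dict = {resid: lf for resid, lf in lip_leaflets}
    for f in range(spec.n_frames):
        xyz = base[f]
        xyz[:n_prot] = prot_xyz
        for slot in range(spec.n_chol):
            entry = assign[slot][f]
            if entry is None:
                key = ("park", slot)
                if key not in cache:
                    cache[key] = _park_position(slot, spec, chol_park[slot])
                    parked_leaflet_by_resid[1000 + slot] = chol_park[slot]
            elif isinstance(entry.region, tuple):
                key = ("bridge", entry.region, entry.angle_offset_deg)
                if key not in cache:
                    for reg in entry.region:
                        if reg not in region_names:
                            raise ValueError(f"schedule region {reg!r} not resolvable")
                    cache[key] = _place_chol_bridge(
                        region_xyz[entry.region[0]], region_xyz[entry.region[1]],
                        target_bound, entry.angle_offset_deg,
                    )
            else:
                key = ("rod", entry.region, entry.anchor_resids, entry.angle_offset_deg)
                if key not in cache:
                    if entry.region not in region_names:
                        raise ValueError(f"schedule region {entry.region!r} not resolvable")
                    cache[key] = _place_chol_rod(
                        anchor_xyz(entry, entry.region), target_bound, entry.angle_offset_deg
                    )
            xyz[chol_slices[slot]] = cache[key]
        xyz[lipid_slice] = lip_xyz
        if lig_slice is not None:
            key = ("lig", pose_targets[f])
            if key not in cache:
                cache[key] = ligand_pose(pose_targets[f])
            xyz[lig_slice] = cache[key]

    # --- ground-truth contact table from the pre-noise frames ----------------
    heavy = np.array([el != "H" for el in elements])
    heavy_prot_idx = np.flatnonzero(heavy[:n_prot])
    region_cols = {
        r.name: np.flatnonzero(
            (prot_resids[heavy_prot_idx] >= r.start) & (prot_resids[heavy_prot_idx] <= r.end)
        )
        for r in usable
    }
    flip_lo = spec.cutoff - 2.0 * spec.noise_clip  # labels provably safe outside
    flip_hi = spec.cutoff + 2.0 * spec.noise_clip

    def measure(coords: np.ndarray, strict: bool) -> np.ndarray:
        table = np.zeros((spec.n_frames, spec.n_chol, len(usable)), dtype=bool)
        for f in range(spec.n_frames):
            prot_heavy = coords[f, heavy_prot_idx]
            for c, sl in enumerate(chol_slices):
                d_all = cdist(coords[f, sl], prot_heavy)
                for r, reg in enumerate(usable):
                    dmin = d_all[:, region_cols[reg.name]].min()
                    if strict and flip_lo + 1e-9 < dmin < flip_hi + 1e-9:
                        raise ValueError(
                            f"frame {f}: cholesterol slot {c} is {dmin:.2f} A from region "
                            f"{reg.name!r}, inside the noise-ambiguous band "
                            f"({flip_lo:.2f}, {flip_hi:.2f}) -- schedule geometry "
                            "is not noise-proof"
                        )
                    table[f, c, r] = dmin <= spec.cutoff
        return table

    truth_table = measure(base, strict=True)

    for slot in range(spec.n_chol):
        for f in range(spec.n_frames):
            entry = assign[slot][f]
            if entry is None:
                continue
            wanted = entry.region if isinstance(entry.region, tuple) else (entry.region,)
            for reg in wanted:
                if not truth_table[f, slot, region_names.index(reg)]:
                    raise RuntimeError(
                        f"placement failed: slot {slot} not bound to {reg!r} at frame {f}"
                    )

    # --- rigid drift + clipped thermal noise ---------------------------------
    coords = base
    if spec.drift_rotation_deg or any(spec.drift_translation):
        coords = np.empty_like(base)
        shift = np.asarray(spec.drift_translation, dtype=float)
        for f in range(spec.n_frames):
            coords[f] = base[f] @ _rot_z(spec.drift_rotation_deg * f).T + shift * f

    sigma_atom = np.zeros(n_atoms)
    if np.isscalar(spec.sigma):
        sigma_atom[:] = float(spec.sigma)
    else:
        sigma_atom[:] = 0.15
        for i in range(n_prot):
            if int(resids[i]) in spec.sigma:
                sigma_atom[i] = float(spec.sigma[int(resids[i])])
    if sigma_atom.any():
        noise = rng.standard_normal((spec.n_frames, n_atoms, 3)) * sigma_atom[None, :, None]
        norms = np.linalg.norm(noise, axis=2, keepdims=True)
        scale = np.minimum(1.0, spec.noise_clip / np.maximum(norms, 1e-300))
        coords = coords + noise * scale

    system = MolecularSystem(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        molecule_ids=_molecule_ids(resnames, resids),
        coords=coords,
        times=np.arange(spec.n_frames) * spec.stride_ns,
    )
    classify_molecules(system)

    if verify and spec.n_chol and sigma_atom.any():
        if not np.array_equal(measure(coords, strict=False), truth_table):
            raise RuntimeError("noisy frames do not reproduce the scheduled contact table")

    # --- ground truth ---------------------------------------------------------
    occ_any = truth_table.any(axis=1)
    occupancy_fraction = {
        name: float(occ_any[:, r].mean()) for r, name in enumerate(region_names)
    }
    mean_bound = {
        name: float(truth_table[:, :, r].sum(axis=1).mean())
        for r, name in enumerate(region_names)
    }

    ligand_fractions: dict = {}
    hbond_fraction = None
    if spec.ligand:
        unique_resids = sorted(built_resids)
        res_cols = {
            r: np.flatnonzero(prot_resids[heavy_prot_idx] == r) for r in unique_resids
        }
        counts = {r: 0 for r in unique_resids}
        lig_atoms = np.arange(lig_slice.start, lig_slice.stop)
        for f in range(spec.n_frames):
            d = cdist(coords[f, heavy_prot_idx], coords[f, lig_atoms]).min(axis=1)
            for r in unique_resids:
                if d[res_cols[r]].min() <= spec.ligand_cutoff:
                    counts[r] += 1
        ligand_fractions = {r: counts[r] / spec.n_frames for r in unique_resids}
        if donor_idx is not None:
            hbond_fraction = (
                sum(1 for t in pose_targets if t == spec.hbond_donor[0]) / spec.n_frames
            )

    # leaflet intent keyed by molecule id
    resid_to_mol = {}
    for i in range(n_atoms):
        if resnames[i] in ("CHL", "POPC", "POPE"):
            resid_to_mol[int(resids[i])] = int(system.molecule_ids[i])
    parked_leaflets = {
        resid_to_mol[r]: lf for r, lf in parked_leaflet_by_resid.items() if r in resid_to_mol
    }

    kink_angles = {
        h: hx.kink_angle_deg for h, hx in enumerate(spec.helices) if hx.kink_resid is not None
    }
    if np.isscalar(spec.sigma):
        rmsf_sigma = {r: float(spec.sigma) for r in sorted(built_resids)}
    else:
        rmsf_sigma = {r: float(spec.sigma.get(r, 0.15)) for r in sorted(built_resids)}

    truth = GroundTruth(
        region_names=region_names,
        chol_molecule_ids=system.molecules_of_class("cholesterol"),
        contact_table=truth_table,
        occupancy_fraction=occupancy_fraction,
        mean_bound=mean_bound,
        bound_events=int(truth_table.any(axis=2).sum()),
        ligand_fractions=ligand_fractions,
        hbond_fraction=hbond_fraction,
        parked_leaflets=parked_leaflets,
        kink_angles=kink_angles,
        rmsf_sigma=rmsf_sigma,
    )
    return system, truth


# ---------------------------------------------------------------------------
# demo study conditions


def demo_apo_spec(n_frames: int = 1000) -> SyntheticSpec:
    """Ligand-free demo system.

    Deterministic schedules realise the emulated ligand-free conditions:
    per-helix occupancies TM I 32%, TM II 51% (lower, inner-leaflet segment),
    TM III 23%, TM IV 27%, TM V 100% of frames; mean 1.5 cholesterol on TM V
    per frame; simultaneous CRAC+CARC binding by two distinct molecules for
    half the trajectory; and a 51-degree kink in TM I.
    """
    def scale(k: int) -> int:
        return int(round(k * n_frames / 1000))

    helices = list(default_helices())
    helices[0] = replace(helices[0], kink_resid=15, kink_angle_deg=51.0)
    return SyntheticSpec(
        helices=tuple(helices),
        n_frames=n_frames,
        chol_schedule=(
            ScheduleEntry(0, "CRAC", frames=range(0, scale(1000))),
            ScheduleEntry(1, "CARC", frames=range(0, scale(500))),
            ScheduleEntry(2, "TM II", frames=range(0, scale(510)), anchor_resids=(62, 66)),
            ScheduleEntry(3, "TM I", frames=range(0, scale(320)), anchor_resids=(8, 12)),
            ScheduleEntry(4, "TM III", frames=range(0, scale(230)), anchor_resids=(89, 93)),
            ScheduleEntry(5, "TM IV", frames=range(0, scale(270)), anchor_resids=(119, 123)),
        ),
    )


def demo_holo_spec(n_frames: int = 1000) -> SyntheticSpec:
    """Ligand-bound demo system.

    Emulates the ligand-bound conditions: per-helix occupancies 47/26/19/15/48%
    (TM I-TM V, with TM II bound only at its upper, outer-leaflet segment),
    cholesterol on the TM I CRAC-like motif and the TM V CRAC motif with no
    simultaneous CRAC+CARC binding, total bound events 2/3 of the ligand-free
    demo (bound-event ratio 1.5), a straight TM I, and a ligand posed on
    residue 53 for 90% of frames with a donor-acceptor hydrogen-bond trace.
    """
    def scale(k: int) -> int:
        return int(round(k * n_frames / 1000))

    return SyntheticSpec(
        helices=default_helices(),
        n_frames=n_frames,
        ligand=True,
        ligand_pose_schedule=((53, 0, scale(900)), (22, scale(900), n_frames)),
        hbond_donor=(53, "CG"),
        chol_schedule=(
            ScheduleEntry(0, "CRAC-like", frames=range(0, scale(470))),
            ScheduleEntry(1, "CRAC", frames=range(0, scale(480))),
            ScheduleEntry(2, "TM II", frames=range(0, scale(260)), anchor_resids=(48, 52)),
            ScheduleEntry(3, "TM III", frames=range(0, scale(190)), anchor_resids=(89, 93)),
            ScheduleEntry(4, "TM IV", frames=range(0, scale(150)), anchor_resids=(119, 123)),
            ScheduleEntry(5, "CRAC-like", frames=range(0, scale(337)), angle_offset_deg=28.0),
        ),
    )
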