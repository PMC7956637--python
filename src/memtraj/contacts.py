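"""Cholesterol-region contact detection and occupancy statistics.

A cholesterol molecule is counted as bound to a region (a TM helix or a
sequence motif such as CRAC/CARC) in a frame when any of its heavy atoms lies
within the distance cutoff (default 5 A) of any heavy atom of the region's
residues.  From the resulting per-frame boolean occupancy table the module
derives the standard summaries: percent of simulation time a region is
occupied, mean number of bound cholesterol per frame, apo/holo total
bound-event ratios, per-leaflet attribution, and the individual vs
simultaneous vs bridging classification of paired motif occupancy.

Simultaneous occupancy of two motifs requires two *different* cholesterol
molecules, one on each motif; a lone molecule bridging both motifs does not
count.  The rule is formalised as the existence of a pair of distinct
representatives: frames where both motifs are touched but only by one and the
same single molecule are classified ``bridged_only``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from MDAnalysis.lib.distances import capped_distance

from .system import MolecularSystem, Region, RegionDefinition, region_atoms

MOTIF_CLASSES = ("none", "only_a", "only_b", "simultaneous", "bridged_only")


def frame_contacts(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    cutoff: float,
    box: np.ndarray | None = None,
    return_pairs: bool = False,
):
    """True iff the minimum inter-group distance is <= cutoff (boundary inclusive).

    Grid-accelerated neighbour search; contractually identical to an all-pairs
    scan.  With ``box`` (orthorhombic lengths) distances are minimum-image.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    pos_a = np.ascontiguousarray(pos_a, dtype=np.float32)
    pos_b = np.ascontiguousarray(pos_b, dtype=np.float32)
    if len(pos_a) == 0 or len(pos_b) == 0:
        raise ValueError("contact groups must be non-empty")
    mda_box = None
    if box is not None:
        mda_box = np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)
    pairs = capped_distance(
        pos_a, pos_b, max_cutoff=float(cutoff), box=mda_box, return_distances=False
    )
    if return_pairs:
        return len(pairs) > 0, pairs
    return len(pairs) > 0


@dataclass
class ContactSeries:
    """Per-frame boolean occupancy of (molecule x region) pairs at a cutoff."""

    region_names: list
    molecules: list  # cholesterol molecule ids
    occupancy: np.ndarray  # (n_frames, n_molecules, n_regions) bool
    cutoff: float
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        f, m, r = self.occupancy.shape
        if m != len(self.molecules) or r != len(self.region_names):
            raise ValueError("occupancy shape inconsistent with molecule/region lists")

    @property
    def frame_count(self) -> int:
        return self.occupancy.shape[0]

    def region_index(self, region: str) -> int:
        try:
            return self.region_names.index(region)
        except ValueError:
            raise KeyError(f"region {region!r} not in series") from None


def region_contact_series(
    system: MolecularSystem,
    regions: Iterable,
    cutoff: float = 5.0,
    molecule_class: str = "cholesterol",
) -> ContactSeries:
    """Build the boolean contact table for every (frame, cholesterol, region).

    ``regions`` may be :class:`Region` objects or a :class:`RegionDefinition`.
    Heavy atoms only on both sides.  A region resolving to zero atoms raises.
    """
    if isinstance(regions, RegionDefinition):
        regions = [regions[name] for name in regions.names()]
    regions = list(regions)
    region_idx = []
    for reg in regions:
        idx = region_atoms(system, reg, heavy_only=True)
        if len(idx) == 0:
            raise ValueError(f"region {reg.name!r} resolves to no atoms")
        region_idx.append(idx)

    mols = system.molecules_of_class(molecule_class)
    heavy = system.is_heavy
    mol_atom_idx = [np.flatnonzero((system.molecule_ids == m) & heavy) for m in mols]
    # flat array of all molecule heavy atoms, with a map back to molecule slot
    if mols:
        flat = np.concatenate(mol_atom_idx)
        owner = np.concatenate([np.full(len(ix), k) for k, ix in enumerate(mol_atom_idx)])
    occ = np.zeros((system.n_frames, len(mols), len(regions)), dtype=bool)
    for f in range(system.n_frames):
        if not mols:
            break
        box = system.box_at(f)
        mda_box = None
        if box is not None:
            mda_box = np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)
        mol_pos = np.ascontiguousarray(system.coords[f, flat], dtype=np.float32)
        for r, idx in enumerate(region_idx):
            reg_pos = np.ascontiguousarray(system.coords[f, idx], dtype=np.float32)
            pairs = capped_distance(
                mol_pos, reg_pos, max_cutoff=float(cutoff), box=mda_box,
                return_distances=False,
            )
            if len(pairs):
                occ[f, np.unique(owner[pairs[:, 0]]), r] = True
    return ContactSeries(
        region_names=[reg.name for reg in regions],
        molecules=mols,
        occupancy=occ,
        cutoff=cutoff,
        times=system.times.copy(),
    )


def occupancy_percent(series: ContactSeries, region: str) -> float:
    """Percent of frames in which >= 1 molecule is bound to ``region``."""
    r = series.region_index(region)
    return 100.0 * series.occupancy[:, :, r].any(axis=1).mean() if series.frame_count else 0.0


def mean_bound_per_frame(series: ContactSeries, region: str) -> float:
    """Mean number of molecules bound to ``region`` per frame."""
    r = series.region_index(region)
    return float(series.occupancy[:, :, r].sum(axis=1).mean()) if series.frame_count else 0.0


def _frame_motif_class(bound_a: np.ndarray, bound_b: np.ndarray) -> str:
    """Classify one frame given per-molecule bound flags for motifs A and B."""
    a_any, b_any = bool(bound_a.any()), bool(bound_b.any())
    if not a_any and not b_any:
        return "none"
    if a_any != b_any:
        return "only_a" if a_any else "only_b"
    # both occupied: simultaneous iff a distinct-representative pair exists,
    # i.e. NOT (one single molecule is the only binder of both)
    set_a = set(np.flatnonzero(bound_a))
    set_b = set(np.flatnonzero(bound_b))
    if len(set_a) == 1 and set_a == set_b:
        return "bridged_only"
    return "simultaneous"


def motif_occupancy_classes(series: ContactSeries, motif_a: str, motif_b: str):
    """Per-frame occupancy class for a motif pair, plus class totals.

    Classes: ``none`` (neither motif occupied), ``only_a``/``only_b`` (exactly
    one), ``simultaneous`` (distinct molecules a != b with a on A and b on B),
    ``bridged_only`` (both occupied but only by one and the same molecule).
    Returns ``(per_frame_labels, totals_counter)``; totals partition frames.
    """
    if motif_a == motif_b:
        raise ValueError("motif_a and motif_b must differ")
    ia, ib = series.region_index(motif_a), series.region_index(motif_b)
    labels = np.array(
        [
            _frame_motif_class(series.occupancy[f, :, ia], series.occupancy[f, :, ib])
            for f in range(series.frame_count)
        ],
        dtype=object,
    )
    totals = Counter(labels.tolist())
    for cls in MOTIF_CLASSES:
        totals.setdefault(cls, 0)
    return labels, totals


def bound_events(series: ContactSeries) -> int:
    """Total bound events: (frame, molecule) pairs with >= 1 region contact."""
    return int(series.occupancy.any(axis=2).sum())


def total_bound_ratio(series_apo: ContactSeries, series_holo: ContactSeries) -> float:
    """Ratio of total bound events, apo over holo."""
    denom = bound_events(series_holo)
    if denom == 0:
        raise ValueError("holo series has zero bound events")
    return bound_events(series_apo) / denom


#: reference atom names whose z coordinate defines a lipid's leaflet
LEAFLET_REFERENCE_NAMES: dict = {"cholesterol": ("O3", "O1", "OH"), "phospholipid": ("P", "P1")}


def _leaflet_reference_atom(system: MolecularSystem, mol: int) -> int:
    cls = system.molecule_classes[mol]
    idx = system.atoms_of_molecule(mol)
    for name in LEAFLET_REFERENCE_NAMES.get(cls, ()):
        hit = idx[np.array([system.names[i] == name for i in idx])]
        if len(hit):
            return int(hit[0])
    return int(idx[0])  # fall back to the first atom


def assign_leaflets(system: MolecularSystem, frame: int = 0) -> dict:
    """Assign every lipid (cholesterol + phospholipid) to the upper/lower leaflet.

    The membrane normal is taken along z.  Each lipid's reference atom
    (cholesterol hydroxyl oxygen, phospholipid phosphorus) is compared with the
    midplane = mean z of all lipid reference atoms in the frame; this tracks
    membrane drift rather than the box centre.
    """
    lipids = system.molecules_of_class("cholesterol") + system.molecules_of_class("phospholipid")
    if not lipids:
        raise ValueError("no lipid molecules in system")
    refs = {m: _leaflet_reference_atom(system, m) for m in lipids}
    zs = {m: float(system.coords[frame, i, 2]) for m, i in refs.items()}
    midplane = float(np.mean(list(zs.values())))
    return {m: ("upper" if z >= midplane else "lower") for m, z in zs.items()}


@dataclass
class OccupancyReport:
    """Table-style cholesterol occupancy summary for one system.

    ``percent`` and ``mean_bound`` are keyed by region name; ``motif_classes``
    holds frame counts of the paired-motif classification; ``events`` is the
    per-system total bound-event count.  ``frame_count`` and ``stride_ns`` are
    recorded because the percentages are meaningless without them.
    """

    system_label: str
    percent: dict
    mean_bound: dict
    motif_classes: dict
    events: int
    frame_count: int
    stride_ns: float
    cutoff: float


def occupancy_report(
    series: ContactSeries,
    system_label: str = "system",
    motif_pair: tuple | None = None,
) -> OccupancyReport:
    """Summarise a contact series into an :class:`OccupancyReport`."""
    pct = {name: occupancy_percent(series, name) for name in series.region_names}
    mean = {name: mean_bound_per_frame(series, name) for name in series.region_names}
    classes: dict = {}
    if motif_pair is not None:
        _, totals = motif_occupancy_classes(series, motif_pair[0], motif_pair[1])
        classes = dict(totals)
    stride = float(np.median(np.diff(series.times))) if len(series.times) > 1 else 0.0
    return OccupancyReport(
        system_label=system_label,
        percent=pct,
        mean_bound=mean,
        motif_classes=classes,
        events=bound_events(series),
        frame_count=series.frame_count,
        stride_ns=stride,
        cutoff=series.cutoff,
    )
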