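"""Topology + trajectory container, molecule classification and atom selection.

A :class:`MolecularSystem` is the in-memory form every analysis stage consumes:
a flat atom table (names, elements, residue numbers/names, molecule ids), a
class per molecule (protein, cholesterol, ligand, phospholipid, water, ion,
other) and a stack of coordinate frames in Angstrom with times in nanoseconds.

Structures and trajectories are read through MDAnalysis (PDB including
multi-MODEL, GRO; any format MDAnalysis can read works the same way), or via a
user-supplied adapter yielding ``(time_ns, coordinates, box)`` per frame.
Distances use minimum-image convention only when box dimensions are present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import yaml

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: default residue-name -> molecule-class rules
DEFAULT_NAMING_RULES: dict = {
    **{aa: "protein" for aa in STANDARD_AA},
    "CHL": "cholesterol",
    "CHL1": "cholesterol",
    "CLOL": "cholesterol",
    "POPC": "phospholipid",
    "POPE": "phospholipid",
    "HOH": "water",
    "SOL": "water",
    "TIP3": "water",
    "NA": "ion",
    "CL": "ion",
    "PK1": "ligand",
}

MOLECULE_CLASSES = ("protein", "cholesterol", "ligand", "phospholipid", "water", "ion", "other")
BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class AnalysisParameters:
    """Distance cutoffs, thresholds and windows used across the pipeline.

    All distances in Angstrom, times in nanoseconds.  ``cholesterol_cutoff`` is
    the heavy-atom contact criterion for cholesterol-region binding,
    ``ligand_cutoff`` the ligand-residue criterion, ``hbond_cutoff`` the
    distance-only hydrogen-bond criterion.  ``constant_binder_threshold`` /
    ``frequent_binder_threshold`` classify per-residue ligand contact
    fractions; ``equilibration_start_ns`` is where equilibrated-window analyses
    (RMSF, windowed fingerprints) start; ``bend_bins`` are the bend-angle bin
    edges in degrees.
    """

    cholesterol_cutoff: float = 5.0
    ligand_cutoff: float = 4.5
    hbond_cutoff: float = 3.5
    constant_binder_threshold: float = 0.90
    frequent_binder_threshold: float = 0.75
    equilibration_start_ns: float = 400.0
    bend_bins: tuple = (6.0, 12.0, 18.0, 24.0)
    rmsd_selection: tuple = (5, 158)  # residue range, backbone heavy atoms

    def __post_init__(self) -> None:
        for name in ("cholesterol_cutoff", "ligand_cutoff", "hbond_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.frequent_binder_threshold <= self.constant_binder_threshold <= 1:
            raise ValueError("need 0 < frequent <= constant <= 1")
        edges = tuple(self.bend_bins)
        if any(b >= c for b, c in zip(edges, edges[1:])):
            raise ValueError("bend_bins edges must be strictly increasing")


@dataclass
class Region:
    """A named residue range with optional leaflet attribution."""

    name: str
    start: int
    end: int
    leaflet: str = "both"  # upper | lower | both

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name!r}: start > end")
        if self.leaflet not in ("upper", "lower", "both"):
            raise ValueError(f"region {self.name!r}: bad leaflet {self.leaflet!r}")

    def contains(self, resid: int) -> bool:
        return self.start <= resid <= self.end


class RegionDefinition:
    """Named residue regions (TM helices, loops, motifs) of one protein."""

    def __init__(self, regions: Iterable):
        self.regions: dict = {r.name: r for r in regions}
        if not self.regions:
            raise ValueError("no regions given")

    @classmethod
    def from_yaml(cls, path) -> "RegionDefinition":
        raw = yaml.safe_load(Path(path).read_text())
        regions = [
            Region(name, int(spec["start"]), int(spec["end"]), spec.get("leaflet", "both"))
            for name, spec in raw["regions"].items()
        ]
        return cls(regions)

    @classmethod
    def default_htspo(cls) -> "RegionDefinition":
        """The bundled human-TSPO region table."""
        return cls.from_yaml(Path(__file__).parent / "data" / "htspo_regions.yaml")

    def __getitem__(self, name: str) -> Region:
        return self.regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def names(self) -> list:
        return list(self.regions)

    def structural_region_of(self, resid: int) -> str | None:
        """Name of the TM/LP region containing ``resid`` (any region as fallback)."""
        for r in self.regions.values():
            if r.name.startswith(("TM", "LP")) and r.contains(resid):
                return r.name
        for r in self.regions.values():
            if r.contains(resid):
                return r.name
        return None


@dataclass
class MolecularSystem:
    """Atoms, molecule classes and a trajectory (coordinates in A, times in ns)."""

    names: np.ndarray  # (n_atoms,) str
    elements: np.ndarray  # (n_atoms,) str
    resids: np.ndarray  # (n_atoms,) int, 1-based
    resnames: np.ndarray  # (n_atoms,) str
    molecule_ids: np.ndarray  # (n_atoms,) int
    coords: np.ndarray  # (n_frames, n_atoms, 3) float, Angstrom
    times: np.ndarray  # (n_frames,) float, ns
    boxes: np.ndarray | None = None  # (n_frames, 3) orthorhombic lengths, or None
    molecule_classes: dict = field(default_factory=dict)  # molecule_id -> class

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.coords.ndim != 3 or self.coords.shape[1] != n or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length must match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def is_heavy(self) -> np.ndarray:
        return self.elements != "H"

    def molecules_of_class(self, cls: str) -> list:
        return sorted(m for m, c in self.molecule_classes.items() if c == cls)

    def atoms_of_molecule(self, molecule_id: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_ids == molecule_id)

    def box_at(self, frame: int) -> np.ndarray | None:
        return None if self.boxes is None else self.boxes[frame]


def _guess_element(name: str, resname: str) -> str:
    """Element from an atom name (PDB conventions; two-letter ions recognised)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if resname.strip() in ("NA", "CL", "MG", "ZN", "CA", "K") and len(stripped) <= 2:
        return stripped.capitalize()
    return stripped[0].upper()


def load_system(
    structure_path,
    trajectory_path=None,
    stride_ns: float = 1.0,
    adapter: Iterator | None = None,
) -> MolecularSystem:
    """Load a structure (PDB/GRO) and optional trajectory into a MolecularSystem.

    ``adapter``, if given, must yield ``(time_ns, coords(n_atoms,3), box)``
    tuples and replaces the trajectory file (pluggable binary-trajectory
    contract).  Frame times default to ``stride_ns`` per frame when the source
    stores none.  Atom-count mismatches raise naming the offending frame.
    """
    import MDAnalysis as mda

    structure_path = Path(structure_path)
    try:
        if trajectory_path is not None:
            u = mda.Universe(str(structure_path), str(trajectory_path))
        else:
            u = mda.Universe(str(structure_path))
    except Exception as exc:  # normalise reader errors
        raise ValueError(f"failed to read {structure_path}: {exc}") from exc

    names = np.array([a.name for a in u.atoms], dtype=object)
    resnames = np.array([a.resname for a in u.atoms], dtype=object)
    resids = np.array([a.resid for a in u.atoms], dtype=int)
    try:
        elements = np.array([e if e else "X" for e in u.atoms.elements], dtype=object)
        elements = np.array(
            [e.capitalize() for e in elements], dtype=object
        )
    except Exception:
        elements = np.array(
            [_guess_element(n, rn) for n, rn in zip(names, resnames)], dtype=object
        )

    # molecule grouping: protein residues share a molecule per segment/chain,
    # every non-protein residue is its own molecule
    molecule_ids = np.empty(len(names), dtype=int)
    mol_map: dict = {}
    chain_mol: dict = {}
    next_id = 0
    segids = np.array([getattr(a, "segid", "") or getattr(a, "chainID", "") for a in u.atoms],
                      dtype=object)
    for i in range(len(names)):
        if resnames[i] in STANDARD_AA:
            key = ("protein", segids[i])
            if key not in chain_mol:
                chain_mol[key] = next_id
                next_id += 1
            molecule_ids[i] = chain_mol[key]
        else:
            key = (segids[i], int(resids[i]), resnames[i])
            if key not in mol_map:
                mol_map[key] = next_id
                next_id += 1
            molecule_ids[i] = mol_map[key]

    frames = []
    times = []
    boxes = []
    have_box = True
    if adapter is not None:
        for f, (t, xyz, box) in enumerate(adapter):
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (len(names), 3):
                raise ValueError(
                    f"frame {f}: atom count {xyz.shape[0]} != topology {len(names)}"
                )
            frames.append(xyz)
            times.append(t)
            boxes.append(box if box is not None else np.zeros(3))
            if box is None:
                have_box = False
    else:
        # text formats carry no reliable time information; frame times come
        # from stride_ns (an adapter supplies explicit times when available)
        for f, ts in enumerate(u.trajectory):
            if ts.positions.shape[0] != len(names):
                raise ValueError(
                    f"frame {f}: atom count {ts.positions.shape[0]} != topology {len(names)}"
                )
            frames.append(ts.positions.astype(float).copy())
            times.append(f * stride_ns)
            dims = ts.dimensions
            if dims is None or not np.all(dims[:3] > 0):
                have_box = False
                boxes.append(np.zeros(3))
            else:
                boxes.append(np.asarray(dims[:3], dtype=float))

    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(frames)) * stride_ns

    system = MolecularSystem(
        names=names,
        elements=elements,
        resids=resids,
        resnames=resnames,
        molecule_ids=molecule_ids,
        coords=np.array(frames),
        times=times,
        boxes=np.array(boxes) if have_box else None,
    )
    classify_molecules(system)
    return system


def classify_molecules(
    system: MolecularSystem, naming_rules: Mapping | None = None
) -> dict:
    """Assign a class to every molecule from residue-name rules.

    Unmatched residue names go to ``other`` with a warning.  The mapping is
    stored on the system and returned.
    """
    rules = dict(DEFAULT_NAMING_RULES)
    if naming_rules:
        rules.update(naming_rules)
    classes: dict = {}
    warned = set()
    for mol in np.unique(system.molecule_ids):
        idx = system.atoms_of_molecule(int(mol))
        resname = str(system.resnames[idx[0]])
        cls = rules.get(resname)
        if cls is None:
            cls = "other"
            if resname not in warned:
                warnings.warn(f"unrecognised residue name {resname!r} classified as 'other'")
                warned.add(resname)
        classes[int(mol)] = cls
    system.molecule_classes = classes
    return classes


def select_atoms(
    system: MolecularSystem,
    resid_range: tuple | None = None,
    resnames: Iterable | None = None,
    names: Iterable | None = None,
    molecule_class: str | None = None,
    backbone: bool = False,
    heavy_only: bool = False,
    allow_empty: bool = False,
) -> np.ndarray:
    """Deterministic, order-preserving atom index selection.

    Criteria combine with AND.  ``backbone`` selects atom names N/CA/C/O.
    An empty result raises unless ``allow_empty`` is set.
    """
    mask = np.ones(system.n_atoms, dtype=bool)
    if resid_range is not None:
        lo, hi = resid_range
        mask &= (system.resids >= lo) & (system.resids <= hi)
    if resnames is not None:
        wanted = set(resnames)
        mask &= np.array([rn in wanted for rn in system.resnames])
    if names is not None:
        wanted = set(names)
        mask &= np.array([n in wanted for n in system.names])
    if backbone:
        bb = set(BACKBONE_NAMES)
        mask &= np.array([n in bb for n in system.names])
    if molecule_class is not None:
        mols = set(system.molecules_of_class(molecule_class))
        mask &= np.array([m in mols for m in system.molecule_ids])
    if heavy_only:
        mask &= system.is_heavy
    idx = np.flatnonzero(mask)
    if len(idx) == 0 and not allow_empty:
        raise ValueError("selection matched no atoms (pass allow_empty=True to permit)")
    return idx


def region_atoms(
    system: MolecularSystem,
    region: Region,
    heavy_only: bool = True,
) -> np.ndarray:
    """Protein heavy atoms of a residue-range region (side chain + backbone)."""
    return select_atoms(
        system,
        resid_range=(region.start, region.end),
        molecule_class="protein",
        heavy_only=heavy_only,
    )


# ---------------------------------------------------------------------------
# multi-MODEL PDB writing (deterministic, byte-stable)

# strict PDB columns: name 13-16, resname 18-21, chain 22, resid 23-26, x from 31
_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s} {resname:<4s}{chain:1s}{resid:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          {element:>2s}\n"
)


def _pdb_atom_name(name: str) -> str:
    # PDB columns 13-16: names of <4 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else name[:4]


def write_pdb(system: MolecularSystem, path, chain_of_molecule: Mapping | None = None) -> None:
    """Write the trajectory as a multi-MODEL PDB (single MODEL for one frame).

    Output is deterministic: identical systems produce byte-identical files.
    """
    chains = {}
    if chain_of_molecule:
        chains.update(chain_of_molecule)
    else:
        letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        per_class = {}
        for mol, cls in sorted(system.molecule_classes.items()):
            per_class.setdefault(cls, len(per_class))
        for mol, cls in sorted(system.molecule_classes.items()):
            chains[mol] = letters[per_class.get(cls, 0) % len(letters)]

    with open(path, "w") as fh:
        if system.boxes is not None:
            a, b, c = system.boxes[0]
            fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1\n")
        multi = system.n_frames > 1
        for f in range(system.n_frames):
            if multi:
                fh.write(f"MODEL     {f + 1:>4d}\n")
            xyz = system.coords[f]
            for i in range(system.n_atoms):
                fh.write(
                    _PDB_ATOM.format(
                        serial=(i % 99999) + 1,
                        name=_pdb_atom_name(str(system.names[i])),
                        resname=str(system.resnames[i])[:4],
                        chain=chains.get(int(system.molecule_ids[i]), "A"),
                        resid=int(system.resids[i]) % 10000,
                        x=xyz[i, 0],
                        y=xyz[i, 1],
                        z=xyz[i, 2],
                        occ=1.00,
                        bfac=0.00,
                        element=str(system.elements[i])[:2],
                    )
                )
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
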