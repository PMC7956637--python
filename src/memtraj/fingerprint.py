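"""Per-residue ligand interaction fingerprints.

For a bound ligand (e.g. the PET tracer PK11195 in the TSPO binding cavity)
the fingerprint is the fraction of frames each protein residue spends within a
heavy-atom distance cutoff (default 4.5 A) of any ligand heavy atom.  Residues
are classified by their contact fraction: constant (>= 0.90), frequent
(>= 0.75), transient (> 0) or none.  Both thresholds are closed on the left;
the 0.90 boundary is deliberately inclusive so the two class boundaries follow
the same convention, and reports state this.

Hydrogen bonds are scored by the distance-only criterion (donor-acceptor
heavy-atom distance <= 3.5 A, no angular term); donor and acceptor atoms are
configuration, not inferred from bonds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .system import AnalysisParameters, MolecularSystem

BINDER_CLASSES = ("constant", "frequent", "transient", "none")


def _window_frames(system: MolecularSystem, window) -> np.ndarray:
    if window is None:
        return np.arange(system.n_frames)
    t0, t1 = window
    mask = (system.times >= t0) & (system.times <= t1)
    frames = np.flatnonzero(mask)
    if len(frames) == 0:
        raise ValueError(f"no frames in time window [{t0}, {t1}] ns")
    return frames


def _min_image(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def residue_contact_fractions(
    system: MolecularSystem,
    cutoff: float = 4.5,
    ligand_class: str = "ligand",
    window: tuple | None = None,
) -> dict:
    """Fraction of window frames each protein residue contacts the ligand.

    Contact: any residue heavy atom within ``cutoff`` of any ligand heavy atom
    (minimum-image when the system carries box dimensions).  ``window`` is a
    ``(t0_ns, t1_ns)`` inclusive time window, defaulting to the whole
    trajectory.  Returns ``{resid: fraction}`` over all protein residues.
    """
    ligands = system.molecules_of_class(ligand_class)
    if not ligands:
        raise ValueError(f"no molecule of class {ligand_class!r} in system")
    heavy = system.is_heavy
    lig_idx = np.flatnonzero(np.isin(system.molecule_ids, ligands) & heavy)
    prot_mols = set(system.molecules_of_class("protein"))
    prot_mask = np.array([m in prot_mols for m in system.molecule_ids]) & heavy
    prot_idx = np.flatnonzero(prot_mask)
    if len(prot_idx) == 0:
        raise ValueError("no protein heavy atoms in system")
    prot_resids = system.resids[prot_idx]
    unique_resids = np.unique(prot_resids)
    # contiguous blocks per residue for a reduceat-style min
    order = np.argsort(prot_resids, kind="stable")
    prot_idx = prot_idx[order]
    prot_resids = prot_resids[order]
    block_starts = np.searchsorted(prot_resids, unique_resids, side="left")

    frames = _window_frames(system, window)
    counts = np.zeros(len(unique_resids), dtype=int)
    for f in frames:
        d = cdist(system.coords[f, prot_idx], system.coords[f, lig_idx])
        box = system.box_at(f)
        if box is not None:
            diff = system.coords[f, prot_idx][:, None, :] - system.coords[f, lig_idx][None, :, :]
            d = np.linalg.norm(_min_image(diff, box), axis=-1)
        per_atom_min = d.min(axis=1)
        per_res_min = np.minimum.reduceat(per_atom_min, block_starts)
        counts += per_res_min <= cutoff
    fractions = counts / len(frames)
    return {int(r): float(fr) for r, fr in zip(unique_resids, fractions)}


def classify_binders(
    fractions: Mapping,
    constant_threshold: float = 0.90,
    frequent_threshold: float = 0.75,
) -> dict:
    """Threshold classification of residue contact fractions.

    ``fraction >= constant_threshold`` -> constant; ``>= frequent_threshold``
    -> frequent; ``> 0`` -> transient; ``0`` -> none.  Pure threshold function:
    idempotent and permutation-invariant.
    """
    out = {}
    for res, fr in fractions.items():
        if not 0.0 <= fr <= 1.0:
            raise ValueError(f"fraction {fr} for residue {res} outside [0, 1]")
        if fr >= constant_threshold:
            out[res] = "constant"
        elif fr >= frequent_threshold:
            out[res] = "frequent"
        elif fr > 0:
            out[res] = "transient"
        else:
            out[res] = "none"
    return out


def _find_atom(system: MolecularSystem, spec) -> int:
    """Resolve an atom given an index or a (resid, atom_name) pair."""
    if isinstance(spec, (int, np.integer)):
        if not 0 <= spec < system.n_atoms:
            raise ValueError(f"atom index {spec} out of range")
        return int(spec)
    resid, name = spec
    hits = np.flatnonzero((system.resids == resid) & (system.names == name))
    if len(hits) == 0:
        raise ValueError(f"atom {name!r} of residue {resid} not found")
    return int(hits[0])


def hbond_occupancy(
    system: MolecularSystem,
    donor,
    acceptor,
    cutoff: float = 3.5,
    window: tuple | None = None,
) -> float:
    """Fraction of frames with donor-acceptor distance <= cutoff.

    ``donor``/``acceptor`` are atom indices or ``(resid, atom_name)`` pairs;
    both must be heavy atoms.  Distance-only criterion, no angular term.
    """
    di = _find_atom(system, donor)
    ai = _find_atom(system, acceptor)
    for i in (di, ai):
        if system.elements[i] == "H":
            raise ValueError("H-bond criterion is defined on heavy atoms")
    frames = _window_frames(system, window)
    diff = system.coords[frames, di] - system.coords[frames, ai]
    if system.boxes is not None:
        diff = _min_image(diff, system.boxes[frames])
    d = np.linalg.norm(diff, axis=1)
    return float((d <= cutoff).mean())


@dataclass
class FingerprintReport:
    """Per-residue ligand-contact summary over one time window."""

    fractions: dict  # resid -> fraction in [0, 1]
    classes: dict  # resid -> constant | frequent | transient | none
    hbonds: dict  # (donor, acceptor) label -> occupancy fraction
    window: tuple | None
    cutoff: float

    def residues_of_class(self, cls: str) -> list:
        return sorted(r for r, c in self.classes.items() if c == cls)


def fingerprint_report(
    system: MolecularSystem,
    params: AnalysisParameters | None = None,
    window: tuple | None = None,
    hbond_pairs: Mapping | None = None,
) -> FingerprintReport:
    """Compute contact fractions, binder classes and H-bond occupancies."""
    params = params or AnalysisParameters()
    fractions = residue_contact_fractions(system, cutoff=params.ligand_cutoff, window=window)
    classes = classify_binders(
        fractions,
        constant_threshold=params.constant_binder_threshold,
        frequent_threshold=params.frequent_binder_threshold,
    )
    hbonds = {}
    for label, (donor, acceptor) in (hbond_pairs or {}).items():
        hbonds[label] = hbond_occupancy(
            system, donor, acceptor, cutoff=params.hbond_cutoff, window=window
        )
    return FingerprintReport(
        fractions=fractions,
        classes=classes,
        hbonds=hbonds,
        window=window,
        cutoff=params.ligand_cutoff,
    )
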