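"""Shared fixtures and helpers for the memtraj test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from memtraj.motifs import ProteinSequence, bundled_sequence_path, read_fasta
from memtraj.system import MolecularSystem, RegionDefinition, classify_molecules

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def htspo() -> ProteinSequence:
    return read_fasta(bundled_sequence_path())[0]


@pytest.fixture(scope="session")
def htspo_regions() -> RegionDefinition:
    return RegionDefinition.default_htspo()


def make_system(
    coords,
    names=None,
    elements=None,
    resnames=None,
    resids=None,
    times=None,
    boxes=None,
) -> MolecularSystem:
    """Build a MolecularSystem from raw arrays with sensible defaults."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    system = MolecularSystem(
        names=np.array(names if names is not None else ["CA"] * n, dtype=object),
        elements=np.array(elements if elements is not None else ["C"] * n, dtype=object),
        resids=np.array(resids if resids is not None else np.arange(1, n + 1), dtype=int),
        resnames=np.array(resnames if resnames is not None else ["ALA"] * n, dtype=object),
        molecule_ids=_molecule_ids_default(
            resnames if resnames is not None else ["ALA"] * n,
            resids if resids is not None else np.arange(1, n + 1),
        ),
        coords=coords,
        times=np.asarray(times if times is not None else np.arange(coords.shape[0]), dtype=float),
        boxes=None if boxes is None else np.asarray(boxes, dtype=float),
    )
    classify_molecules(system)
    return system


def rigid_free_mode(base: np.ndarray, raw_mode: np.ndarray) -> np.ndarray:
    """Normalise a displacement mode after projecting out rigid components.

    Superposition removes net translation and (infinitesimal) rotation, so a
    mode meant to survive superposition unchanged must be orthogonal to the
    six rigid-body generators of the reference cloud.
    """
    c = base - base.mean(axis=0)
    gens = [np.tile(np.eye(3)[k], (len(base), 1)).ravel() for k in range(3)]
    gens += [np.cross(np.eye(3)[k], c).ravel() for k in range(3)]
    Q, _ = np.linalg.qr(np.array(gens).T)
    v = raw_mode.ravel().astype(float)
    v = v - Q @ (Q.T @ v)
    return (v / np.linalg.norm(v)).reshape(base.shape)


def _molecule_ids_default(resnames, resids):
    from memtraj.system import STANDARD_AA

    ids = np.empty(len(resnames), dtype=int)
    seen: dict = {}
    nxt = 0
    for i, (rn, ri) in enumerate(zip(resnames, resids)):
        key = ("protein",) if rn in STANDARD_AA else (rn, int(ri))
        if key not in seen:
            seen[key] = nxt
            nxt += 1
        ids[i] = seen[key]
    return ids
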