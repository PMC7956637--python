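"""Sequence-level motif scanning for cholesterol-binding and oligomerization motifs.

Mammalian TSPO carries several short linear motifs that matter for its membrane
biology: the cholesterol recognition/interaction amino acid consensus (CRAC,
here the instance L150-X-Y152-X(3)-R156), its inverted counterpart CARC
(R135-X(2)-Y138-X(2)-L141), a CRAC-resembling motif in the first transmembrane
helix (L17-X(2)-F20-X(3)-R24), the LAF tripeptide that enhances cholesterol
affinity, the GXXXG glycine zipper mediating helix-helix packing and the fully
conserved WXPXF motif.  This module locates such anchor/gap motifs in protein
sequences and computes pairwise global-alignment sequence identity.

Patterns are instantiated from their concrete anchor residues and gap counts
rather than from a generic published consensus: only the instances above are
asserted for this protein family, and user-defined patterns cover the general
case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in a :class:`ProteinSequence` (standard 20 + X for unknown)
SEQUENCE_ALPHABET = AMINO_ACIDS | {"X"}


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with 1-based (UniProt-style) residue numbering.

    ``numbering_offset`` is the residue number of the first residue (default 1),
    so residue *i* of the string is addressed as ``numbering_offset + i - 1``.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        for i, aa in enumerate(self.residues):
            if aa not in SEQUENCE_ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: invalid residue {aa!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, number: int) -> str:
        """One-letter code of the residue with 1-based number ``number``."""
        idx = number - self.numbering_offset
        if not 0 <= idx < len(self.residues):
            raise IndexError(f"residue {number} outside {self.id!r}")
        return self.residues[idx]


@dataclass(frozen=True)
class PatternElement:
    """One motif anchor: an allowed residue set plus the gap to the next anchor."""

    residues: frozenset
    min_gap: int = 0
    max_gap: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("anchor residue set is empty")
        if self.min_gap < 0 or self.max_gap < self.min_gap:
            raise ValueError(f"bad gap range [{self.min_gap}, {self.max_gap}]")


def _el(residues: str, min_gap: int = 0, max_gap: int | None = None) -> PatternElement:
    return PatternElement(frozenset(residues), min_gap, min_gap if max_gap is None else max_gap)


@dataclass(frozen=True)
class MotifPattern:
    """An anchor/gap motif pattern, e.g. L-X(2)-F-X(3)-R."""

    name: str
    elements: tuple

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValueError(f"pattern {self.name!r} needs >= 2 anchors")


@dataclass(frozen=True)
class MotifHit:
    """A located motif instance (1-based inclusive residue numbers)."""

    pattern_name: str
    start: int
    end: int
    anchor_positions: tuple  # of (residue number, one-letter code)
    region: str | None = None


#: The six built-in patterns, instantiated from their concrete anchors and gaps.
BUILTIN_PATTERNS: dict = {
    "CRAC": MotifPattern("CRAC", (_el("L", 1), _el("Y", 3), _el("R"))),
    "CARC": MotifPattern("CARC", (_el("R", 2), _el("Y", 2), _el("L"))),
    "CRAC-like": MotifPattern("CRAC-like", (_el("L", 2), _el("F", 3), _el("R"))),
    "GXXXG": MotifPattern("GXXXG", (_el("G", 3), _el("G"))),
    "WXPXF": MotifPattern("WXPXF", (_el("W", 1), _el("P", 1), _el("F"))),
    "LAF": MotifPattern("LAF", (_el("L"), _el("A"), _el("F"))),
}


def read_fasta(path) -> list:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    The header token before the first whitespace becomes the sequence id.
    Alignment gaps (``-``) and stop marks (``*``) are stripped with a warning;
    any other non-amino-acid character raises an error naming its position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        raw = str(rec.seq).upper()
        if "-" in raw or "*" in raw:
            warnings.warn(f"{path}: stripping gap/stop characters from record {rec.id!r}")
        cleaned = []
        for i, aa in enumerate(raw):
            if aa in "-*":
                continue
            if aa not in SEQUENCE_ALPHABET:
                raise ValueError(
                    f"{path}: record {rec.id!r} has invalid residue {aa!r} at position {i + 1}"
                )
            cleaned.append(aa)
        out.append(ProteinSequence(id=rec.id, residues="".join(cleaned)))
    return out


def scan_pattern(seq: ProteinSequence, pattern: MotifPattern) -> list:
    """Locate every match of ``pattern`` in ``seq``, including overlapping ones.

    For variable gaps every distinct anchor placement is reported as a distinct
    hit.  Hits are sorted by start position, then by anchor placement.
    """
    s = seq.residues
    n = len(s)
    hits = []

    def extend(idx: int, elem_i: int, anchors: list) -> None:
        elem = pattern.elements[elem_i]
        if idx >= n or s[idx] not in elem.residues:
            return
        anchors = anchors + [idx]
        if elem_i == len(pattern.elements) - 1:
            hits.append(tuple(anchors))
            return
        for gap in range(elem.min_gap, elem.max_gap + 1):
            extend(idx + 1 + gap, elem_i + 1, anchors)

    for start in range(n):
        extend(start, 0, [])

    off = seq.numbering_offset
    result = [
        MotifHit(
            pattern_name=pattern.name,
            start=a[0] + off,
            end=a[-1] + off,
            anchor_positions=tuple((i + off, s[i]) for i in a),
        )
        for a in sorted(hits)
    ]
    return result


def find_named_motifs(
    seq: ProteinSequence,
    region_defs=None,
    patterns: Mapping | None = None,
) -> dict:
    """Run the built-in patterns (or ``patterns``) and annotate hits with regions.

    ``region_defs`` (a :class:`memtraj.system.RegionDefinition`) supplies helix/loop
    ranges used to disambiguate multiple raw matches; each hit is annotated with
    the structural region containing its start.  Multiple matches are never
    dropped -- disambiguation is by annotation only.
    """
    patterns = dict(BUILTIN_PATTERNS) if patterns is None else dict(patterns)
    out = {}
    for name, pat in patterns.items():
        hits = scan_pattern(seq, pat)
        if region_defs is not None:
            hits = [replace(h, region=region_defs.structural_region_of(h.start)) for h in hits]
        out[name] = hits
    return out


def hit_rematches(seq: ProteinSequence, pattern: MotifPattern, hit: MotifHit) -> bool:
    """Character-by-character check that ``hit`` is a genuine match of ``pattern``."""
    positions = [p for p, _ in hit.anchor_positions]
    if positions != sorted(positions) or hit.start != positions[0] or hit.end != positions[-1]:
        return False
    for (num, aa), elem in zip(hit.anchor_positions, pattern.elements):
        if seq.residue_at(num) != aa or aa not in elem.residues:
            return False
    for (a, _), (b, _), elem in zip(
        hit.anchor_positions, hit.anchor_positions[1:], pattern.elements
    ):
        gap = b - a - 1
        if not elem.min_gap <= gap <= elem.max_gap:
            return False
    return True


def pairwise_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent sequence identity from an optimal global alignment.

    Global dynamic-programming alignment with affine gaps (defaults: BLOSUM62,
    gap open 10, extend 0.5).  Identity is the number of identical aligned
    positions divided by the number of alignment columns, excluding columns in
    terminal-gap stretches (overhangs), as a percentage.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return _alignment_identity(ga, gb)


def _alignment_identity(ga: str, gb: str) -> float:
    """Percent identity of a gapped alignment, excluding terminal-gap columns."""
    core = [i for i in range(len(ga)) if ga[i] != "-" and gb[i] != "-"]
    if not core:
        return 0.0
    lo, hi = core[0], core[-1]
    n_cols = hi - lo + 1
    n_match = sum(1 for i in range(lo, hi + 1) if ga[i] == gb[i] and ga[i] != "-")
    return 100.0 * n_match / n_cols


def write_motif_report(motifs: Mapping, path, sequence_id: str = "") -> None:
    """Write located motifs as TSV (sequence_id, pattern, start, end, anchors, region)."""
    lines = ["sequence_id\tpattern\tstart\tend\tanchors\tregion"]
    for name in motifs:
        for h in motifs[name]:
            anchors = ",".join(f"{aa}{num}" for num, aa in h.anchor_positions)
            lines.append(
                f"{sequence_id}\t{h.pattern_name}\t{h.start}\t{h.end}\t{anchors}\t{h.region or ''}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def bundled_sequence_path() -> Path:
    """Path of the bundled human TSPO (P30536) FASTA record."""
    return Path(__file__).parent / "data" / "P30536.fasta"
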