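"""Sequence data model, FASTA I/O and pairwise alignment.

The central object is :class:`SequenceRecord`, a validated amino-acid
sequence with 1-based position accessors (transcarbamylase literature
numbers residues from 1, e.g. the carbamylphosphate-binding STRT motif
at position 52 of *Enterococcus faecalis* putrescine transcarbamylase).

Pairwise alignment is global (Needleman-Wunsch) with affine gap
penalties and a log-odds substitution matrix (BLOSUM62 by default);
percent identity and percent similarity are computed over aligned
residue pairs, where "similar" means a positive substitution score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
VALID_AA = STANDARD_AA | {"X"}


class SequenceError(ValueError):
    """Raised for invalid sequence content or degenerate alignment input."""


@dataclass
class SequenceRecord:
    """An identified amino-acid sequence.

    Residues are stored uppercase; the alphabet is the 20 standard amino
    acids plus ``X`` (unknown). Positions are 1-based throughout.
    """

    id: str
    residues: str
    description: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for i, aa in enumerate(self.residues, start=1):
            if aa not in VALID_AA:
                raise SequenceError(
                    f"record {self.id!r}: invalid residue {aa!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Substring over the 1-based closed interval [start, end]."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(f"interval [{start}, {end}] outside 1..{len(self.residues)}")
        return self.residues[start - 1 : end]


@dataclass
class PairwiseAlignment:
    """Result of a global pairwise alignment.

    ``pct_identity`` and ``pct_similarity`` are percentages over aligned
    residue pairs (columns where both sequences have a residue);
    ``overlap_length`` counts those pairs. ``X`` never counts as
    identical or similar.
    """

    aligned_a: str
    aligned_b: str
    score: float
    pct_identity: float
    pct_similarity: float
    overlap_length: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into validated records.

    Line wrapping and trailing whitespace are normalized and residues
    uppercased. Raises :class:`SequenceError` for an empty file or a
    non-amino-acid character (the error names the record and position).
    """
    path = Path(path)
    records = [
        SequenceRecord(id=r.id, residues=str(r.seq).strip(), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as standard FASTA, wrapping bodies at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _default_matrix():
    """BLOSUM62 with the X row/column zeroed (X is scored neutral)."""
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = mat.alphabet
    xi = alphabet.index("X")
    for j in range(len(alphabet)):
        mat[xi, j] = 0.0
        mat[j, xi] = 0.0
    return mat


@dataclass
class AlignParams:
    """Alignment parameterization: affine gaps, log-odds matrix.

    Defaults: BLOSUM62, gap open 10, gap extend 0.5 (penalties; the
    first gapped position costs ``gap_open``, each further position
    ``gap_extend``). End gaps are penalized the same way.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


def _make_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if params.matrix_name == "BLOSUM62":
        aligner.substitution_matrix = _default_matrix()
    else:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(
    a: SequenceRecord, b: SequenceRecord, params: Optional[AlignParams] = None
) -> PairwiseAlignment:
    """Optimal global alignment of two records with identity/similarity.

    Identity counts identical non-X aligned pairs; similarity counts
    pairs whose substitution score is positive. Both are percentages of
    the aligned (residue-residue) columns.
    """
    if params is None:
        params = AlignParams()
    for rec in (a, b):
        if set(rec.residues) == {"X"}:
            raise SequenceError(f"record {rec.id!r}: all-X sequence cannot be aligned")
    aligner = _make_aligner(params)
    alignment = aligner.align(a.residues, b.residues)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])

    matrix = aligner.substitution_matrix
    n_pairs = n_ident = n_sim = 0
    for ra, rb in zip(aligned_a, aligned_b):
        if ra == "-" or rb == "-":
            continue
        n_pairs += 1
        if ra == rb and ra != "X":
            n_ident += 1
        if matrix[ra, rb] > 0:
            n_sim += 1
    pct_identity = 100.0 * n_ident / n_pairs if n_pairs else 0.0
    pct_similarity = 100.0 * n_sim / n_pairs if n_pairs else 0.0
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        pct_identity=pct_identity,
        pct_similarity=pct_similarity,
        overlap_length=n_pairs,
    )
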