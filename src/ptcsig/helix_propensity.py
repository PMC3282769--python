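"""Window-averaged alpha-helix propensity scoring.

The classifier needs to know whether the C-terminal signature of a
candidate putrescine transcarbamylase sits in a helix-favoring context
(the signature marks a 5-turn C-terminal helix). A full secondary
structure predictor is overkill for that yes/no call, so we score each
residue with the classic Chou-Fasman helix conformational parameters
(P_alpha; dimensionless, >1 helix-favoring, table mean 1.00) and take
the arithmetic mean over a window. A window mean above 1.05 over 15
residues is taken as helix-favoring by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq_core import STANDARD_AA, SequenceRecord

# Chou & Fasman helix conformational parameters (P_alpha).
CHOU_FASMAN_HELIX = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}

DEFAULT_THRESHOLD = 1.05
DEFAULT_WINDOW = 15


@dataclass
class PropensityTable:
    """Per-residue helix propensity; ``X`` scores the table mean."""

    values: dict = field(default_factory=lambda: dict(CHOU_FASMAN_HELIX))

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise ValueError(f"propensity table missing residues: {sorted(missing)}")
        for aa, v in self.values.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"non-finite or non-positive propensity for {aa}: {v}")
        self._mean = float(np.mean([self.values[aa] for aa in sorted(STANDARD_AA)]))

    def __getitem__(self, residue: str) -> float:
        if residue == "X":
            return self._mean
        return self.values[residue]

    @property
    def mean(self) -> float:
        return self._mean


def load_table(path) -> PropensityTable:
    """Read a two-column (residue, value) whitespace/comma-delimited table."""
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"malformed propensity line: {line!r}")
        values[parts[0].upper()] = float(parts[1])
    return PropensityTable(values=values)


def residue_scores(seq: SequenceRecord, table: PropensityTable | None = None) -> np.ndarray:
    """Per-residue propensity vector aligned with the sequence."""
    if table is None:
        table = PropensityTable()
    return np.array([table[aa] for aa in seq.residues], dtype=float)


def window_mean(scores: np.ndarray, start: int, end: int) -> float:
    """Mean score over the 1-based closed interval [start, end]."""
    n = len(scores)
    if not (1 <= start <= end <= n):
        raise IndexError(f"window [{start}, {end}] outside 1..{n}")
    return float(np.mean(scores[start - 1 : end]))
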