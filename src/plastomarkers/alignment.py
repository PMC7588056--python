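"""Multiple-alignment container used by every statistic in the package.

Sequences are held as a byte matrix (taxa x columns, ASCII codes) so that
column-wise statistics over ~150 kb plastome alignments stay vectorised.
The alphabet is {A, C, G, T, N, -}; 'N' and '-' are both treated as missing
data by downstream gap policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = ord("-")
UNKNOWN = ord("N")
BASES = tuple(ord(b) for b in "ACGT")

__all__ = ["MultipleAlignment", "GAP", "UNKNOWN", "BASES"]


@dataclass
class MultipleAlignment:
    """Ordered taxa with equal-length aligned sequences.

    Parameters
    ----------
    taxa:
        Unique sequence labels, in input order.
    matrix:
        uint8 array of shape ``(len(taxa), length)`` holding ASCII codes of
        upper-case bases.
    """

    taxa: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D (taxa x columns)")
        if len(self.taxa) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.taxa)} taxa but {self.matrix.shape[0]} sequence rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_sequences(
        cls, taxa: Sequence[str], sequences: Iterable[str]
    ) -> "MultipleAlignment":
        rows = [s.upper().encode("ascii") for s in sequences]
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
        matrix = np.frombuffer(b"".join(rows), dtype=np.uint8)
        n = len(rows)
        matrix = matrix.reshape(n, -1) if n else matrix.reshape(0, 0)
        return cls(list(taxa), matrix.copy())

    @classmethod
    def read_fasta(cls, path: str | Path) -> "MultipleAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls.from_sequences([r.id for r in records], [str(r.seq) for r in records])

    # -- properties --------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, taxon: str) -> str:
        idx = self.taxa.index(taxon)
        return self.matrix[idx].tobytes().decode("ascii")

    def row(self, i: int) -> str:
        return self.matrix[i].tobytes().decode("ascii")

    # -- manipulation ------------------------------------------------------
    def slice_columns(self, start: int, end: int) -> "MultipleAlignment":
        """Sub-alignment over half-open column interval [start, end)."""
        return MultipleAlignment(list(self.taxa), self.matrix[:, start:end].copy())

    def take_columns(self, indices: np.ndarray) -> "MultipleAlignment":
        return MultipleAlignment(list(self.taxa), self.matrix[:, indices].copy())

    def missing_mask(self) -> np.ndarray:
        """Boolean (taxa x columns) mask of gap or 'N' cells."""
        return (self.matrix == GAP) | (self.matrix == UNKNOWN)

    def column_gap_fraction(self) -> np.ndarray:
        """Per-column fraction of rows that are gap or 'N'."""
        return self.missing_mask().mean(axis=0)

    # -- I/O ---------------------------------------------------------------
    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(self.row(i)), id=name, description="")
            for i, name in enumerate(self.taxa)
        ]
        with open(path, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
            writer.write_file(records)
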