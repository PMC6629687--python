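"""Gapped multiple-alignment container.

An :class:`Alignment` is an ordered list of ids with equal-length gapped
rows over the residue alphabet plus ``-``.  Removing the gaps from row *k*
recovers the input residues of sequence *k* exactly; no column may consist
entirely of gaps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np

from .seqio import ALPHABET, ProteinSequence, SequenceError

GAP = "-"
#: Alignment alphabet with the gap appended last (index 21).
ALN_ALPHABET = ALPHABET + GAP
_CHAR_INDEX = {c: i for i, c in enumerate(ALN_ALPHABET)}


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise SequenceError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise SequenceError("duplicate ids in alignment")
        if self.rows:
            ncols = len(self.rows[0])
            for i, row in enumerate(self.rows):
                if len(row) != ncols:
                    raise SequenceError(f"row {self.ids[i]!r} has deviant length")
                bad = next((c for c in row if c not in _CHAR_INDEX), None)
                if bad is not None:
                    raise SequenceError(
                        f"row {self.ids[i]!r}: illegal character {bad!r}"
                    )
            if ncols and any(
                all(row[j] == GAP for row in self.rows) for j in range(ncols)
            ):
                raise SequenceError("alignment contains an all-gap column")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def to_matrix(self) -> np.ndarray:
        """(nrows, ncols) int8 matrix of alphabet indices (gap = 21)."""
        return np.array(
            [[_CHAR_INDEX[c] for c in row] for row in self.rows], dtype=np.int8
        )

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        return Alignment(wanted, [self.row(i) for i in wanted])

    @classmethod
    def from_sequences(cls, seqs: Iterable[ProteinSequence]) -> "Alignment":
        """Treat equal-length ungapped sequences as already aligned
        (positional homology known, e.g. indel-free simulated data)."""
        seqs = list(seqs)
        lens = {len(s.residues) for s in seqs}
        if len(lens) > 1:
            raise SequenceError("sequences differ in length; align them first")
        return cls([s.id for s in seqs], [s.residues for s in seqs])


def write_aligned_fasta(aln: Alignment, sink: TextIO, wrap: int = 60) -> None:
    for seq_id, row in zip(aln.ids, aln.rows):
        sink.write(f">{seq_id}\n")
        for k in range(0, len(row), wrap):
            sink.write(row[k:k + wrap] + "\n")


def read_aligned_fasta(source: TextIO | str) -> Alignment:
    from Bio import SeqIO

    handle = io.StringIO(source) if isinstance(source, str) else source
    ids, rows = [], []
    for rec in SeqIO.parse(handle, "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(ids, rows)
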