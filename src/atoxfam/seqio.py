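"""Sequence and group-table I/O.

Protein sequences travel as :class:`ProteinSequence` records over the 20
canonical amino-acid letters plus ``X`` (unknown residue).  Ambiguity codes
(B/Z/J) and the non-standard U/O are rejected outright: the pipeline's
distance and likelihood machinery assumes a fixed 20-state alphabet, and a
curated protein set should not contain them.

Group membership is a mapping from sequence id to an ordered taxonomy path
(most inclusive group first, e.g. ``Chordata;Sauropsida;Aves``).  A group
name denotes the set of ids whose path contains that name, so membership is
transitive along the path by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_ALPHABET_SET = frozenset(ALPHABET)
FASTA_WRAP = 60


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class ProteinSequence:
    """One amino-acid sequence with id and free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"invalid sequence id: {self.id!r}")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = next(
            ((i, c) for i, c in enumerate(self.residues) if c not in _ALPHABET_SET),
            None,
        )
        if bad is not None:
            pos, char = bad
            raise SequenceError(
                f"sequence {self.id!r}: illegal residue {char!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(source: TextIO | str) -> list[ProteinSequence]:
    """Parse FASTA text into validated :class:`ProteinSequence` records.

    Residues are uppercased and a single terminal ``*`` (stop) is stripped.
    Duplicate ids, empty records and illegal residue characters are errors.
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        if not residues:
            raise SequenceError(f"sequence {rec.id!r} has no residues")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        seqs.append(ProteinSequence(id=rec.id, residues=residues, description=desc))
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], sink: TextIO) -> None:
    """Write standard FASTA, wrapped at 60 residues per line."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    SeqIO.write(records, sink, "fasta")


def fasta_string(seqs: Iterable[ProteinSequence]) -> str:
    buf = io.StringIO()
    write_fasta(seqs, buf)
    return buf.getvalue()


@dataclass
class GroupLabeling:
    """Map from sequence id to an ordered taxonomy path."""

    paths: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.paths

    def __len__(self) -> int:
        return len(self.paths)

    def groups(self) -> set[str]:
        return {g for path in self.paths.values() for g in path}

    def members(self, group: str) -> set[str]:
        """Ids whose taxonomy path contains *group*."""
        return {i for i, path in self.paths.items() if group in path}

    def validate_against(self, seqs: Iterable[ProteinSequence]) -> None:
        """Raise if any labelled id is absent from the sequence set."""
        ids = {s.id for s in seqs}
        orphans = sorted(set(self.paths) - ids)
        if orphans:
            raise SequenceError(
                "labelled ids missing from sequence set: " + ", ".join(orphans)
            )


def read_group_table(source: TextIO | str) -> GroupLabeling:
    """Parse a two-column TSV (id, semicolon-joined taxonomy path)."""
    handle = io.StringIO(source) if isinstance(source, str) else source
    paths: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise SequenceError(
                f"group table line {lineno}: expected 2 tab-separated columns"
            )
        seq_id, path_str = fields[0].strip(), fields[1].strip()
        if seq_id in paths:
            raise SequenceError(f"group table line {lineno}: duplicate id {seq_id!r}")
        path = tuple(p.strip() for p in path_str.split(";") if p.strip())
        if not path:
            raise SequenceError(f"group table line {lineno}: empty taxonomy path")
        paths[seq_id] = path
    return GroupLabeling(paths)


def write_group_table(labels: GroupLabeling, sink: TextIO) -> None:
    for seq_id, path in labels.paths.items():
        sink.write(f"{seq_id}\t{';'.join(path)}\n")
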