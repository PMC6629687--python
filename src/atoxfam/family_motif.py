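"""The AT/Ox family motif at the TMIII / IC Loop 2 interface.

Rhodopsin-family GPCRs carry a charged E/DR motif at the cytoplasmic end of
the third transmembrane helix.  The Allatotropin/Orexin receptor family is
distinguished by a tryptophan in the third slot and extends the conserved
element to six residues, captured here by the degenerate pattern

    [D/E] R W [Y/N] A [I/V]

The Y/N alternative admits the single known Hydra-type variant (ERWNAI);
the D/E and I/V slots span the variants observed across phyla.  A match
counts only when anchored at the helix/loop interface: its start must lie
between six residues before the end of TMIII and the end of IC Loop 2.

The codon-change calculator backs the parsimony argument for the observed
substitutions: it finds, by exhaustive search over the standard genetic
code, the minimum number of nucleotide substitutions interconverting two
amino acids and the codon positions at which the minimal changes occur
(D<->E: one change, always at codon position 3; Y->N: one change at
position 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

from Bio.Data import CodonTable

from .seqio import ProteinSequence
from .topology import Topology

#: Degenerate family pattern: union of the variants observed across phyla.
DEFAULT_PATTERN = r"[DE]RW[YN]A[IV]"

#: Slot index (0-based) -> allowed residues, for the default pattern.
DEGENERATE_SLOTS = {0: "DE", 3: "YN", 5: "IV"}

MOTIF_LEN = 6


class CodonError(ValueError):
    """Raised when a letter does not encode a standard amino acid."""


@dataclass(frozen=True)
class FamilyMotifMatch:
    """A family-motif occurrence in one sequence."""

    variant: str
    start: int
    regions: tuple[str, ...]
    pattern_positions: dict[int, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern_positions", dict(self.pattern_positions))


def anchor_window(topo: Topology) -> tuple[int, int]:
    """Allowed motif-start window: [TMIII.end - 6, end of IC Loop 2)."""
    tm3_end = topo.tm_segments[2][1]
    icl2_end = topo.loop("IC", 2)[1]
    return max(0, tm3_end - MOTIF_LEN), icl2_end


def find_family_motif(
    seq: ProteinSequence,
    topo: Topology,
    pattern: str = DEFAULT_PATTERN,
) -> FamilyMotifMatch | None:
    """First match of *pattern* whose start lies in the anchor window."""
    lo, hi = anchor_window(topo)
    rx = re.compile(pattern)
    for m in rx.finditer(seq.residues):
        if m.start() < lo:
            continue
        if m.start() >= hi:
            break
        variant = m.group(0)
        regions = tuple(topo.span_regions(m.start(), m.end()))
        slots = {
            i: variant[i] for i in DEGENERATE_SLOTS if i < len(variant)
        }
        return FamilyMotifMatch(
            variant=variant, start=m.start(), regions=regions,
            pattern_positions=slots,
        )
    return None


def classify_variant(match: FamilyMotifMatch) -> str:
    """Canonical label of a match: the literal 6-mer itself."""
    return match.variant


def variant_counts(matches: list[FamilyMotifMatch | None]) -> dict[str, int]:
    """Count literal variants over a dataset (None entries are skipped)."""
    counts: dict[str, int] = {}
    for m in matches:
        if m is None:
            continue
        counts[m.variant] = counts.get(m.variant, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def _sense_codons() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    return by_aa


_CODONS_BY_AA = _sense_codons()


def codon_min_changes(
    aa_from: str, aa_to: str
) -> tuple[int, list[tuple[str, str, tuple[int, ...]]]]:
    """Minimum nucleotide substitutions interconverting two amino acids.

    Returns the minimum Hamming distance over all (codon encoding
    *aa_from*, codon encoding *aa_to*) pairs under the standard genetic
    code, together with every minimizing pair and the 1-based codon
    positions at which the pair differs.
    """
    for aa in (aa_from, aa_to):
        if aa not in _CODONS_BY_AA:
            raise CodonError(f"{aa!r} does not encode a standard amino acid")
    best = 4
    witnesses: list[tuple[str, str, tuple[int, ...]]] = []
    for c1, c2 in product(_CODONS_BY_AA[aa_from], _CODONS_BY_AA[aa_to]):
        diff = tuple(k + 1 for k in range(3) if c1[k] != c2[k])
        if len(diff) < best:
            best = len(diff)
            witnesses = [(c1, c2, diff)]
        elif len(diff) == best:
            witnesses.append((c1, c2, diff))
    return best, witnesses
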