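"""Clade-specific signature-motif mining.

A signature motif of a labelled group is a contiguous, ungapped peptide
that is 100% conserved across every in-group sequence (same residues at
the same alignment columns) and absent — as an exact, full-length
substring — from every sequence outside the group.  Candidates are the
maximal gap-free conserved column runs of the group; each is kept only if
its length is inside the configured bounds and its residue string passes
the specificity check against the whole dataset (an in-dataset replacement
for a database identity search).

With a single member every substring is trivially "conserved", so groups
below ``min_group_size`` are skipped with a warning; single-member mining
must be requested explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .alignment import GAP, Alignment
from .seqio import GroupLabeling, ProteinSequence
from .topology import Topology

log = logging.getLogger(__name__)

DEFAULT_LEN_BOUNDS = (6, 25)


class SignatureError(ValueError):
    """Raised for unknown groups or inconsistent inputs."""


@dataclass
class SignatureMotif:
    """A group-diagnostic conserved peptide with its alignment span."""

    group: str
    motif: str
    aln_start: int
    aln_end: int
    n_in_group: int
    region: str | None = None
    region_disagreement: bool = field(default=False)


def check_specificity(
    motif: str,
    labels: GroupLabeling,
    group: str,
    seqs: list[ProteinSequence],
) -> bool:
    """True iff no sequence outside *group* contains *motif* exactly."""
    if not motif:
        raise SignatureError("empty motif")
    members = labels.members(group)
    return not any(
        motif in s.residues for s in seqs if s.id not in members
    )


def mine_signatures(
    aln: Alignment,
    labels: GroupLabeling,
    group: str,
    len_bounds: tuple[int, int] = DEFAULT_LEN_BOUNDS,
    min_group_size: int = 2,
    seqs: list[ProteinSequence] | None = None,
) -> list[SignatureMotif]:
    """Mine maximal conserved, group-specific runs for one group.

    *seqs* (default: the alignment's own ungapped rows) is the dataset the
    specificity check runs against.
    """
    if group not in labels.groups():
        raise SignatureError(f"unknown group {group!r}")
    members = sorted(labels.members(group) & set(aln.ids))
    if len(members) < min_group_size:
        log.warning(
            "group %r has %d aligned member(s), fewer than min_group_size=%d;"
            " no signatures mined", group, len(members), min_group_size,
        )
        return []
    if seqs is None:
        seqs = [
            ProteinSequence(id=i, residues=aln.ungapped(i)) for i in aln.ids
        ]
    rows = [aln.row(i) for i in members]
    lo, hi = len_bounds
    ncols = aln.ncols
    # a conserved column holds one definite residue in every member row;
    # gaps and unknown (X) residues break candidate runs
    conserved = [
        all(r[j] == rows[0][j] for r in rows) and rows[0][j] not in (GAP, "X")
        for j in range(ncols)
    ]
    out: list[SignatureMotif] = []
    j = 0
    while j < ncols:
        if conserved[j]:
            k = j
            while k < ncols and conserved[k]:
                k += 1
            motif = rows[0][j:k]
            if lo <= len(motif) <= hi and check_specificity(
                motif, labels, group, seqs
            ):
                out.append(
                    SignatureMotif(
                        group=group, motif=motif, aln_start=j, aln_end=k,
                        n_in_group=len(members),
                    )
                )
            j = k
        else:
            j += 1
    return out


def annotate_motif_region(
    motif: SignatureMotif,
    topologies: dict[str, Topology],
    aln: Alignment,
    members: list[str],
) -> str:
    """Structural-region label(s) of a motif's residue span.

    Per in-group sequence, the distinct region labels covered by the span
    are joined with " – " (e.g. "TMIII – IC Loop 2"); the majority label
    across sequences is reported and a disagreement flag set when the
    sequences do not all agree.
    """
    votes: dict[str, int] = {}
    for seq_id in members:
        if seq_id not in topologies:
            raise SignatureError(f"missing topology for {seq_id!r}")
        row = aln.row(seq_id)
        res_start = sum(1 for c in row[: motif.aln_start] if c != GAP)
        res_end = res_start + (motif.aln_end - motif.aln_start)
        label = " – ".join(
            topologies[seq_id].span_regions(res_start, res_end)
        )
        votes[label] = votes.get(label, 0) + 1
    majority = max(sorted(votes), key=lambda k: votes[k])
    motif.region = majority
    motif.region_disagreement = len(votes) > 1
    return majority


def signature_report(motifs: list[SignatureMotif]) -> pd.DataFrame:
    """Tabulate signatures (group, location, motif, support, span)."""
    rows = [
        {
            "group": m.group,
            "location": m.region if m.region is not None else "",
            "motif": m.motif,
            "n_in_group": m.n_in_group,
            "aln_start": m.aln_start,
            "aln_end": m.aln_end,
        }
        for m in motifs
    ]
    df = pd.DataFrame(
        rows, columns=["group", "location", "motif", "n_in_group",
                       "aln_start", "aln_end"],
    )
    return df.sort_values(["group", "aln_start"], kind="stable").reset_index(drop=True)
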