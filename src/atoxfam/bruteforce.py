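"""Exhaustive reference implementations.

Small, slow, obviously-correct counterparts to the optimized routines:
full enumeration of global alignments, likelihood by summation over all
internal-state assignments, and signature mining by substring
enumeration.  They exist for validation at tiny problem sizes and are
deliberately independent of the production code paths.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .alignment import Alignment
from .likelihood import PoissonAminoAcidModel
from .msa import ScoringScheme
from .seqio import GroupLabeling, ProteinSequence
from .tree import PhyloTree


def enumerate_alignment_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Best global affine-gap score by explicit enumeration of every
    alignment (exponential; lengths <= ~7 only).

    An alignment is a sequence of columns, each consuming a residue of
    `a`, of `b`, or both; a gap run of length L costs
    gap_open + (L - 1) * gap_extend.
    """
    open_, ext = scheme.gap_open, scheme.gap_extend
    best = [-float("inf")]

    def recurse(i: int, j: int, score: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + scheme.score(a[i], b[j]), "M")
        if i < len(a):  # a[i] against a gap in b
            pen = ext if prev == "X" else open_
            recurse(i + 1, j, score + pen, "X")
        if j < len(b):  # b[j] against a gap in a
            pen = ext if prev == "Y" else open_
            recurse(i, j + 1, score + pen, "Y")

    recurse(0, 0, 0.0, "")
    return best[0]


def enumerate_log_likelihood(
    tree: PhyloTree, aln: Alignment, model: PoissonAminoAcidModel | None = None
) -> float:
    """Log-likelihood by brute-force summation over every assignment of
    states to internal nodes (20^m per column)."""
    model = model or PoissonAminoAcidModel()
    k = model.n_states
    mat = aln.to_matrix()
    row_of = {seq_id: r for r, seq_id in enumerate(aln.ids)}
    nodes = list(tree.root.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    pmat: dict[int, np.ndarray] = {
        id(n): model.transition_matrix(n.length)
        for n in nodes
        if n is not tree.root
    }
    log_total = 0.0
    for col in range(aln.ncols):
        total = 0.0
        for assign in product(range(k), repeat=len(internal)):
            states: dict[int, int] = {
                id(n): s for n, s in zip(internal, assign)
            }
            prob = 1.0 / k  # uniform root frequency
            for n in nodes:
                if n is tree.root:
                    continue
                parent_state = states[id(n.parent)]
                if n.is_leaf:
                    obs = int(mat[row_of[n.name], col])
                    if obs >= k:  # gap/X: missing, sums to 1
                        continue
                    prob_edge = pmat[id(n)][parent_state, obs]
                else:
                    prob_edge = pmat[id(n)][parent_state, states[id(n)]]
                prob *= prob_edge
            total += prob
        log_total += float(np.log(total))
    return log_total


def mine_signatures_bruteforce(
    seqs: list[ProteinSequence],
    labels: GroupLabeling,
    group: str,
    len_bounds: tuple[int, int],
) -> set[str]:
    """Group signatures by substring enumeration.

    Candidates are all substrings of one in-group sequence; a candidate
    qualifies if every in-group sequence contains it and no out-group
    sequence does.  Maximality is imposed before the length bounds, as in
    the run-based miner: a qualifying substring contained in a longer
    qualifying substring is discarded, then the bounds filter applies.
    """
    members = labels.members(group)
    in_group = [s.residues for s in seqs if s.id in members]
    out_group = [s.residues for s in seqs if s.id not in members]
    if not in_group:
        return set()
    first = in_group[0]
    qualifying: set[str] = set()
    for i in range(len(first)):
        for j in range(i + 1, len(first) + 1):
            sub = first[i:j]
            if all(sub in s for s in in_group) and not any(
                sub in s for s in out_group
            ):
                qualifying.add(sub)
    maximal = {
        s for s in qualifying
        if not any(s != t and s in t for t in qualifying)
    }
    lo, hi = len_bounds
    return {s for s in maximal if lo <= len(s) <= hi}


def random_protein(rng: np.random.Generator, length: int) -> str:
    from .seqio import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
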