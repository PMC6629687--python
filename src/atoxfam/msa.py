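"""Progressive multiple sequence alignment.

The aligner is a Gotoh affine-gap global aligner generalized to
profile–profile alignment with sum-of-pairs column scoring: the score of
aligning column i of profile A with column j of profile B is

    S(i, j) = sum_{x,y} c_A[i, x] c_B[j, y] s(x, y) / (n_A n_B)

over residue counts c (gaps and X contribute nothing), with BLOSUM62 as
the default substitution matrix; normalizing by the number of row pairs
keeps column scores on the single-sequence scale that the flat affine gap
penalties are calibrated against.  A gap run of length L costs
gap_open + (L - 1) * gap_extend per profile column event (the first gap
position carries the open penalty).  Defaults: gap_open -10,
gap_extend -1, the standard protein settings.

Progressive alignment merges profiles bottom-up along a Neighbour-Joining
guide tree built from p-distances of the pairwise alignments.  Traceback
ties are fixed for determinism: match/mismatch first, then gap in the
second profile, then gap in the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .alignment import GAP, Alignment
from .phylo import DistanceMatrix, nj_tree
from .seqio import AMINO_ACIDS, ProteinSequence, SequenceError
from .tree import PhyloTree, TreeError

_NEG = -1e30
_N_RES = 21  # 20 amino acids + X (X scores 0 against everything)


class AlignmentError(ValueError):
    """Raised for invalid aligner input."""


@dataclass(frozen=True)
class ScoringScheme:
    """Symmetric substitution matrix over the 21-letter alphabet plus
    affine gap penalties (gap_open <= gap_extend < 0)."""

    matrix: np.ndarray
    gap_open: int = -10
    gap_extend: int = -1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (_N_RES, _N_RES) or not np.allclose(m, m.T):
            raise AlignmentError("substitution matrix must be symmetric 21x21")
        if not (self.gap_open <= self.gap_extend < 0):
            raise AlignmentError("require gap_open <= gap_extend < 0")
        object.__setattr__(self, "matrix", m)

    def score(self, a: str, b: str) -> float:
        ia = (AMINO_ACIDS + "X").index(a)
        ib = (AMINO_ACIDS + "X").index(b)
        return float(self.matrix[ia, ib])


def blosum62_scheme(gap_open: int = -10, gap_extend: int = -1) -> ScoringScheme:
    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((_N_RES, _N_RES))
    letters = AMINO_ACIDS  # X row/col stays 0
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            mat[i, j] = blosum[a][b]
    return ScoringScheme(matrix=mat, gap_open=gap_open, gap_extend=gap_extend)


def _profile_counts(aln: Alignment) -> np.ndarray:
    """(ncols, 21) residue counts per column; gaps excluded."""
    mat = aln.to_matrix()
    counts = np.zeros((aln.ncols, _N_RES))
    for r in range(mat.shape[0]):
        row = mat[r]
        keep = row < _N_RES
        np.add.at(counts, (np.nonzero(keep)[0], row[keep].astype(int)), 1.0)
    return counts


def _gotoh(S: np.ndarray, open_: float, ext: float):
    """Affine-gap DP over the column-score matrix S (n x m).

    Returns (score, path) where path is a list of (i | None, j | None)
    0-based column indices; None marks a gap on that side.
    States: M consumes both; X consumes a column of A (gap in B);
    Y consumes a column of B (gap in A).
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if m:
        j = np.arange(1, m + 1)
        Y[0, 1:] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        X[i, :] = np.maximum.reduce(
            [M[i - 1, :] + open_, X[i - 1, :] + ext, Y[i - 1, :] + open_]
        )
        if m:
            prev = np.maximum.reduce([M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
            M[i, 1:] = prev + S[i - 1, :]
            M[i, 0] = _NEG
            # horizontal pass: Y[i,j] = max(max(M,X)[i,j-1]+open, Y[i,j-1]+ext)
            W = np.maximum(M[i, :-1], X[i, :-1]) + open_
            A = W - ext * np.arange(1, m + 1)
            Z = np.maximum.accumulate(A)
            Y[i, 1:] = Z + ext * np.arange(1, m + 1)
            Y[i, 0] = _NEG

    finals = (M[n, m], X[n, m], Y[n, m])
    # deterministic priority: M, then X (gap in second), then Y
    best = max(finals)
    state = next(k for k, v in enumerate(finals) if v == best)
    score = best

    path: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:  # M
            path.append((i - 1, j - 1))
            cands = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
        elif state == 1:  # X: consume A_i against gap
            path.append((i - 1, None))
            cands = (M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_)
            i = i - 1
        else:  # Y: consume B_j against gap
            path.append((None, j - 1))
            cands = (M[i, j - 1] + open_, X[i, j - 1] + open_, Y[i, j - 1] + ext)
            j = j - 1
        if i == 0 and j == 0:
            break
        # predecessor state by value, ties in priority order M, X, Y
        bestv = max(cands)
        state = next(k for k in (0, 1, 2) if cands[k] == bestv)
    path.reverse()
    return float(score), path


def _merge(a: Alignment, b: Alignment, path) -> Alignment:
    rows_a = ["".join(r[i] if i is not None else GAP for i, _ in path) for r in a.rows]
    rows_b = ["".join(r[j] if j is not None else GAP for _, j in path) for r in b.rows]
    return Alignment(a.ids + b.ids, rows_a + rows_b)


def align_profiles(
    a: Alignment, b: Alignment, scheme: ScoringScheme | None = None
) -> tuple[Alignment, float]:
    """Globally align two profiles; returns the merged alignment and score."""
    scheme = scheme or blosum62_scheme()
    ca = _profile_counts(a)
    cb = _profile_counts(b)
    # average-of-pairs column score: dividing the sum-of-pairs score by the
    # (constant) number of row pairs keeps it on the single-sequence scale
    # the flat affine gap penalties were chosen for
    S = (ca @ scheme.matrix @ cb.T) / (a.nrows * b.nrows)
    score, path = _gotoh(S, float(scheme.gap_open), float(scheme.gap_extend))
    return _merge(a, b, path), score


def pairwise_align(
    a: ProteinSequence, b: ProteinSequence, scheme: ScoringScheme | None = None
) -> tuple[str, str, float]:
    """Global affine-gap alignment of two sequences (Gotoh)."""
    if not a.residues or not b.residues:
        raise AlignmentError("cannot align empty sequences")
    merged, score = align_profiles(
        Alignment([a.id], [a.residues]),
        Alignment([b.id], [b.residues]),
        scheme,
    )
    return merged.rows[0], merged.rows[1], score


def pairwise_p_distance(row_a: str, row_b: str) -> float:
    """p-distance over columns where both rows hold residues."""
    pairs = [
        (x, y) for x, y in zip(row_a, row_b) if x != GAP and y != GAP
    ]
    if not pairs:
        raise AlignmentError("no comparable columns")
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def build_guide_tree(
    seqs: list[ProteinSequence], scheme: ScoringScheme | None = None
) -> PhyloTree:
    """NJ guide tree from p-distances of all pairwise alignments."""
    if len(seqs) < 2:
        raise TreeError("need at least 2 sequences")
    scheme = scheme or blosum62_scheme()
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb, _ = pairwise_align(seqs[i], seqs[j], scheme)
            d[i, j] = d[j, i] = pairwise_p_distance(ra, rb)
    return nj_tree(DistanceMatrix([s.id for s in seqs], d))


def progressive_align(
    seqs: list[ProteinSequence],
    guide: PhyloTree | None = None,
    scheme: ScoringScheme | None = None,
) -> Alignment:
    """Merge profiles bottom-up along the guide tree."""
    if not seqs:
        raise AlignmentError("no sequences to align")
    scheme = scheme or blosum62_scheme()
    by_id = {s.id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise SequenceError("duplicate sequence ids")
    if len(seqs) == 1:
        return Alignment([seqs[0].id], [seqs[0].residues])
    if guide is None:
        guide = build_guide_tree(seqs, scheme)
    if set(guide.leaf_names()) != set(by_id):
        raise TreeError("guide tree leaves do not match sequence ids")

    def merge_node(node) -> Alignment:
        if node.is_leaf:
            seq = by_id[node.name]
            return Alignment([seq.id], [seq.residues])
        acc = merge_node(node.children[0])
        for child in node.children[1:]:
            acc, _ = align_profiles(acc, merge_node(child), scheme)
        return acc

    return merge_node(guide.root)


def sum_of_pairs_score(aln: Alignment, scheme: ScoringScheme | None = None) -> float:
    """Sum over row pairs of the induced pairwise alignment scores."""
    scheme = scheme or blosum62_scheme()
    total = 0.0
    for i in range(aln.nrows):
        for j in range(i + 1, aln.nrows):
            total += _induced_pair_score(aln.rows[i], aln.rows[j], scheme)
    return total


def _induced_pair_score(ra: str, rb: str, scheme: ScoringScheme) -> float:
    cols = [(x, y) for x, y in zip(ra, rb) if not (x == GAP and y == GAP)]
    total = 0.0
    in_gap_a = in_gap_b = False
    for x, y in cols:
        if x != GAP and y != GAP:
            total += scheme.score(x, y)
            in_gap_a = in_gap_b = False
        elif x == GAP:
            total += scheme.gap_extend if in_gap_a else scheme.gap_open
            in_gap_a, in_gap_b = True, False
        else:
            total += scheme.gap_extend if in_gap_b else scheme.gap_open
            in_gap_b, in_gap_a = True, False
    return total


def conserved_blocks(
    aln: Alignment, min_identity: float = 0.9, min_len: int = 10
) -> list[tuple[int, int, str]]:
    """Maximal gap-free column runs with majority frequency >= min_identity.

    Returns (start, end, consensus) triples, consensus being the
    per-column majority residue (ties broken alphabetically).
    """
    if aln.nrows == 0 or aln.ncols == 0:
        return []
    good = []
    consensus_chars = []
    for j in range(aln.ncols):
        col = aln.column(j)
        if GAP in col:
            good.append(False)
            consensus_chars.append("")
            continue
        freq: dict[str, int] = {}
        for c in col:
            freq[c] = freq.get(c, 0) + 1
        best = max(sorted(freq), key=lambda c: freq[c])
        good.append(freq[best] / aln.nrows >= min_identity)
        consensus_chars.append(best)
    blocks = []
    i = 0
    while i < aln.ncols:
        if good[i]:
            j = i
            while j < aln.ncols and good[j]:
                j += 1
            if j - i >= min_len:
                blocks.append((i, j, "".join(consensus_chars[i:j])))
            i = j
        else:
            i += 1
    return blocks
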