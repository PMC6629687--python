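"""Distance-based phylogenetics: p-distances, Poisson correction,
Neighbour-Joining, bootstrap and majority-rule consensus.

The observed proportion of differing sites p is converted to an expected
number of substitutions per site by the Poisson correction
d = -ln(1 - p), which assumes equal rates among sites and no repeated
substitution bias; p >= the saturation cap (default 0.95) is an error so
that rogue, saturated sequences surface instead of producing infinite
distances.

Neighbour-Joining follows Saitou & Nei's agglomeration: at each step the
pair minimizing Q(i,j) = (n-2) d(i,j) - R_i - R_j (R = row sums) is
joined; ties are broken on the smallest (i, j) index pair.  A negative
branch length is clamped to zero and the deficit moved to the sibling
edge, keeping the path length between the joined taxa intact.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .alignment import Alignment
from .tree import PhyloTree, TreeError, TreeNode

log = logging.getLogger(__name__)

X_INDEX = 20
GAP_INDEX = 21
SATURATION_CAP = 0.95


class DistanceError(ValueError):
    """Raised for undefined or saturated distances."""


class DistanceMatrix:
    """Symmetric pairwise distances with an ordered id list."""

    def __init__(self, ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise DistanceError("matrix shape does not match id count")
        if not np.allclose(values, values.T, atol=1e-12):
            raise DistanceError("distance matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise DistanceError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise DistanceError("distances must be finite and non-negative")
        self.ids = list(ids)
        self.values = values

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.ids.index(p) for p in pair)
        return float(self.values[i, j])

    def __len__(self) -> int:
        return len(self.ids)


def _comparable_mask(mat: np.ndarray) -> np.ndarray:
    return (mat != GAP_INDEX) & (mat != X_INDEX)


def p_distance_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing sites per pair.

    Sites with a gap or X in either row (``pairwise`` deletion) or in any
    row (``complete``) are excluded from the comparison.
    """
    if aln.nrows < 2:
        raise DistanceError("need at least 2 rows")
    if deletion not in ("pairwise", "complete"):
        raise DistanceError(f"unknown deletion policy {deletion!r}")
    mat = aln.to_matrix()
    ok = _comparable_mask(mat)
    if deletion == "complete":
        keep = ok.all(axis=0)
        mat = mat[:, keep]
        ok = ok[:, keep]
    n = aln.nrows
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise DistanceError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            diff = int(((mat[i] != mat[j]) & both).sum())
            out[i, j] = out[j, i] = diff / m
    return DistanceMatrix(aln.ids, out)


def poisson_correct(p: float, cap: float = SATURATION_CAP) -> float:
    """Poisson-corrected distance d = -ln(1 - p)."""
    if p < 0:
        raise DistanceError(f"negative p-distance {p}")
    if p >= cap:
        raise DistanceError(f"saturated distance: p = {p} >= cap {cap}")
    return -math.log1p(-p)


def poisson_distance_matrix(
    aln: Alignment, deletion: str = "pairwise", cap: float = SATURATION_CAP
) -> DistanceMatrix:
    pmat = p_distance_matrix(aln, deletion)
    vals = pmat.values
    if np.any(vals >= cap):
        i, j = np.argwhere(vals >= cap)[0]
        raise DistanceError(
            f"saturated distance between {pmat.ids[i]!r} and {pmat.ids[j]!r}"
            f" (p = {vals[i, j]:.3f})"
        )
    return DistanceMatrix(pmat.ids, -np.log1p(-vals))


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbour-Joining tree (unrooted; trifurcating root for n >= 3)."""
    n = len(dm)
    if n < 2:
        raise TreeError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    if n == 2:
        root = TreeNode()
        d = float(dm.values[0, 1])
        for node in nodes:
            node.length = d / 2
            root.add_child(node)
        return PhyloTree(root)

    d = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties on smallest (i, j) position pair
        flat = np.argmin(q)
        qmin = q.flat[flat]
        ties = np.argwhere(q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        ai, aj = min((int(a), int(b)) for a, b in ties if a < b)
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances to the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final three nodes joined at the (unrooted) trifurcating root
    a, b, c = active
    root = TreeNode()
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = float(max(length, 0.0))
        root.add_child(node)
    return PhyloTree(root)


def bootstrap_trees(
    aln: Alignment,
    n_reps: int,
    seed: int,
    deletion: str = "pairwise",
    cap: float = SATURATION_CAP,
) -> list[PhyloTree]:
    """NJ trees on column-resampled (with replacement) alignments.

    Replicates in which some pair becomes saturated or incomparable are
    dropped (with a warning) rather than aborting the whole analysis.
    """
    rng = np.random.default_rng(seed)
    mat = aln.to_matrix()
    ncols = aln.ncols
    trees: list[PhyloTree] = []
    dropped = 0
    from .alignment import ALN_ALPHABET

    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rows = ["".join(ALN_ALPHABET[k] for k in mat[r, cols]) for r in range(aln.nrows)]
        rep = Alignment(aln.ids, rows)
        try:
            dmat = poisson_distance_matrix(rep, deletion=deletion, cap=cap)
        except DistanceError as exc:
            dropped += 1
            log.warning("bootstrap replicate dropped: %s", exc)
            continue
        trees.append(nj_tree(dmat))
    if dropped:
        log.warning("%d of %d bootstrap replicates dropped", dropped, n_reps)
    return trees


def majority_consensus(trees: list[PhyloTree], cutoff_pct: float = 50.0) -> PhyloTree:
    """Majority-rule consensus with per-edge support percentages.

    Contains exactly the non-trivial bipartitions present in more than
    *cutoff_pct* percent of the input trees; for cutoff >= 50 these are
    mutually compatible by construction.
    """
    if not trees:
        raise TreeError("need at least one tree")
    taxa = set(trees[0].leaf_names())
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        if set(t.leaf_names()) != taxa:
            raise TreeError("trees have differing leaf sets")
        for bip in t.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    n = len(trees)
    keep = {
        bip: 100.0 * c / n
        for bip, c in counts.items()
        if 100.0 * c / n > cutoff_pct
    }
    ref = min(taxa)
    # root at the reference leaf; every kept side is then a clade
    root = TreeNode()
    root.add_child(TreeNode(name=ref))
    inner = root.add_child(TreeNode())
    nodes: dict[TreeNode, set[str]] = {}
    for name in sorted(taxa - {ref}):
        leaf = inner.add_child(TreeNode(name=name))
        nodes[leaf] = {name}
    nodes[inner] = taxa - {ref}
    for bip in sorted(keep, key=len):
        side = set(bip)
        # deepest node whose clade contains the side
        host = inner
        changed = True
        while changed:
            changed = False
            for child in host.children:
                if not child.is_leaf and side < nodes.get(child, set()):
                    host = child
                    changed = True
                    break
        grouped = [c for c in host.children if nodes.get(c, {c.name}) <= side]
        covered = set().union(*(nodes.get(c, {c.name}) for c in grouped)) if grouped else set()
        if covered != side:
            continue  # incompatible with an earlier (larger-support) edge
        for c in grouped:
            host.children.remove(c)
        new = host.add_child(TreeNode(support=keep[bip]))
        for c in grouped:
            new.add_child(c)
        nodes[new] = set(side)
    return PhyloTree(root)
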