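"""Phylogenetic tree container, Newick I/O and bipartition utilities.

Trees are stored rooted for traversal but carry unrooted semantics: all
comparisons (bipartitions, Robinson–Foulds) treat the root as a display
artifact.  Branch lengths are expected substitutions per site; internal
nodes may carry either a clade *name* (used by the simulator to label
groups) or a bootstrap *support* percentage (written as the internal node
label in Newick, the convention most tree viewers understand).

Newick parsing is delegated to dendropy; a numeric internal-node label is
interpreted as support, anything else as a clade name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import dendropy


class TreeError(ValueError):
    """Raised for malformed trees or incompatible leaf sets."""


@dataclass(eq=False)  # identity semantics: nodes are hashable tree positions
class TreeNode:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False)

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()


class PhyloTree:
    """Rooted container with unrooted comparison semantics."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- basic queries ---------------------------------------------------
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        names = [n.name for n in self.leaves()]
        if any(n is None for n in names):
            raise TreeError("tree has unnamed leaves")
        if len(set(names)) != len(names):
            raise TreeError("leaf labels are not unique")
        return names  # type: ignore[return-value]

    def find(self, name: str) -> TreeNode | None:
        for n in self.root.preorder():
            if n.name == name:
                return n
        return None

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(name=node.name, length=node.length, support=node.support)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root))

    # -- bipartitions ----------------------------------------------------
    def _clades(self) -> dict[TreeNode, frozenset[str]]:
        clades: dict[TreeNode, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                clades[node] = frozenset([node.name])  # type: ignore[list-item]
            else:
                clades[node] = frozenset().union(*(clades[c] for c in node.children))
        return clades

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the side excluding a fixed
        reference leaf (the lexicographically smallest label)."""
        return set(self.bipartition_nodes().keys())

    def bipartition_nodes(self) -> dict[frozenset[str], TreeNode]:
        """Map each non-trivial bipartition to the child-end node of its
        edge (for length/support lookup)."""
        taxa = frozenset(self.leaf_names())
        ref = min(taxa)
        clades = self._clades()
        out: dict[frozenset[str], TreeNode] = {}
        for node, clade in clades.items():
            if node is self.root:
                continue
            side = clade if ref not in clade else taxa - clade
            if 2 <= len(side) <= len(taxa) - 2:
                out.setdefault(side, node)
        return out

    def edge_lengths(self) -> dict[frozenset[str], float]:
        """Branch lengths keyed by the leaf set below each edge, including
        trivial (leaf) edges; a degree-2 root merges its two half-edges."""
        taxa = frozenset(self.leaf_names())
        ref = min(taxa)
        clades = self._clades()
        out: dict[frozenset[str], float] = {}
        for node, clade in clades.items():
            if node is self.root or node.length is None:
                continue
            side = clade if ref not in clade else taxa - clade
            if len(side) in (0, len(taxa)):
                continue
            out[side] = out.get(side, 0.0) + node.length
        return out

    # -- serialization ---------------------------------------------------
    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                if node.support is not None:
                    label = format(node.support, "g")
                elif node.name:
                    label = node.name
                else:
                    label = ""
                body = f"({inner}){label}"
            if lengths and node.length is not None:
                body += f":{node.length:.10g}"
            return body

        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return f"PhyloTree({self.to_newick()})"


def newick_write(tree: PhyloTree, lengths: bool = True) -> str:
    return tree.to_newick(lengths=lengths)


def newick_parse(text: str) -> PhyloTree:
    """Parse Newick text; numeric internal labels become supports."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> TreeNode:
        node = TreeNode(length=dnode.edge.length)
        if dnode.is_leaf():
            node.name = dnode.taxon.label if dnode.taxon else dnode.label
        elif dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                node.name = dnode.label
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric difference of the non-trivial bipartition sets."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise TreeError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def path_distance_matrix(tree: PhyloTree) -> tuple[list[str], list[list[float]]]:
    """Leaf-to-leaf path-length distances (the additive matrix)."""
    # undirected adjacency over nodes
    adj: dict[int, list[tuple[TreeNode, float]]] = {}
    nodes = list(tree.root.preorder())
    for node in nodes:
        for child in node.children:
            w = child.length if child.length is not None else 0.0
            adj.setdefault(id(node), []).append((child, w))
            adj.setdefault(id(child), []).append((node, w))
    leaves = tree.leaves()
    names = [lf.name for lf in leaves]
    dist = [[0.0] * len(leaves) for _ in leaves]
    index = {id(lf): k for k, lf in enumerate(leaves)}
    for k, start in enumerate(leaves):
        seen = {id(start)}
        stack = [(start, 0.0)]
        while stack:
            node, d = stack.pop()
            if id(node) in index and node is not start:
                dist[k][index[id(node)]] = d
            for nxt, w in adj.get(id(node), []):
                if id(nxt) not in seen:
                    seen.add(id(nxt))
                    stack.append((nxt, d + w))
    # exact symmetry (the two traversal directions can differ by rounding)
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            dist[j][i] = dist[i][j]
    return names, dist  # type: ignore[return-value]


def all_unrooted_topologies(labels: list[str]) -> list[PhyloTree]:
    """Every unrooted binary topology over *labels* ((2n-5)!! trees).

    Built by stepwise leaf insertion on every edge; the root is the
    initial trifurcation, so trees are unrooted-binary throughout.
    """
    if len(labels) < 3:
        raise TreeError("need at least 3 labels")

    def base() -> PhyloTree:
        root = TreeNode()
        for lab in labels[:3]:
            root.add_child(TreeNode(name=lab))
        return PhyloTree(root)

    trees = [base()]
    for lab in labels[3:]:
        nxt: list[PhyloTree] = []
        for t in trees:
            edges = [n for n in t.root.preorder() if n is not t.root]
            for k in range(len(edges)):
                t2 = t.copy()
                target = [n for n in t2.root.preorder() if n is not t2.root][k]
                parent = target.parent
                assert parent is not None
                parent.children.remove(target)
                mid = parent.add_child(TreeNode())
                mid.add_child(target)
                mid.add_child(TreeNode(name=lab))
                nxt.append(t2)
        trees = nxt
    return trees


def reroot_on_edge(tree: PhyloTree, name: str, split: float = 0.5) -> PhyloTree:
    """New tree rooted on the edge above the node called *name*.

    The edge's length is divided *split* / (1 - split) between the two
    root children.  Under a time-reversible model the likelihood is
    invariant under this operation for any edge and any split (the pulley
    principle).  Unifurcations left by moving the old root are collapsed.
    """
    if not 0.0 <= split <= 1.0:
        raise TreeError("split must be in [0, 1]")
    t = tree.copy()
    node = t.find(name)
    if node is None:
        raise TreeError(f"no node called {name!r}")
    if node is t.root:
        return t
    parent = node.parent
    assert parent is not None
    parent.children.remove(node)
    length = node.length if node.length is not None else 0.0
    new_root = TreeNode()
    node.length = length * split
    new_root.add_child(node)
    # invert the parent chain up to the old root
    carry = length * (1.0 - split)
    attach_to = new_root
    cur: TreeNode | None = parent
    while cur is not None:
        nxt = cur.parent
        if nxt is not None:
            nxt.children.remove(cur)
        upstream_len = cur.length
        cur.length = carry
        attach_to.add_child(cur)
        attach_to = cur
        carry = upstream_len if upstream_len is not None else 0.0
        cur = nxt
    _suppress_unifurcations(new_root)
    return PhyloTree(new_root)


def _suppress_unifurcations(root: TreeNode) -> None:
    for node in list(root.postorder()):
        if node is root or len(node.children) != 1:
            continue
        child = node.children[0]
        if node.length is not None or child.length is not None:
            child.length = (node.length or 0.0) + (child.length or 0.0)
        parent = node.parent
        assert parent is not None
        idx = parent.children.index(node)
        parent.children[idx] = child
        child.parent = parent


def assign_random_branch_lengths(
    tree: PhyloTree, draw: Callable[[], float]
) -> None:
    """Set every non-root branch length from *draw* (in place)."""
    for node in tree.root.preorder():
        if node is not tree.root:
            node.length = float(draw())
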