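"""Unrooted phylogenetic trees as flat parent/length arrays.

Trees are stored in a rooted representation whose root is an internal
node of degree three (the standard unrooted convention), so a tree on
``n`` tips has ``2n - 2`` nodes and ``2n - 3`` edges.  Tips occupy node
indices ``0 .. n-1`` in ``taxa`` order; every non-root node carries the
length of the edge to its parent, in expected substitutions per site.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .exceptions import InvalidInputError, ParseError


class PhyloTree:
    """Phylogeny over named tips with branch lengths.

    Parameters
    ----------
    taxa : sequence of str
        Tip names; tip ``i`` is node ``i``.
    parent : array of int
        Parent index per node; the root has parent ``-1``.
    lengths : array of float
        Branch length above each node (ignored for the root).
    """

    def __init__(self, taxa, parent, lengths):
        self.taxa = list(taxa)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        n_nodes = self.parent.size
        if self.lengths.size != n_nodes:
            raise InvalidInputError("parent and lengths must have equal size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise InvalidInputError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n_nodes)]
        for v in range(n_nodes):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        for i in range(self.n_tips):
            if self.children[i]:
                raise InvalidInputError(f"tip node {i} has children")
        self._postorder = self._compute_postorder()

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def total_length(self) -> float:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(self.lengths[mask].sum())

    def _compute_postorder(self) -> np.ndarray:
        order, stack, visited = [], [self.root], []
        while stack:
            v = stack.pop()
            visited.append(v)
            stack.extend(self.children[v])
        return np.asarray(visited[::-1], dtype=np.int64)

    def postorder(self) -> np.ndarray:
        """All node indices, children before parents (root last)."""
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self._postorder[::-1]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.taxa, self.parent.copy(), self.lengths.copy())

    # ------------------------------------------------------------------
    def to_newick(self, precision: int = 10) -> str:
        fmt = f"%.{precision}g"

        def render(v: int) -> str:
            if v < self.n_tips:
                label = self.taxa[v]
            else:
                label = ""
            if self.children[v]:
                inner = ",".join(render(c) for c in self.children[v])
                label = f"({inner})" + label
            if v == self.root:
                return label
            return label + ":" + (fmt % self.lengths[v])

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return render(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, newick: str, taxa_order=None) -> "PhyloTree":
        """Parse a Newick string (underscores preserved in labels).

        A bifurcating root is collapsed so the stored representation is
        unrooted; missing branch lengths default to 0.
        """
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse errors
            raise ParseError(f"could not parse Newick: {exc}") from exc
        seed = dtree.seed_node
        kids = seed.child_nodes()
        if len(kids) == 2:
            # collapse the basal bifurcation: merge the two basal edges
            a, b = kids
            donor, keeper = (a, b) if a.is_leaf() else (b, a)
            if keeper.is_leaf():
                raise ParseError("tree needs at least 3 tips")
            extra = (donor.edge.length or 0.0) + (keeper.edge.length or 0.0)
            seed.remove_child(keeper)
            for c in list(keeper.child_nodes()):
                keeper.remove_child(c)
                seed.add_child(c)
            donor.edge.length = extra
        leaves = [lf for lf in dtree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
        if any(lbl is None for lbl in labels):
            raise ParseError("unlabelled tip in Newick input")
        if len(set(labels)) != len(labels):
            raise ParseError("duplicate tip labels in Newick input")
        if taxa_order is not None:
            if set(taxa_order) != set(labels):
                raise ParseError("tip labels do not match requested taxa order")
            taxa = list(taxa_order)
        else:
            taxa = labels
        tip_index = {name: i for i, name in enumerate(taxa)}
        n_tips = len(taxa)
        n_nodes = n_tips + sum(1 for _ in dtree.preorder_internal_node_iter())
        parent = np.full(n_nodes, -1, dtype=np.int64)
        lengths = np.zeros(n_nodes, dtype=float)
        next_internal = n_tips
        index = {}
        for node in dtree.preorder_node_iter():
            if node.is_leaf():
                lbl = node.taxon.label if node.taxon else node.label
                idx = tip_index[lbl]
            else:
                idx = next_internal
                next_internal += 1
            index[id(node)] = idx
            if node.parent_node is not None:
                parent[idx] = index[id(node.parent_node)]
                lengths[idx] = node.edge.length or 0.0
        return cls(taxa, parent, lengths)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read(cls, path, taxa_order=None) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), taxa_order=taxa_order)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PhyloTree: {self.n_tips} tips, {self.n_edges} edges>"
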