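"""Phylogenetic tree container and newick I/O.

:class:`PhyloTree` is a thin wrapper around a :class:`dendropy.Tree` that
enforces the conventions used throughout the package: unique leaf names,
non-negative branch lengths (negative neighbor-joining estimates are clamped
to zero), and deterministic conversion to/from the flat array form used by
the fast scanning kernels.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "read_newick", "write_newick"]


class PhyloTree:
    """A (rooted or unrooted) tree with branch lengths and named leaves."""

    def __init__(self, dtree: dendropy.Tree, *, clamp_negative: bool = True) -> None:
        self._tree = dtree
        if clamp_negative:
            for edge in dtree.preorder_edge_iter():
                if edge.length is not None and edge.length < 0:
                    edge.length = 0.0
        names = self.leaf_names
        if len(set(names)) != len(names):
            raise ValueError("leaf names must be unique")

    # -- construction --------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"could not parse newick: {exc}") from exc
        return cls(dtree)

    @classmethod
    def from_arrays(
        cls,
        left: np.ndarray,
        right: np.ndarray,
        lengths: np.ndarray,
        root: int,
        leaf_names: Sequence[str],
    ) -> "PhyloTree":
        """Build a rooted tree from child-pointer arrays.

        ``left``/``right`` give the two children of each internal node (-1
        for leaves); nodes ``0..len(leaf_names)-1`` are the leaves;
        ``lengths[i]`` is the branch length above node ``i``.
        """
        ns = dendropy.TaxonNamespace([str(n) for n in leaf_names])
        n_nodes = len(left)
        nodes = [dendropy.Node() for _ in range(n_nodes)]
        for i, name in enumerate(leaf_names):
            nodes[i].taxon = ns.get_taxon(str(name))
        for i in range(n_nodes):
            for child in (left[i], right[i]):
                if child >= 0:
                    nodes[i].add_child(nodes[child])
                    nodes[child].edge.length = float(lengths[child])
        dtree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[root])
        dtree.is_rooted = True
        return cls(dtree)

    @classmethod
    def unrooted_from_edges(
        cls,
        edge_u: np.ndarray,
        edge_v: np.ndarray,
        edge_len: np.ndarray,
        leaf_names: Sequence[str],
    ) -> "PhyloTree":
        """Build an unrooted tree from an undirected edge list.

        Nodes ``0..len(leaf_names)-1`` are leaves.  The highest-numbered
        internal node (the last neighbor-joining agglomeration) is used as
        the display root; the tree is flagged unrooted.
        """
        n_nodes = int(max(edge_u.max(), edge_v.max())) + 1
        adj: list[list[tuple[int, float]]] = [[] for _ in range(n_nodes)]
        for u, v, l in zip(edge_u, edge_v, edge_len):
            adj[int(u)].append((int(v), float(l)))
            adj[int(v)].append((int(u), float(l)))
        ns = dendropy.TaxonNamespace([str(n) for n in leaf_names])
        nodes = [dendropy.Node() for _ in range(n_nodes)]
        for i, name in enumerate(leaf_names):
            nodes[i].taxon = ns.get_taxon(str(name))
        seed = n_nodes - 1
        seen = {seed}
        stack = [seed]
        while stack:
            a = stack.pop()
            for b, l in adj[a]:
                if b not in seen:
                    seen.add(b)
                    nodes[a].add_child(nodes[b])
                    nodes[b].edge.length = l
                    stack.append(b)
        dtree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[seed])
        dtree.is_rooted = False
        return cls(dtree)

    # -- basic queries --------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def is_rooted(self) -> bool:
        return bool(self._tree.is_rooted)

    @property
    def total_branch_length(self) -> float:
        return float(
            sum(e.length or 0.0 for e in self._tree.preorder_edge_iter())
        )

    def midpoint_rooted(self) -> "PhyloTree":
        """Return a copy rooted at the midpoint of the longest leaf-leaf path."""
        t = self._tree.clone(depth=1)
        t.reroot_at_midpoint(update_bipartitions=False)
        t.is_rooted = True
        return PhyloTree(t)

    def edge_descendants(
        self, strain_order: Sequence[str] | None = None
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Branch lengths and descendant leaf-index sets for every branch.

        The seed/root node itself carries no branch.  Leaf indices refer to
        ``strain_order`` (default: this tree's leaf order).
        """
        if strain_order is None:
            strain_order = self.leaf_names
        pos = {name: i for i, name in enumerate(strain_order)}
        lengths: list[float] = []
        desc: list[np.ndarray] = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            lengths.append(node.edge.length or 0.0)
            desc.append(
                np.array(
                    sorted(pos[lf.taxon.label] for lf in node.leaf_iter()),
                    dtype=np.int64,
                )
            )
        return np.asarray(lengths, dtype=float), desc

    # -- serialization --------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        )
        return s.strip() + "\n"

    def __repr__(self) -> str:  # pragma: no cover
        kind = "rooted" if self.is_rooted else "unrooted"
        return f"PhyloTree({self.n_leaves} leaves, {kind})"


def read_newick(path) -> PhyloTree:
    """Read one newick tree from ``path``."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick())
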