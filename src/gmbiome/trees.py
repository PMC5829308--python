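"""Rooted phylogenies as branch/leaf incidence structures.

Phylogenetic diversity and UniFrac-type distances only ever need, for each
branch, (a) its length and (b) the set of leaves that descend from it.
:class:`PhyloTree` therefore flattens a rooted dendropy tree into

* ``branch_lengths`` — one entry per non-root node (the branch above it), and
* ``incidence`` — a boolean (branches x leaves) matrix, ``incidence[b, i]``
  true when leaf ``i`` lies below branch ``b``.

Given per-sample leaf abundances ``p`` (length n_leaves), the abundance
carried by every branch is the single matrix product ``incidence @ p``, which
is what makes whole-cohort distance matrices cheap.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import InvalidArgumentError, MissingLeafError

__all__ = ["PhyloTree", "simulate_tree"]


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, flattened for fast traversal-free
    diversity computations.

    Attributes
    ----------
    leaf_names:
        Leaf labels in a fixed order; columns of ``incidence`` follow it.
    branch_lengths:
        Length of the branch subtending each non-root node, ``>= 0``.
    incidence:
        Boolean (n_branches, n_leaves) descendant matrix.
    newick:
        The serialized form this tree was built from (round-trip anchor).
    """

    leaf_names: list[str]
    branch_lengths: np.ndarray
    incidence: np.ndarray
    newick: str = field(repr=False, default="")

    def __post_init__(self):
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.incidence.shape != (self.branch_lengths.size, len(self.leaf_names)):
            raise InvalidArgumentError("incidence shape inconsistent with branches/leaves")
        if not np.all(np.isfinite(self.branch_lengths)):
            raise InvalidArgumentError("branch lengths must be finite")
        if np.any(self.branch_lengths < 0):
            raise InvalidArgumentError("branch lengths must be non-negative")

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        """Flatten a rooted dendropy tree.

        A missing branch length is treated as 0 (legal: zero-length branches
        contribute nothing to PD or UniFrac sums).
        """
        leaves = [lf for lf in tree.leaf_node_iter()]
        leaf_names = [lf.taxon.label if lf.taxon else str(id(lf)) for lf in leaves]
        if len(set(leaf_names)) != len(leaf_names):
            raise InvalidArgumentError("duplicate leaf labels in tree")
        leaf_index = {lf: i for i, lf in enumerate(leaves)}

        lengths: list[float] = []
        rows: list[np.ndarray] = []
        below: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(len(leaves), dtype=bool)
                mask[leaf_index[node]] = True
            else:
                mask = np.zeros(len(leaves), dtype=bool)
                for ch in node.child_nodes():
                    mask |= below[ch]
            below[node] = mask
            if node.parent_node is not None:  # non-root: has a branch above
                lengths.append(node.edge.length or 0.0)
                rows.append(mask)
        newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
        return cls(leaf_names, np.array(lengths), np.array(rows), newick=newick)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick.rstrip("\n") + "\n")

    # -- queries ------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_branches(self) -> int:
        return self.branch_lengths.size

    def leaf_indices(self, names) -> np.ndarray:
        """Map leaf labels to column indices; unknown labels raise
        :class:`MissingLeafError` listing every offender."""
        pos = {n: i for i, n in enumerate(self.leaf_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise MissingLeafError(missing)
        return np.array([pos[n] for n in names], dtype=int)

    def branch_loads(self, abundances: np.ndarray) -> np.ndarray:
        """Per-branch abundance totals for one or many samples.

        ``abundances`` has leaves on its last axis, ordered as
        ``leaf_names``; returns loads with branches on the last axis.
        """
        A = np.asarray(abundances, dtype=float)
        return A @ self.incidence.T.astype(float)


def simulate_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Simulate a rooted binary tree under a pure-birth (Yule) process.

    Topology grows by splitting a uniformly chosen extant lineage until
    ``n_taxa`` tips exist; every branch then receives an independent
    Exponential(1) length. This is the simplest generator whose trees give
    non-degenerate UniFrac geometry (no zero branches, no polytomies).
    Leaves are labelled ``OTU_0001`` ... in a deterministic order, and the
    same seed always yields a byte-identical newick string.
    """
    if n_taxa < 2:
        raise InvalidArgumentError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tips = [tree.seed_node]
    while len(tips) < n_taxa:
        parent = tips.pop(int(rng.integers(len(tips))))
        children = [dendropy.Node(), dendropy.Node()]
        for ch in children:
            parent.add_child(ch)
        tips.extend(children)

    # label leaves in a stable (traversal) order, then draw branch lengths
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            i += 1
            node.taxon = taxa.new_taxon(f"OTU_{i:04d}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.exponential(1.0))
    return PhyloTree.from_dendropy(tree)
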