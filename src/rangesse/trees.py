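"""Indexed views of time-calibrated trees for the pruning machinery.

Likelihood, reconstruction and simulation all operate on a flat, array-based
view of a rooted binary tree: nodes numbered in post-order (children before
parents, tips included), ages measured backwards from the present (t = 0 at
the youngest tip), and per-node parent/child indices.  dendropy handles all
Newick parsing and serialization; this module only validates and indexes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["IndexedTree", "index_tree", "read_newick", "write_newick", "TreeValidationError"]

# relative ultrametricity slack: empirical chronograms carry rounding noise
ULTRAMETRIC_RTOL = 1e-3


class TreeValidationError(ValueError):
    """Raised when a tree violates the model's structural requirements."""


@dataclass
class IndexedTree:
    """Post-order-indexed rooted binary tree with ages in time before present."""

    n_tips: int
    n_nodes: int
    parent: np.ndarray  # int, -1 at the root
    left: np.ndarray  # int, -1 at tips
    right: np.ndarray  # int, -1 at tips
    ages: np.ndarray  # float, time before present (0 at the youngest tip)
    branch_lengths: np.ndarray  # edge above each node; 0 at the root
    tip_labels: tuple[str, ...]  # tip_labels[i] is the label of node i (i < n_tips? no: see tip_index)
    tip_index: dict[str, int]  # label -> node id

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.left >= 0)

    @property
    def tips(self) -> np.ndarray:
        return np.flatnonzero(self.left < 0)

    def is_tip(self, node: int) -> bool:
        return self.left[node] < 0

    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    def label_of(self, node: int) -> str:
        for lab, i in self.tip_index.items():
            if i == node:
                return lab
        return f"node{node}"


def index_tree(tree: dendropy.Tree, require_ultrametric: bool = False) -> IndexedTree:
    """Validate a dendropy tree and build its post-order array view.

    Requires a rooted binary topology with non-negative branch lengths on
    every non-root edge.  Departures from ultrametricity larger than
    ``ULTRAMETRIC_RTOL`` times the tree height draw a warning (or an error if
    ``require_ultrametric``), since branch lengths are read as absolute time.
    """
    nodes = list(tree.postorder_node_iter())
    n_nodes = len(nodes)
    if n_nodes < 3:
        raise TreeValidationError("tree must have at least 2 tips")
    ids = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    depth = np.zeros(n_nodes)
    tip_labels: list[str] = []
    tip_index: dict[str, int] = {}
    for i, nd in reversed(list(enumerate(nodes))):  # root-first for depths
        children = nd.child_nodes()
        if len(children) not in (0, 2):
            name = nd.taxon.label if nd.taxon else (nd.label or f"node{i}")
            raise TreeValidationError(
                f"node {name!r} has {len(children)} children; the model requires a binary tree"
            )
        if children:
            left[i], right[i] = ids[id(children[0])], ids[id(children[1])]
            parent[left[i]] = i
            parent[right[i]] = i
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise TreeValidationError("every non-root edge needs a branch length")
            if nd.edge.length < 0:
                raise TreeValidationError(f"negative branch length {nd.edge.length}")
            blen[i] = float(nd.edge.length)
            depth[i] = depth[ids[id(nd.parent_node)]] + blen[i]
        if not children:
            if nd.taxon is None or not nd.taxon.label:
                raise TreeValidationError("every tip needs a label")
            lab = nd.taxon.label
            if lab in tip_index:
                raise TreeValidationError(f"duplicate tip label {lab!r}")
            tip_index[lab] = i
            tip_labels.append(lab)
    height = depth.max()
    ages = height - depth
    tip_ids = np.flatnonzero(left < 0)
    spread = float(ages[tip_ids].max())
    if height > 0 and spread > ULTRAMETRIC_RTOL * height:
        msg = (
            f"tree deviates from ultrametric by {spread:.4g} "
            f"({spread / height:.2%} of tree height)"
        )
        if require_ultrametric:
            raise TreeValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    # snap tiny tip-age jitter to zero so epoch boundaries stay clean
    ages[np.abs(ages) < 1e-12 * max(height, 1.0)] = 0.0
    return IndexedTree(
        n_tips=len(tip_ids),
        n_nodes=n_nodes,
        parent=parent,
        left=left,
        right=right,
        ages=ages,
        branch_lengths=blen,
        tip_labels=tuple(tip_labels),
        tip_index=tip_index,
    )


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree, preserving node labels."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as err:  # dendropy parse errors vary by class
        raise TreeValidationError(f"could not parse Newick file {path}: {err}") from err
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)
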