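"""Internal helpers shared by the diversity and congruence modules.

Everything here reduces a rooted :class:`dendropy.Tree` to arrays: a
branch incidence matrix (branch x tip membership), branch lengths, node
depths, and the Brownian-motion covariance (shared root-to-MRCA path
length) matrix.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def branch_incidence(
    tree: dendropy.Tree,
    tip_order: Sequence[str] | None = None,
    require_lengths: bool = True,
):
    """Return ``(lengths, incidence, order)`` for all non-root branches.

    ``incidence[e, t]`` is True when tip ``t`` descends through branch
    ``e``.  ``lengths[e]`` is the branch length (missing lengths raise
    unless ``require_lengths`` is False, in which case they count as 0).
    """
    labels = tip_labels(tree)
    if tip_order is None:
        tip_order = labels
    index = {lab: i for i, lab in enumerate(tip_order)}
    missing = [lab for lab in labels if lab not in index]
    if missing:
        raise KeyError(f"tree tips missing from requested order: {missing}")
    n_tips = len(tip_order)
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            node._mask = getattr(node, "_mask", None)
            continue
        mask = np.zeros(n_tips, dtype=bool)
        if node.is_leaf():
            mask[index[node.taxon.label]] = True
        else:
            for child in node.child_nodes():
                mask |= child._mask
        node._mask = mask
        length = node.edge.length
        if length is None:
            if require_lengths:
                raise ValueError(
                    "tree has branches without lengths; lengths are required here"
                )
            length = 0.0
        lengths.append(float(length))
        rows.append(mask)
    for node in tree.postorder_node_iter():  # drop scratch attribute
        if hasattr(node, "_mask"):
            del node._mask
    if rows:
        incidence = np.vstack(rows)
    else:
        incidence = np.zeros((0, n_tips), dtype=bool)
    return np.asarray(lengths, dtype=float), incidence, list(tip_order)


def patristic_matrix(tree: dendropy.Tree, tip_order: Sequence[str] | None = None):
    """Tip-to-tip path-length matrix (sum of branch lengths)."""
    lengths, inc, order = branch_incidence(tree, tip_order, require_lengths=True)
    weighted = inc * lengths[:, None]
    shared = weighted.T @ inc  # shared root-to-MRCA path length
    depth = weighted.sum(axis=0)
    dist = depth[:, None] + depth[None, :] - 2.0 * shared
    np.fill_diagonal(dist, 0.0)
    return dist, order


def vcv_matrix(tree: dendropy.Tree, tip_order: Sequence[str] | None = None):
    """Brownian-motion covariance: V[i, j] = shared root-to-MRCA path length."""
    lengths, inc, order = branch_incidence(tree, tip_order, require_lengths=True)
    weighted = inc * lengths[:, None]
    vcv = weighted.T @ inc
    return vcv, order


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Distance from the root to each node (missing lengths count as 0)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())
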