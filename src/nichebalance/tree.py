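"""Bifurcating trees: newick I/O, validation, and UPGMA from a niche vector.

Trees are ``skbio.TreeNode`` objects.  Everything downstream requires a
strictly binary rooted tree whose tips are feature identifiers and whose
internal nodes carry unique names; by convention internal nodes are
labelled ``y0, y1, ...`` in level order from the root, matching how the
balances they define are usually referred to (y0 = the root balance).

The niche-driven construction clusters features by average linkage
(UPGMA) on the absolute difference of their mean niche values (e.g. mean
pH).  Within every merge the cluster with the larger mean niche is
placed as the first (numerator) child, so the root balance reads
"high-niche features over low-niche features".  Merge order is fully
deterministic: distance ties are broken by the lexicographically
smallest feature identifier contained in each candidate pair.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "read_newick",
    "write_newick",
    "validate_bifurcating",
    "name_internal_nodes",
    "internal_nodes_levelorder",
    "subtree_tip_sets",
    "upgma_from_niche",
    "random_binary_tree",
]


def validate_bifurcating(tree: TreeNode, feature_ids=None) -> None:
    """Raise unless the tree is strictly binary with unique tip labels.

    If ``feature_ids`` is given, additionally require the tip set to equal
    it exactly (the error lists the symmetric difference).
    """
    tips = []
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            if node.name is None:
                raise ValueError("tree has an unlabelled tip")
            tips.append(node.name)
        elif len(node.children) != 2:
            label = node.name if node.name is not None else "<unnamed>"
            raise ValueError(
                f"tree is not strictly binary: node {label!r} has "
                f"{len(node.children)} children"
            )
    if len(set(tips)) != len(tips):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    if feature_ids is not None:
        want = set(feature_ids)
        have = set(tips)
        if want != have:
            raise ValueError(
                "tree tips do not match the feature set; "
                f"only in tree: {sorted(have - want)}; "
                f"only in features: {sorted(want - have)}"
            )


def internal_nodes_levelorder(tree: TreeNode) -> list[TreeNode]:
    """Internal nodes in breadth-first order from the root."""
    return [n for n in tree.levelorder(include_self=True) if not n.is_tip()]


def name_internal_nodes(tree: TreeNode, prefix: str = "y", overwrite: bool = False) -> TreeNode:
    """Label internal nodes ``y0, y1, ...`` in level order from the root.

    Existing names are kept unless ``overwrite`` is set.  Returns the tree
    for chaining (the tree is modified in place).
    """
    for i, node in enumerate(internal_nodes_levelorder(tree)):
        if overwrite or node.name is None:
            node.name = f"{prefix}{i}"
    return tree


def read_newick(source) -> TreeNode:
    """Parse a newick tree and validate it for balance analysis.

    ``source`` may be a newick string, a file path, or a file handle.
    The tree must resolve to strictly binary; unnamed internal nodes are
    assigned level-order names ``y0, y1, ...``.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        tree = TreeNode.read(io.StringIO(source))
    else:
        tree = TreeNode.read(source)
    validate_bifurcating(tree)
    return name_internal_nodes(tree)


def write_newick(tree: TreeNode, path=None) -> str | None:
    """Serialise to newick (internal labels after the closing parenthesis)."""
    if path is None:
        buf = io.StringIO()
        tree.write(buf)
        return buf.getvalue().strip()
    tree.write(str(path))
    return None


def subtree_tip_sets(tree: TreeNode, node) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Numerator and denominator tip labels of an internal node.

    ``node`` may be a TreeNode or an internal-node name.  The first
    element holds the tips of the node's first child (the numerator of
    its balance), the second those of its second child; the two sets are
    disjoint and their union is the node's clade.
    """
    if not isinstance(node, TreeNode):
        node = tree.find(node)
    if node.is_tip():
        raise ValueError(f"node {node.name!r} is a tip, not an internal node")
    first, second = node.children
    num = (first.name,) if first.is_tip() else tuple(t.name for t in first.tips())
    den = (second.name,) if second.is_tip() else tuple(t.name for t in second.tips())
    return num, den


def _tie_key(members_i, members_j):
    """Deterministic sort key for a candidate merge pair."""
    a, b = sorted((min(members_i), min(members_j)))
    return (a, b)


def upgma_from_niche(niche: pd.Series, higher_first: bool = True) -> TreeNode:
    """Average-linkage clustering of features along a 1-D niche gradient.

    Parameters
    ----------
    niche : pandas.Series
        Mean niche value (e.g. mean pH) per feature identifier.  All
        values must be finite; at least two features are required.
    higher_first : bool
        If True (default) every merge places the child cluster with the
        larger mean niche value first, so each balance contrasts
        high-niche features (numerator) over low-niche features
        (denominator).  Set False to flip the orientation globally.

    Returns
    -------
    skbio.TreeNode
        Strictly binary rooted tree with internal nodes named ``y0..``
        in level order and cophenetic branch lengths (half the merge
        distance; retained for reference, the balances depend only on
        the topology).

    Notes
    -----
    The pairwise distance is ``|niche_x - niche_y|``, the only natural
    metric on a one-dimensional gradient.  Equal-distance ties are broken
    towards the pair containing the lexicographically smallest feature
    identifier, making the output byte-reproducible.
    """
    if len(niche) < 2:
        raise ValueError("upgma_from_niche: need at least 2 features")
    if niche.index.has_duplicates:
        raise ValueError("upgma_from_niche: duplicate feature identifiers")
    bad = [str(f) for f, v in niche.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"upgma_from_niche: non-finite niche values for {bad}")

    labels = [str(f) for f in niche.index]
    values = niche.to_numpy(dtype=float)
    n = len(labels)

    # active cluster state, indexed 0..n-1 then n.. for merged clusters
    nodes = {i: TreeNode(name=labels[i], length=None) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    means = {i: float(values[i]) for i in range(n)}
    members = {i: [labels[i]] for i in range(n)}
    heights = {i: 0.0 for i in range(n)}

    active = list(range(n))
    dist = np.abs(values[:, None] - values[None, :]).astype(float)
    # grow the matrix as merges append new cluster rows
    size_cap = 2 * n - 1
    full = np.full((size_cap, size_cap), np.inf)
    full[:n, :n] = dist
    np.fill_diagonal(full, np.inf)

    next_id = n
    while len(active) > 1:
        idx = np.array(active)
        sub = full[np.ix_(idx, idx)]
        dmin = sub.min()
        ii, jj = np.nonzero(sub == dmin)
        best = None
        best_key = None
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            ca, cb = idx[a], idx[b]
            key = _tie_key(members[ca], members[cb])
            if best_key is None or key < best_key:
                best_key = key
                best = (ca, cb)
        ca, cb = best

        # orientation: numerator child = larger mean niche
        pair = sorted((ca, cb), key=lambda c: (-means[c], min(members[c])))
        if not higher_first:
            pair = pair[::-1]
        first, second = pair
        height = dmin / 2.0
        for child in (first, second):
            nodes[child].length = max(height - heights[child], 0.0)
        parent = TreeNode(children=[nodes[first], nodes[second]])
        nodes[next_id] = parent
        heights[next_id] = height
        sizes[next_id] = sizes[ca] + sizes[cb]
        members[next_id] = members[ca] + members[cb]
        means[next_id] = (
            means[ca] * sizes[ca] + means[cb] * sizes[cb]
        ) / sizes[next_id]

        # average-linkage update against all remaining clusters
        rest = [c for c in active if c not in (ca, cb)]
        for c in rest:
            full[next_id, c] = full[c, next_id] = (
                sizes[ca] * full[ca, c] + sizes[cb] * full[cb, c]
            ) / (sizes[ca] + sizes[cb])
        active = rest + [next_id]
        for gone in (ca, cb):
            del nodes[gone]
        next_id += 1

    root = nodes[active[0]]
    root.length = None
    return name_internal_nodes(root, overwrite=True)


def random_binary_tree(feature_ids, rng) -> TreeNode:
    """Uniform-ish random strictly binary tree over the given tips.

    Repeatedly joins two clusters chosen at random until one remains;
    used for property testing (basis orthonormality, tree invariance of
    fit statistics).  ``rng`` is a numpy Generator.
    """
    feature_ids = [str(f) for f in feature_ids]
    if len(feature_ids) < 2:
        raise ValueError("random_binary_tree: need at least 2 features")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError("random_binary_tree: duplicate feature identifiers")
    clusters = [TreeNode(name=f) for f in feature_ids]
    while len(clusters) > 1:
        i, j = rng.choice(len(clusters), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        b = clusters.pop(j)
        a = clusters.pop(i)
        clusters.append(TreeNode(children=[a, b]))
    return name_internal_nodes(clusters[0], overwrite=True)
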