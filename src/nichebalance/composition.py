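"""Compositional geometry on the Aitchison simplex.

Closure, pseudocount zero-replacement, the centred log-ratio (clr)
transform, and the isometric log-ratio (ILR) transform driven by a
bifurcating tree.  A strictly binary tree over the D features defines a
sequential binary partition: each of its D-1 internal nodes contrasts the
features of its first (numerator) subtree against those of its second
(denominator) subtree.  The balance at node *i* for a composition x is

    b_i = sqrt(r*s / (r + s)) * ln( g(x_num) / g(x_den) )

where r and s are the numbers of tips in the numerator and denominator
subtrees and g() is the geometric mean.  The same numbers arise as the
inner product of clr(x) with an orthonormal basis row carrying
``+sqrt(s / (r*(r+s)))`` on numerator tips and ``-sqrt(r / (s*(r+s)))``
on denominator tips; both routes are exposed here and agree to machine
precision.

Tables are pandas DataFrames with samples as rows and features as
columns.  All operations preserve label alignment and raise on
misaligned inputs rather than silently reordering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tree import internal_nodes_levelorder, subtree_tip_sets, validate_bifurcating

__all__ = [
    "closure",
    "add_pseudocount",
    "clr_transform",
    "build_ilr_basis",
    "ilr_transform",
    "balances_direct",
    "inverse_ilr",
    "perturbation",
    "power",
]


def _as_frame(x) -> tuple[pd.DataFrame, bool]:
    """Coerce a vector / array / DataFrame to a 2-D DataFrame.

    Returns the frame and a flag saying whether the input was 1-D, so the
    caller can squeeze the result back.
    """
    if isinstance(x, pd.DataFrame):
        return x, False
    if isinstance(x, pd.Series):
        return x.to_frame().T, True
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return pd.DataFrame(arr[None, :]), True
    if arr.ndim == 2:
        return pd.DataFrame(arr), False
    raise ValueError(f"expected a vector or matrix, got {arr.ndim} dimensions")


def closure(x):
    """Normalise each row of a non-negative table to proportions summing to 1.

    Parameters
    ----------
    x : vector, array or DataFrame
        Non-negative abundances (counts or proportions), samples as rows.

    Returns
    -------
    Same shape/type as the input, rows summing to 1.

    Raises
    ------
    ValueError
        If any entry is negative or a row is entirely zero (the offending
        sample is named in the message).
    """
    frame, squeeze = _as_frame(x)
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("closure: input contains missing values")
    if (values < 0).any():
        raise ValueError("closure: negative abundances are not allowed")
    totals = values.sum(axis=1)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        names = [str(frame.index[i]) for i in dead]
        raise ValueError(f"closure: all-zero rows for samples {names}")
    out = pd.DataFrame(values / totals[:, None], index=frame.index, columns=frame.columns)
    if squeeze:
        return out.iloc[0] if isinstance(x, pd.Series) else out.to_numpy()[0]
    return out if isinstance(x, pd.DataFrame) else out.to_numpy()


def add_pseudocount(table, c: float = 1.0):
    """Add a constant pseudocount to every entry of a count table.

    The default ``c=1`` makes every log ratio finite in the presence of
    sampling zeros.  ``c`` must be strictly positive.
    """
    if not np.isfinite(c) or c <= 0:
        raise ValueError(f"pseudocount must be > 0, got {c}")
    frame, squeeze = _as_frame(table)
    values = frame.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("add_pseudocount: negative abundances are not allowed")
    out = pd.DataFrame(values + c, index=frame.index, columns=frame.columns)
    if squeeze:
        return out.iloc[0] if isinstance(table, pd.Series) else out.to_numpy()[0]
    return out if isinstance(table, pd.DataFrame) else out.to_numpy()


def _require_positive(frame: pd.DataFrame, op: str) -> np.ndarray:
    values = frame.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values <= 0).any():
        raise ValueError(
            f"{op}: table must be strictly positive; add a pseudocount "
            "(add_pseudocount) before closure to handle zero counts"
        )
    return values


def clr_transform(table):
    """Centred log-ratio transform: ln of each part over the row geometric mean."""
    frame, squeeze = _as_frame(table)
    values = _require_positive(frame, "clr_transform")
    logs = np.log(values)
    out = pd.DataFrame(logs - logs.mean(axis=1, keepdims=True),
                       index=frame.index, columns=frame.columns)
    if squeeze:
        return out.iloc[0] if isinstance(table, pd.Series) else out.to_numpy()[0]
    return out if isinstance(table, pd.DataFrame) else out.to_numpy()


def build_ilr_basis(tree, feature_ids=None) -> pd.DataFrame:
    """Build the orthonormal ILR basis defined by a bifurcating tree.

    Every internal node *l* with r tips in its numerator (first) subtree
    and s tips in its denominator (second) subtree contributes one
    clr-space basis row with ``sqrt(s / (r*(r+s)))`` on numerator tips,
    ``-sqrt(r / (s*(r+s)))`` on denominator tips and zero elsewhere.
    Rows are ordered by level order from the root, so the root contrast
    comes first.

    Parameters
    ----------
    tree : skbio.TreeNode
        Strictly binary rooted tree with named internal nodes whose tips
        are feature identifiers.
    feature_ids : sequence of str, optional
        Column order for the basis.  Defaults to the tree's tip order.
        Must be exactly the tip set (an error lists any symmetric
        difference).

    Returns
    -------
    pandas.DataFrame of shape (D-1, D), internal-node names as the index
    and feature identifiers as columns.  Rows are zero-sum, unit-norm and
    pairwise orthogonal.
    """
    validate_bifurcating(tree)
    tips = [t.name for t in tree.tips()]
    if feature_ids is None:
        feature_ids = tips
    else:
        feature_ids = list(feature_ids)
        missing = set(tips) - set(feature_ids)
        extra = set(feature_ids) - set(tips)
        if missing or extra:
            raise ValueError(
                "build_ilr_basis: tree tips and feature_ids differ; "
                f"tips not in feature_ids: {sorted(missing)}; "
                f"feature_ids not in tree: {sorted(extra)}"
            )
    col = {f: j for j, f in enumerate(feature_ids)}
    internals = internal_nodes_levelorder(tree)
    names = []
    matrix = np.zeros((len(internals), len(feature_ids)))
    for row, node in enumerate(internals):
        if node.name is None:
            raise ValueError(
                "build_ilr_basis: unnamed internal node; run "
                "tree.name_internal_nodes first"
            )
        num, den = subtree_tip_sets(tree, node)
        r, s = len(num), len(den)
        a = np.sqrt(s / (r * (r + s)))
        b = -np.sqrt(r / (s * (r + s)))
        matrix[row, [col[f] for f in num]] = a
        matrix[row, [col[f] for f in den]] = b
        names.append(node.name)
    if len(set(names)) != len(names):
        raise ValueError("build_ilr_basis: duplicate internal node names")
    return pd.DataFrame(matrix, index=pd.Index(names, name="node"), columns=list(feature_ids))


def _check_alignment(columns, basis: pd.DataFrame, op: str) -> None:
    if list(columns) != list(basis.columns):
        raise ValueError(
            f"{op}: feature order of the table does not match the basis "
            f"columns; table={list(columns)[:5]}..., basis={list(basis.columns)[:5]}..."
        )


def ilr_transform(table: pd.DataFrame, basis: pd.DataFrame) -> pd.DataFrame:
    """Map strictly positive compositions to balances via a tree basis.

    Equivalent to ``clr(x) @ basis.T``; scale invariant, so raw positive
    counts and their closed proportions give identical balances.

    Returns a samples x (D-1) DataFrame whose columns are the basis's
    internal-node names, in basis row order.
    """
    frame, squeeze = _as_frame(table)
    if isinstance(table, (pd.DataFrame, pd.Series)):
        _check_alignment(frame.columns, basis, "ilr_transform")
    elif frame.shape[1] != basis.shape[1]:
        raise ValueError(
            f"ilr_transform: table has {frame.shape[1]} features but the "
            f"basis has {basis.shape[1]} columns"
        )
    values = _require_positive(frame, "ilr_transform")
    logs = np.log(values)
    logs -= logs.mean(axis=1, keepdims=True)
    out = pd.DataFrame(logs @ basis.to_numpy().T, index=frame.index, columns=basis.index)
    if squeeze:
        return out.iloc[0] if isinstance(table, pd.Series) else out.to_numpy()[0]
    return out


def balances_direct(table: pd.DataFrame, tree) -> pd.DataFrame:
    """Evaluate each balance straight from its defining log-ratio.

    Walks the internal nodes and computes
    ``sqrt(r*s/(r+s)) * ln(g(numerator)/g(denominator))`` per sample;
    an independent route to the matrix product in :func:`ilr_transform`
    (the two agree to ~1e-12 and the agreement is under test).
    """
    frame, squeeze = _as_frame(table)
    values = _require_positive(frame, "balances_direct")
    logs = np.log(values)
    col = {f: j for j, f in enumerate(frame.columns)}
    internals = internal_nodes_levelorder(tree)
    out = np.empty((len(frame), len(internals)))
    names = []
    for k, node in enumerate(internals):
        num, den = subtree_tip_sets(tree, node)
        r, s = len(num), len(den)
        g_num = logs[:, [col[f] for f in num]].mean(axis=1)
        g_den = logs[:, [col[f] for f in den]].mean(axis=1)
        out[:, k] = np.sqrt(r * s / (r + s)) * (g_num - g_den)
        names.append(node.name)
    res = pd.DataFrame(out, index=frame.index, columns=names)
    if squeeze:
        return res.iloc[0] if isinstance(table, pd.Series) else res.to_numpy()[0]
    return res


def inverse_ilr(balances: pd.DataFrame, basis: pd.DataFrame) -> pd.DataFrame:
    """Map balances back to proportions: ``closure(exp(b @ basis))``.

    Inverse of :func:`ilr_transform` up to closure: the round trip
    reproduces each closed composition exactly (to ~1e-12).
    """
    frame, squeeze = _as_frame(balances)
    if frame.shape[1] != basis.shape[0]:
        raise ValueError(
            f"inverse_ilr: got {frame.shape[1]} balance columns but the "
            f"basis has {basis.shape[0]} rows"
        )
    if isinstance(balances, pd.DataFrame) and list(frame.columns) != list(basis.index):
        raise ValueError(
            "inverse_ilr: balance column order does not match basis node order"
        )
    clr = frame.to_numpy(dtype=float) @ basis.to_numpy()
    # subtract the row max before exponentiating for numerical safety
    clr -= clr.max(axis=1, keepdims=True)
    raw = np.exp(clr)
    out = pd.DataFrame(raw / raw.sum(axis=1, keepdims=True),
                       index=frame.index, columns=basis.columns)
    if squeeze:
        return out.iloc[0] if isinstance(balances, pd.Series) else out.to_numpy()[0]
    return out


def perturbation(x, y):
    """Aitchison perturbation: closure of the elementwise product.

    The simplex analogue of vector addition; ``ilr(x ⊕ y) = ilr(x) + ilr(y)``.
    """
    fx, _ = _as_frame(x)
    fy, _ = _as_frame(y)
    _require_positive(fx, "perturbation")
    _require_positive(fy, "perturbation")
    vx = np.asarray(fx, dtype=float)
    vy = np.asarray(fy, dtype=float)
    if vx.shape[1] != vy.shape[1]:
        raise ValueError("perturbation: inputs have different numbers of parts")
    prod = vx * vy
    out = prod / prod.sum(axis=1, keepdims=True)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=fx.index, columns=fx.columns)
    return out[0] if np.asarray(x).ndim == 1 else out


def power(x, t: float):
    """Aitchison powering: closure of the elementwise t-th power.

    The simplex analogue of scalar multiplication; ``ilr(t ⊙ x) = t * ilr(x)``.
    """
    fx, _ = _as_frame(x)
    _require_positive(fx, "power")
    vx = np.asarray(fx, dtype=float) ** float(t)
    out = vx / vx.sum(axis=1, keepdims=True)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=fx.index, columns=fx.columns)
    return out[0] if np.asarray(x).ndim == 1 else out
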