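"""Synthetic community generators and false-discovery experiments.

Three generators emulate the regimes the balance machinery is designed
for:

* :func:`generate_gradient_community` — unimodal (Gaussian-bump) species
  responses along a continuous gradient, like soil taxa distributed
  along a pH range.  Small expected proportions are rounded down to zero
  before multinomial sequencing, so the pseudocount pathway is exercised.
* :func:`generate_bloom_dataset` — two groups of samples over an
  otherwise uniform community where exactly one taxon blooms in the
  second group.  Because sequencing is compositional, every other
  taxon's *proportion* drops even though its absolute abundance never
  changed — the classic trap for per-taxon tests.
* :func:`generate_patient_gradient` — repeated measures across a pH
  gradient for multiple subjects with idiosyncratic (partially disjoint)
  communities that nonetheless share per-feature niche optima, the
  regime where mixed-effects models on balances gain power.

All generators are deterministic given (spec, seed) and return plain
pandas objects plus a dictionary of ground-truth parameters for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .composition import add_pseudocount, build_ilr_basis, closure, ilr_transform
from .tree import name_internal_nodes, subtree_tip_sets, validate_bifurcating

__all__ = [
    "GradientCommunitySpec",
    "BloomSpec",
    "generate_gradient_community",
    "generate_bloom_dataset",
    "generate_patient_gradient",
    "balanced_binary_tree",
    "caterpillar_tree",
    "bloom_experiment_tree",
    "fdr_experiment",
]


def _feature_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"F{i:0{width}d}" for i in range(n)]


def _sample_names(n: int, prefix: str = "S") -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


@dataclass
class GradientCommunitySpec:
    """Unimodal gradient community.

    Defaults emulate a soils-like survey: 88 samples spanning pH 3.8 to
    8.2, 40 taxa with niche optima spread evenly across that range,
    niche breadth 1.0 pH unit, 1,000 reads per sample, and expected
    proportions below 1e-4 rounded down to zero before sequencing.
    """

    n_features: int = 40
    gradient: np.ndarray = field(default_factory=lambda: np.linspace(3.8, 8.2, 88))
    optima: np.ndarray | None = None       # default: even spread over gradient
    widths: np.ndarray | float = 1.0       # gaussian niche breadth, gradient units
    depth: int = 1000                      # reads per sample
    zero_threshold: float = 1e-4           # proportions below this are zeroed
    seed: int = 0

    def resolve(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        g = np.asarray(self.gradient, dtype=float)
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if g.size < 1 or not np.isfinite(g).all():
            raise ValueError("gradient must be non-empty and finite")
        if self.optima is None:
            optima = np.linspace(g.min(), g.max(), self.n_features)
        else:
            optima = np.asarray(self.optima, dtype=float)
            if optima.size != self.n_features:
                raise ValueError("optima length must equal n_features")
            if (optima < g.min()).any() or (optima > g.max()).any():
                raise ValueError("optima must lie within the gradient range")
        widths = np.broadcast_to(np.asarray(self.widths, dtype=float),
                                 (self.n_features,)).copy()
        if (widths <= 0).any():
            raise ValueError("widths must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.zero_threshold < 0 or self.zero_threshold >= 1:
            raise ValueError("zero_threshold must be in [0, 1)")
        return g, optima, widths


def generate_gradient_community(spec: GradientCommunitySpec):
    """Simulate counts from unimodal species responses along a gradient.

    Expected proportions at gradient value g are proportional to
    ``exp(-(g - optimum)^2 / (2 width^2))`` per feature; proportions
    below ``zero_threshold`` are set to zero and the row re-closed;
    counts are multinomial at the requested depth.

    Returns ``(counts, metadata, truth)`` — a samples x features count
    DataFrame, a metadata DataFrame with a ``gradient`` column, and the
    ground-truth parameters.
    """
    g, optima, widths = spec.resolve()
    rng = np.random.default_rng(spec.seed)
    features = _feature_names(spec.n_features)
    samples = _sample_names(g.size)

    bumps = np.exp(-((g[:, None] - optima[None, :]) ** 2) / (2 * widths[None, :] ** 2))
    expected = bumps / bumps.sum(axis=1, keepdims=True)
    if spec.zero_threshold > 0:
        expected = np.where(expected < spec.zero_threshold, 0.0, expected)
        row_sums = expected.sum(axis=1)
        if (row_sums == 0).any():
            raise ValueError(
                "zero_threshold removed every feature from at least one sample"
            )
        expected = expected / row_sums[:, None]

    counts = np.vstack([
        rng.multinomial(spec.depth, expected[i]) for i in range(g.size)
    ])
    table = pd.DataFrame(counts, index=samples, columns=features)
    metadata = pd.DataFrame({"gradient": g}, index=samples)
    truth = {"optima": dict(zip(features, optima.tolist())),
             "widths": dict(zip(features, widths.tolist())),
             "expected_proportions": expected,
             "depth": spec.depth,
             "zero_threshold": spec.zero_threshold}
    return table, metadata, truth


@dataclass
class BloomSpec:
    """One blooming taxon in an otherwise uniform community.

    Group 1 has uniform expected composition over ``n_features`` taxa;
    group 2 is identical except the bloom taxon's absolute abundance is
    multiplied by ``bloom_factor`` (its expected proportion becomes
    factor / (factor + n_features - 1)).  The default factor of 100
    makes the bloomer ~9% of a 1,000-taxon community — a dominant bloom,
    strong enough that naive per-taxon proportion tests enter their
    near-total false-positive regime at the default depth and sample
    size.
    """

    n_features: int = 1000
    n_samples: int = 50                    # per group
    bloom_feature: int = 0
    bloom_factor: float = 100.0
    depth: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2 per group")
        if not 0 <= self.bloom_feature < self.n_features:
            raise ValueError("bloom_feature index out of range")
        if self.bloom_factor < 1:
            raise ValueError("bloom_factor must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


def generate_bloom_dataset(spec: BloomSpec):
    """Simulate the two-group bloom scenario.

    Returns ``(counts, labels, truth)``: counts for 2 * n_samples
    samples over n_features taxa, a group-label Series ("group1" /
    "group2"), and the ground truth (bloom feature name, factor,
    expected proportions per group).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    features = _feature_names(spec.n_features)
    bloom = features[spec.bloom_feature]

    p1 = np.full(spec.n_features, 1.0 / spec.n_features)
    w = np.ones(spec.n_features)
    w[spec.bloom_feature] = spec.bloom_factor
    p2 = w / w.sum()

    counts = np.vstack([
        rng.multinomial(spec.depth, p1, size=spec.n_samples),
        rng.multinomial(spec.depth, p2, size=spec.n_samples),
    ])
    samples = _sample_names(2 * spec.n_samples)
    table = pd.DataFrame(counts, index=samples, columns=features)
    labels = pd.Series(["group1"] * spec.n_samples + ["group2"] * spec.n_samples,
                       index=samples, name="group")
    truth = {"bloom_feature": bloom, "bloom_factor": spec.bloom_factor,
             "expected_group1": p1, "expected_group2": p2}
    return table, labels, truth


def balanced_binary_tree(feature_ids) -> TreeNode:
    """Near-balanced strictly binary tree over the given tips (recursive
    halving), internal nodes named in level order."""
    feature_ids = [str(f) for f in feature_ids]
    if len(feature_ids) < 1:
        raise ValueError("need at least one feature")

    def build(block):
        if len(block) == 1:
            return TreeNode(name=block[0])
        mid = len(block) // 2
        return TreeNode(children=[build(block[:mid]), build(block[mid:])])

    return name_internal_nodes(build(feature_ids), overwrite=True)


def caterpillar_tree(feature_ids) -> TreeNode:
    """Fully pectinate (comb) tree: the first feature splits off at the
    root, the last two share the deepest cherry."""
    feature_ids = [str(f) for f in feature_ids]
    if len(feature_ids) < 2:
        raise ValueError("need at least two features")
    node = TreeNode(children=[TreeNode(name=feature_ids[-2]),
                              TreeNode(name=feature_ids[-1])])
    for name in reversed(feature_ids[:-2]):
        node = TreeNode(children=[TreeNode(name=name), node])
    return name_internal_nodes(node, overwrite=True)


def bloom_experiment_tree(feature_ids, bloom_feature: str,
                          placement: str = "root") -> TreeNode:
    """Tree for the bloom false-discovery experiment.

    ``placement="root"`` isolates the bloom taxon as one child of the
    root, with the remaining taxa in a balanced subtree — every balance
    below the root then excludes the bloomer entirely and is a true
    null.  ``placement="tip"`` buries the bloomer at the bottom of a
    caterpillar so that every internal node's clade contains it.
    """
    feature_ids = [str(f) for f in feature_ids]
    if bloom_feature not in feature_ids:
        raise ValueError(f"bloom feature {bloom_feature!r} not among features")
    rest = [f for f in feature_ids if f != bloom_feature]
    if placement == "root":
        tree = TreeNode(children=[TreeNode(name=bloom_feature),
                                  balanced_binary_tree(rest)])
        return name_internal_nodes(tree, overwrite=True)
    if placement == "tip":
        return caterpillar_tree(rest + [bloom_feature])
    raise ValueError(f"placement must be 'root' or 'tip', got {placement!r}")


def fdr_experiment(table: pd.DataFrame, labels: pd.Series, tree: TreeNode,
                   alpha: float = 0.05, bloom_feature: str | None = None,
                   pseudocount: float = 1.0) -> dict:
    """Contrast per-taxon proportion tests with per-balance tests.

    Runs a two-sample t test per feature on the closed proportions and a
    two-sample t test per balance on the tree's ILR coordinates
    (pseudocount, closure, then the tree basis).  A balance is a *null*
    balance when the bloom taxon lies outside its clade: by
    subcompositional coherence such balances are untouched by the bloom,
    so their rejections are pure false positives.

    Returns a dict with the rejection fractions, counts, and the raw
    p-value vectors.
    """
    groups = labels.loc[table.index]
    names = groups.unique()
    if len(names) != 2:
        raise ValueError("fdr_experiment: exactly two groups required")
    idx1 = groups == names[0]
    idx2 = groups == names[1]
    if idx1.sum() < 2 or idx2.sum() < 2:
        raise ValueError("fdr_experiment: each group needs >= 2 samples")

    proportions = closure(table)
    p1 = proportions.loc[idx1].to_numpy()
    p2 = proportions.loc[idx2].to_numpy()
    prop_p = stats.ttest_ind(p1, p2, axis=0).pvalue
    prop_p = pd.Series(prop_p, index=table.columns)

    validate_bifurcating(tree, feature_ids=table.columns)
    basis = build_ilr_basis(tree, feature_ids=table.columns)
    balances = ilr_transform(closure(add_pseudocount(table, pseudocount)), basis)
    b1 = balances.loc[idx1].to_numpy()
    b2 = balances.loc[idx2].to_numpy()
    bal_p = pd.Series(stats.ttest_ind(b1, b2, axis=0).pvalue, index=balances.columns)

    report = {
        "alpha": alpha,
        "proportion_pvalues": prop_p,
        "balance_pvalues": bal_p,
        "proportion_rejection_fraction": float((prop_p < alpha).mean()),
        "balance_rejection_fraction": float((bal_p < alpha).mean()),
    }
    if bloom_feature is not None:
        if bloom_feature not in table.columns:
            raise ValueError(f"bloom feature {bloom_feature!r} not in table")
        non_bloom = prop_p.drop(bloom_feature)
        report["nonbloom_proportion_rejection_fraction"] = float(
            (non_bloom < alpha).mean())
        null_nodes = []
        for node in balances.columns:
            num, den = subtree_tip_sets(tree, node)
            if bloom_feature not in num and bloom_feature not in den:
                null_nodes.append(node)
        report["null_balances"] = null_nodes
        report["n_null_balances"] = len(null_nodes)
        report["null_balance_rejection_fraction"] = (
            float((bal_p.loc[null_nodes] < alpha).mean()) if null_nodes else np.nan
        )
    return report


def generate_patient_gradient(
    n_patients: int = 16,
    ph_levels=np.arange(5.0, 8.51, 0.5),
    n_features: int = 40,
    effect_size: float = 1.0,
    idiosyncrasy: float = 0.5,
    depth: int = 10_000,
    seed: int = 0,
):
    """Repeated-measures pH gradient with idiosyncratic subject communities.

    Every feature has a niche optimum shared across patients (spread
    evenly over the pH range, Gaussian response with breadth
    ``1/effect_size`` pH units).  Each patient carries a random subset
    of the feature pool: a feature is present with probability
    ``1 - idiosyncrasy`` (at least two features per patient are forced).
    Counts are multinomial over each patient's present features at the
    given depth, one sample per (patient, pH level).

    Returns ``(counts, metadata, truth)`` where metadata has columns
    ``patient`` and ``ph``.
    """
    ph = np.asarray(ph_levels, dtype=float)
    if n_patients < 2 or ph.size < 2:
        raise ValueError("need >= 2 patients and >= 2 pH levels")
    if not 0 <= idiosyncrasy < 1:
        raise ValueError("idiosyncrasy must be in [0, 1)")
    if effect_size <= 0:
        raise ValueError("effect_size must be > 0")
    rng = np.random.default_rng(seed)
    features = _feature_names(n_features)
    optima = np.linspace(ph.min(), ph.max(), n_features)
    width = 1.0 / effect_size

    masks = rng.random((n_patients, n_features)) >= idiosyncrasy
    for p in range(n_patients):
        while masks[p].sum() < 2:
            masks[p, rng.integers(n_features)] = True

    rows, meta = [], []
    for p in range(n_patients):
        present = masks[p].astype(float)
        for g in ph:
            bump = np.exp(-((g - optima) ** 2) / (2 * width ** 2)) * present
            probs = bump / bump.sum()
            rows.append(rng.multinomial(depth, probs))
            meta.append((f"P{p:02d}", g))
    samples = _sample_names(len(meta))
    counts = pd.DataFrame(np.vstack(rows), index=samples, columns=features)
    metadata = pd.DataFrame(meta, columns=["patient", "ph"], index=samples)
    truth = {"optima": dict(zip(features, optima.tolist())), "width": width,
             "masks": pd.DataFrame(masks, index=[f"P{p:02d}" for p in range(n_patients)],
                                   columns=features)}
    return counts, metadata, truth
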