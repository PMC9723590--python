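"""Alpha and beta diversity metrics.

Four beta metrics span the presence/abundance and taxonomy/phylogeny
axes of community dissimilarity:

=================   ===========  =================
metric              weighting    microbial tree
=================   ===========  =================
Jaccard             presence     ignored
Bray-Curtis         abundance    ignored
unweighted UniFrac  presence     branch lengths
weighted UniFrac    abundance    branch lengths
=================   ===========  =================

UniFrac metrics weight deep (old) microbial clades more heavily, the
taxonomy-only ("star phylogeny") metrics weight every ASV equally.
Alpha diversity is Faith's phylogenetic diversity: the total branch
length of the minimal rooted subtree spanning a sample's ASVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from . import _tree
from .data_model import AsvTable, DistanceMatrix

__all__ = [
    "BETA_METRICS",
    "AlphaVector",
    "beta_diversity",
    "bray_curtis",
    "jaccard",
    "unweighted_unifrac",
    "weighted_unifrac",
    "faith_pd",
]

BETA_METRICS = ("bray_curtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")


@dataclass
class AlphaVector:
    """Per-sample alpha diversity values (Faith's PD: summed branch length)."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = "faith_pd"

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values, index=self.sample_ids, name=self.metric)


def _check_no_empty(table: AsvTable) -> None:
    sums = table.row_sums()
    empty = [s for s, t in zip(table.sample_ids, sums) if t == 0]
    if empty:
        raise ValueError(f"distance undefined for all-zero samples: {empty}")


def _require_two(table: AsvTable) -> None:
    if table.n_samples < 2:
        raise ValueError("beta diversity requires at least 2 samples")


def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min(x, y)) / (sum x + sum y)."""
    _require_two(table)
    _check_no_empty(table)
    x = table.counts.astype(float)
    sums = x.sum(axis=1)
    # sum(min) = (s_i + s_j - sum|x_i - x_j|) / 2, so d = sum|x-y| / (s_i+s_j)
    n = table.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        l1 = np.abs(x[i] - x).sum(axis=1)
        dist[i] = l1 / (sums[i] + sums)
    return DistanceMatrix(dist, table.sample_ids)


def jaccard(table: AsvTable) -> DistanceMatrix:
    """Jaccard distance on ASV presence/absence: 1 - |A∩B| / |A∪B|."""
    _require_two(table)
    _check_no_empty(table)
    p = (table.counts > 0).astype(float)
    inter = p @ p.T
    sizes = p.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    dist = 1.0 - inter / union
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, table.sample_ids)


def _unifrac_setup(table: AsvTable, tree: dendropy.Tree):
    _require_two(table)
    _check_no_empty(table)
    tips = set(_tree.tip_labels(tree))
    present = table.counts.sum(axis=0) > 0
    missing = [a for a, p in zip(table.asv_ids, present) if p and a not in tips]
    if missing:
        raise KeyError(f"ASVs missing from microbial tree: {missing}")
    # extend the tip order with tree tips absent from the table (zero counts)
    order = list(table.asv_ids) + [t for t in _tree.tip_labels(tree) if t not in set(table.asv_ids)]
    lengths, inc, _ = _tree.branch_incidence(tree, order)
    inc = inc[:, : table.n_asvs]  # columns align with the table's ASVs
    return lengths, inc


def unweighted_unifrac(table: AsvTable, tree: dendropy.Tree) -> DistanceMatrix:
    """Fraction of branch length leading to tips found in exactly one community."""
    lengths, inc = _unifrac_setup(table, tree)
    presence = table.counts > 0  # samples x asvs
    covered = inc @ presence.T > 0  # branches x samples
    weighted = covered * lengths[:, None]
    shared = weighted.T @ covered  # sum of lengths on branches covered by both
    totals = weighted.sum(axis=0)
    union = totals[:, None] + totals[None, :] - shared
    unique = totals[:, None] + totals[None, :] - 2.0 * shared
    with np.errstate(invalid="ignore"):
        dist = np.where(union > 0, unique / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, table.sample_ids)


def weighted_unifrac(
    table: AsvTable, tree: dendropy.Tree, normalized: bool = False
) -> DistanceMatrix:
    """Abundance-weighted UniFrac.

    Unnormalized (the default, matching the common tool convention):
    ``d(A, B) = sum_e b_e * |p_e^A - p_e^B|`` where ``p_e^X`` is the
    fraction of community X's reads descending through branch ``e``.
    The normalized variant divides by ``sum_e b_e * (p_e^A + p_e^B)``.
    """
    lengths, inc = _unifrac_setup(table, tree)
    rel = table.counts / table.row_sums()[:, None]
    p = inc.astype(float).T  # asvs x branches
    frac = rel @ p  # samples x branches: fraction of reads through each branch
    n = table.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        dist[i] = (np.abs(frac[i] - frac) * lengths[None, :]).sum(axis=1)
    if normalized:
        denom = np.zeros((n, n))
        for i in range(n):
            denom[i] = ((frac[i] + frac) * lengths[None, :]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            dist = np.where(denom > 0, dist / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, table.sample_ids)


def beta_diversity(
    metric: str,
    table: AsvTable,
    tree: dendropy.Tree | None = None,
    **kwargs,
) -> DistanceMatrix:
    """Dispatch a beta-diversity metric by name (see ``BETA_METRICS``)."""
    if metric == "bray_curtis":
        return bray_curtis(table)
    if metric == "jaccard":
        return jaccard(table)
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a microbial tree")
        if metric == "unweighted_unifrac":
            return unweighted_unifrac(table, tree)
        return weighted_unifrac(table, tree, **kwargs)
    raise ValueError(f"unknown beta metric {metric!r}; choose from {BETA_METRICS}")


def faith_pd(
    table: AsvTable, tree: dendropy.Tree, include_root_path: bool = True
) -> AlphaVector:
    """Faith's phylogenetic diversity per sample.

    Sum of branch lengths of the minimal subtree connecting a sample's
    ASVs.  By default the subtree is rooted at the tree's root (the tool
    convention), so a single-tip community has PD equal to its
    root-to-tip path; ``include_root_path=False`` instead spans only the
    observed tips' MRCA subtree.
    """
    tips = set(_tree.tip_labels(tree))
    present_any = table.counts.sum(axis=0) > 0
    missing = [a for a, p in zip(table.asv_ids, present_any) if p and a not in tips]
    if missing:
        raise KeyError(f"ASVs missing from microbial tree: {missing}")
    order = list(table.asv_ids) + [t for t in _tree.tip_labels(tree) if t not in set(table.asv_ids)]
    lengths, inc, _ = _tree.branch_incidence(tree, order)
    inc = inc[:, : table.n_asvs]
    presence = table.counts > 0
    covered = inc @ presence.T > 0  # branches x samples
    values = (covered * lengths[:, None]).sum(axis=0)
    if not include_root_path:
        # subtract the unbranched stem above each sample's tip MRCA
        for s in range(table.n_samples):
            cov = covered[:, s]
            n_tips_present = presence[s].sum()
            if n_tips_present <= 1:
                values[s] = 0.0
                continue
            # stem branches subtend all present tips
            counts_per_branch = inc @ presence[s]
            stem = cov & (counts_per_branch == n_tips_present)
            values[s] -= lengths[stem].sum()
    empty = [s for s, t in zip(table.sample_ids, table.row_sums()) if t == 0]
    if empty:
        warnings.warn(f"empty samples have PD 0: {empty}")
    return AlphaVector(list(table.sample_ids), values.astype(float))
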