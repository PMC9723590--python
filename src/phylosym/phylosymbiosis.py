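"""Congruence and correlation tests of phylosymbiosis.

Two predictions are tested against the host phylogeny:

* **Topology** — the UPGMA dendrogram of microbiome distances should
  recapitulate host branching order.  Congruence is the normalized
  Robinson-Foulds (RF) distance (0 = identical topology, 1 = no shared
  bipartitions), and significance comes from comparing the observed RF
  to RF distances between the host tree and randomized topologies.
* **Distance** — microbiome distance should increase with host
  phylogenetic (patristic) distance, tested by a one-tailed Mantel
  permutation test with the Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from . import _tree
from .data_model import DistanceMatrix, derive_seed

__all__ = [
    "RfTestResult",
    "MantelResult",
    "upgma",
    "robinson_foulds",
    "random_topology",
    "rf_randomization_test",
    "patristic_distances",
    "mantel",
]


@dataclass
class RfTestResult:
    """Observed normalized RF distance with its randomization null."""

    observed_rf: float
    null_rf: np.ndarray
    p_value: float
    n_null: int


@dataclass
class MantelResult:
    """Mantel correlation between two distance matrices."""

    r: float
    p_value: float
    n_permutations: int
    method: str = "pearson"
    alternative: str = "greater"


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) dendrogram of a distance matrix.

    Merge heights are half the average-linkage distance, so cophenetic
    distances on the output reproduce an ultrametric input exactly.  Ties
    are broken by merging the pair whose (lexicographically smallest,
    then largest) member labels sort first, making the topology
    deterministic across platforms.
    """
    n = dm.n
    if n < 2:
        raise ValueError("UPGMA requires at least 2 labels")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains NaN")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    # active clusters: key -> (node, size, height, min_label)
    nodes: dict[int, dendropy.Node] = {}
    sizes: dict[int, int] = {}
    heights: dict[int, float] = {}
    min_label: dict[int, str] = {}
    for i, lab in enumerate(dm.labels):
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[i] = node
        sizes[i] = 1
        heights[i] = 0.0
        min_label[i] = lab
    dist = {
        (i, j): float(dm.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    next_key = n
    while len(active) > 1:
        best = None
        for a_idx in range(len(active)):
            for b_idx in range(a_idx + 1, len(active)):
                i, j = active[a_idx], active[b_idx]
                key = (min(i, j), max(i, j))
                d = dist[key]
                li, lj = sorted((min_label[i], min_label[j]))
                cand = (d, li, lj, key)
                if best is None or cand < best:
                    best = cand
        d, _, _, (i, j) = best
        height = d / 2.0
        parent = dendropy.Node()
        for child in (i, j):
            edge_len = height - heights[child]
            nodes[child].edge.length = max(edge_len, 0.0)
            parent.add_child(nodes[child])
        new = next_key
        next_key += 1
        nodes[new] = parent
        sizes[new] = sizes[i] + sizes[j]
        heights[new] = height
        min_label[new] = min(min_label[i], min_label[j])
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(new, k), max(new, k))] = dnew
        active = [k for k in active if k not in (i, j)] + [new]
    root = nodes[active[0]]
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def _splits(tree: dendropy.Tree) -> tuple[set[frozenset[str]], list[str]]:
    """Non-trivial unrooted bipartitions, each encoded as the tip set on
    the side *not* containing a fixed reference tip."""
    labels = sorted(_tree.tip_labels(tree))
    full = frozenset(labels)
    ref = labels[0]
    n = len(labels)
    splits: set[frozenset[str]] = set()
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(sets[c] for c in node.child_nodes()))
            sets[node] = s
            if node.parent_node is None:
                continue
            side = s if ref not in s else full - s
            if 2 <= len(side) <= n - 2:
                splits.add(side)
    return splits, labels


def robinson_foulds(
    t1: dendropy.Tree, t2: dendropy.Tree, normalized: bool = True
) -> float:
    """Robinson-Foulds distance between two trees on the same tip set.

    Computed on unrooted bipartitions.  The normalized form divides the
    symmetric-difference count by the total number of non-trivial
    bipartitions in both trees — equal to ``2(n-3)`` for two fully
    resolved trees — which handles multifurcating dendrograms gracefully.
    """
    s1, l1 = _splits(t1)
    s2, l2 = _splits(t2)
    if l1 != l2:
        diff = sorted(set(l1) ^ set(l2))
        raise ValueError(f"tip sets differ; symmetric difference: {diff}")
    return _rf_from_splits(s1, s2, normalized)


def _rf_from_splits(
    s1: set[frozenset[str]], s2: set[frozenset[str]], normalized: bool
) -> float:
    rf = len(s1 ^ s2)
    if not normalized:
        return float(rf)
    denom = len(s1) + len(s2)
    if denom == 0:
        return 0.0
    return rf / denom


# ---------------------------------------------------------------------------
# Randomization null
# ---------------------------------------------------------------------------

def _random_merges(labels: list[str], seed: int) -> list[tuple[frozenset, frozenset]]:
    """Coalescent-style random join sequence over a permuted label set."""
    rng = np.random.default_rng(seed)
    items = [frozenset([str(lab)]) for lab in rng.permutation(labels)]
    merges = []
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = items[i] | items[j]
        merges.append((items[i], items[j]))
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return merges


def random_topology(labels, seed: int) -> dendropy.Tree:
    """Uniform random binary topology with unit branch lengths.

    Built by coalescent-style random joins of a uniformly permuted label
    set (the same null as the standard random-tree generators).
    """
    labels = [str(x) for x in labels]
    if len(labels) < 3:
        raise ValueError("random topology requires at least 3 labels")
    taxa = dendropy.TaxonNamespace(labels)
    nodes: dict[frozenset, dendropy.Node] = {}
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        node.edge.length = 1.0
        nodes[frozenset([lab])] = node
    root = None
    for a, b in _random_merges(labels, seed):
        parent = dendropy.Node()
        parent.edge.length = 1.0
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a | b] = parent
        root = parent
    root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def _random_topology_splits(labels: list[str], seed: int) -> set[frozenset[str]]:
    """Non-trivial splits of ``random_topology(labels, seed)`` without
    building the tree (same merge sequence, same canonicalization)."""
    if len(labels) < 3:
        raise ValueError("random topology requires at least 3 labels")
    slabels = sorted(str(x) for x in labels)
    full = frozenset(slabels)
    ref = slabels[0]
    n = len(slabels)
    splits: set[frozenset[str]] = set()
    for a, b in _random_merges(list(labels), seed):
        s = a | b
        if len(s) == n:
            continue
        side = s if ref not in s else full - s
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def rf_randomization_test(
    host: dendropy.Tree,
    gm_dendrogram: dendropy.Tree,
    n_null: int = 10000,
    seed: int = 0,
) -> RfTestResult:
    """Test dendrogram congruence against randomized microbiome trees.

    The null distribution replaces the microbiome dendrogram by random
    topologies on the same tips; the add-one p-value is
    ``(1 + #{null RF <= observed RF}) / (1 + n_null)`` (small p means the
    observed congruence is higher than expected by chance).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    host_splits, host_labels = _splits(host)
    gm_splits, gm_labels = _splits(gm_dendrogram)
    if host_labels != gm_labels:
        diff = sorted(set(host_labels) ^ set(gm_labels))
        raise ValueError(f"tip sets differ; symmetric difference: {diff}")
    observed = _rf_from_splits(host_splits, gm_splits, normalized=True)
    null = np.empty(n_null)
    for k in range(n_null):
        rand_splits = _random_topology_splits(host_labels, derive_seed(seed, f"rf_null:{k}"))
        null[k] = _rf_from_splits(host_splits, rand_splits, normalized=True)
    p = (1.0 + np.sum(null <= observed + 1e-12)) / (1.0 + n_null)
    return RfTestResult(observed, null, float(p), n_null)


# ---------------------------------------------------------------------------
# Patristic distance and Mantel
# ---------------------------------------------------------------------------

def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip sum of branch lengths along the connecting path."""
    dist, order = _tree.patristic_matrix(tree)
    return DistanceMatrix(dist, order)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of matrix correlation (Pearson, permutation p-value).

    ``dm2`` is reordered to ``dm1``'s labels; its rows and columns are
    then permuted jointly.  The default alternative is one-tailed
    "greater" (phylosymbiosis predicts a positive correlation).
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if set(dm1.labels) != set(dm2.labels):
        diff = sorted(set(dm1.labels) ^ set(dm2.labels))
        raise ValueError(f"label sets differ; symmetric difference: {diff}")
    n = dm1.n
    if n < 4:
        raise ValueError("Mantel test requires at least 4 objects")
    m2 = dm2.reorder(dm1.labels)
    iu = np.triu_indices(n, k=1)
    v1 = dm1.values[iu]
    z1 = (v1 - v1.mean()) / v1.std()
    v2 = m2.values[iu]
    z2 = (v2 - v2.mean()) / v2.std()
    m = v1.size
    r_obs = float(z1 @ z2 / m)
    rng = np.random.default_rng(derive_seed(seed, "mantel"))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        vp = m2.values[np.ix_(perm, perm)][iu]
        zp = (vp - vp.mean()) / vp.std()
        r_perm = z1 @ zp / m
        if alternative == "greater":
            count += r_perm >= r_obs - 1e-12
        elif alternative == "less":
            count += r_perm <= r_obs + 1e-12
        else:
            count += abs(r_perm) >= abs(r_obs) - 1e-12
    p = (1.0 + count) / (1.0 + n_permutations)
    return MantelResult(r_obs, float(p), n_permutations, alternative=alternative)
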