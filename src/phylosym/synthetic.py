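"""Synthetic host/microbiome datasets with controllable phylosymbiosis.

The generator emulates a field study of a 15-species, 3-family host
clade (5 + 7 + 3 species, echoing the cheirogaleid / lemurid / indriid
design), with 1-30 fecal samples per species and per-sample read depths
of 2000-10000.  Microbial communities are built from three layered
effects on per-ASV log-abundances:

* a host-structured effect per ASV, drawn by Brownian motion on the host
  tree with rate ``sigma_phy`` (this creates phylosymbiosis);
* a diet effect restricted to *deep* microbial clades — clades whose
  stem crosses relative depth ``tau_deep`` — each sharing one loading,
  scaled by ``beta_diet`` and the species' diet trait (this creates the
  old-clades-track-diet contrast that UniFrac metrics are sensitive to);
* species- and individual-level Gaussian noise.

Log-abundances pass through a softmax to relative abundances, and reads
are drawn multinomially.  Negative controls contain only a designated
contaminant ASV set, which is also spiked into real samples so the
control-filtering step is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import dendropy
import numpy as np
import yaml

from . import _tree
from .data_model import (
    AsvTable,
    SampleInfo,
    TraitMatrix,
    derive_seed,
    newick_string,
    write_asv_table,
    write_metadata,
    write_newick,
    write_traits,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_yule_tree",
    "simulate_bm_trait",
    "simulate_community",
    "write_bundle",
    "phylosymbiosis_regime",
    "null_regime",
    "deep_diet_regime",
]

DIET_ITEMS = ("fruit", "leaves", "insects", "bamboo", "gum", "flowers")


@dataclass
class SimulationConfig:
    """Knobs of the community simulator (defaults mirror the study design)."""

    n_species: int = 15
    family_sizes: tuple[int, ...] = (5, 7, 3)
    samples_per_species: tuple[int, int] = (1, 30)
    n_asvs: int = 400
    read_depth: tuple[int, int] = (2000, 10000)
    sigma_phy: float = 2.0  # BM rate of host-structured ASV effects
    beta_diet: float = 1.0  # diet effect size on deep microbial clades
    tau_deep: float = 0.3  # relative microbial-tree depth separating deep clades
    lambda_diet: float = 0.7  # phylogenetic structure of the diet trait
    sigma_noise: float = 0.3  # species-level noise sd
    sigma_individual: float = 0.3  # within-species (per-sample) noise sd
    alpha_sd: float = 3.0  # spread of per-ASV baseline log-abundances
    n_controls: int = 3
    n_contaminants: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if sum(self.family_sizes) != self.n_species:
            raise ValueError("family_sizes must partition n_species")
        if any(s < 1 for s in self.family_sizes):
            raise ValueError("family sizes must be >= 1")
        lo, hi = self.samples_per_species
        if not (1 <= lo <= hi):
            raise ValueError("invalid samples_per_species range")
        if self.n_asvs < 10:
            raise ValueError("n_asvs must be >= 10")
        dlo, dhi = self.read_depth
        if not (1 <= dlo <= dhi):
            raise ValueError("invalid read_depth range")
        for name in ("sigma_phy", "beta_diet", "sigma_noise", "sigma_individual", "alpha_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.tau_deep <= 1.0:
            raise ValueError("tau_deep must be in [0, 1]")
        if not 0.0 <= self.lambda_diet <= 1.0:
            raise ValueError("lambda_diet must be in [0, 1]")
        if self.n_contaminants >= self.n_asvs:
            raise ValueError("n_contaminants must be < n_asvs")


@dataclass
class SyntheticDataset:
    """Everything a pipeline run needs, plus the generating parameters."""

    host_tree: dendropy.Tree
    microbial_tree: dendropy.Tree
    table: AsvTable
    meta: list[SampleInfo]
    traits: TraitMatrix
    true_params: SimulationConfig


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _yule_node_times(n_tips: int, rng: np.random.Generator):
    """Speciation times of a pure-birth (Yule) tree, crown age rescaled later."""
    times = []
    t = 0.0
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / k)
        times.append(t)
        k += 1
    end = t + rng.exponential(1.0 / n_tips)
    return times, end


def simulate_yule_tree(
    n_tips: int, seed: int, labels: list[str] | None = None
) -> dendropy.Tree:
    """Pure-birth ultrametric tree rescaled to unit root-to-tip depth."""
    if n_tips < 3:
        raise ValueError("Yule tree requires >= 3 tips")
    rng = np.random.default_rng(seed)
    if labels is None:
        width = len(str(n_tips))
        labels = [f"t{i + 1:0{width}d}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    split_times, end = _yule_node_times(n_tips, rng)
    # grow the tree forward in time: each split picks a random active lineage
    root = tree.seed_node
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active = [c1, c2]
    birth = {c1: 0.0, c2: 0.0}
    for t in split_times:
        idx = rng.integers(len(active))
        parent = active.pop(idx)
        parent_birth = birth.pop(parent)
        parent.edge.length = t - parent_birth
        a, b = dendropy.Node(), dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        birth[a] = t
        birth[b] = t
        active.extend([a, b])
    perm = rng.permutation(n_tips)
    for node, lab_idx in zip(active, perm):
        node.edge.length = end - birth[node]
        node.taxon = taxa.get_taxon(labels[int(lab_idx)])
    scale = 1.0 / end
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    tree.is_rooted = True
    return tree


def _build_host_tree(cfg: SimulationConfig, rng_seed: int) -> tuple[dendropy.Tree, dict]:
    """Host tree with monophyletic families joined on a fixed backbone.

    Family crowns start at relative depth 0.5; the backbone splits at 0
    and 0.15, so deep structure separates families while within-family
    structure stays comparatively shallow.  Genera are clades whose stem
    crosses relative depth 0.8.
    """
    n_fam = len(cfg.family_sizes)
    width = len(str(cfg.n_species))
    species = [f"sp{i + 1:0{width}d}" for i in range(cfg.n_species)]
    fam_assign: dict[str, str] = {}
    start = 0
    subtrees = []
    for f, size in enumerate(cfg.family_sizes):
        labs = species[start: start + size]
        start += size
        fam = f"Fam{f + 1}"
        for s in labs:
            fam_assign[s] = fam
        if size == 1:
            subtrees.append((labs, None))
        elif size == 2:
            subtrees.append((labs, f"({labs[0]}:0.5,{labs[1]}:0.5)"))
        else:
            sub = simulate_yule_tree(size, derive_seed(rng_seed, f"family:{f}"), labels=labs)
            for edge in sub.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= 0.5
            nwk = newick_string(sub).rstrip(";").strip()
            subtrees.append((labs, nwk))

    def stemmed(labs, nwk, stem_from: float) -> str:
        # stem length from backbone depth `stem_from` down to crown at 0.5
        if nwk is None:
            return f"{labs[0]}:{1.0 - stem_from}"
        return f"{nwk}:{0.5 - stem_from}"

    parts = [stemmed(*subtrees[0], 0.15), stemmed(*subtrees[1], 0.15)]
    inner = f"({parts[0]},{parts[1]}):0.15"
    if n_fam >= 3:
        rest = [stemmed(*st, 0.0) for st in subtrees[2:]]
        newick = f"({inner},{','.join(rest)});"
    else:
        newick = f"({inner});"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True

    # genera: maximal clades whose stem crosses relative depth 0.8
    depths = _tree.node_depths(tree)
    genus_assign: dict[str, str] = {}
    counter = {f: 0 for f in {fam_assign[s] for s in species}}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if depths[parent] < 0.8 <= depths[node] or (node.is_leaf() and depths[node] < 0.8):
            tips = (
                [node.taxon.label]
                if node.is_leaf()
                else [leaf.taxon.label for leaf in node.leaf_iter()]
            )
            if any(t in genus_assign for t in tips):
                continue
            fam = fam_assign[tips[0]]
            counter[fam] += 1
            for t in tips:
                genus_assign[t] = f"Gen{fam[3:]}_{counter[fam]}"
    meta_map = {"family": fam_assign, "genus": genus_assign, "species": species}
    return tree, meta_map


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_bm_trait(
    tree: dendropy.Tree, rate: float, lam: float = 1.0, seed: int = 0
):
    """Draw one trait by (lambda-damped) Brownian motion on a tree.

    Returns a dict of tip label -> value; the draw is multivariate
    normal with covariance ``rate * V(lambda)``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    labels = _tree.tip_labels(tree)
    if rate == 0:
        return {lab: 0.0 for lab in labels}
    vcv, _ = _tree.vcv_matrix(tree, labels)
    cov = lam * vcv
    np.fill_diagonal(cov, np.diag(vcv))
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(labels)))
    x = np.sqrt(rate) * (chol @ rng.standard_normal(len(labels)))
    return dict(zip(labels, x))


def _diet_proportions(diet: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map the scalar diet trait to six food-item proportions.

    The trait loads on an insects-vs-leaves axis (the dominant contrast
    among the sampled hosts); remaining items get weak independent
    variation.  Rows are softmax-normalized so proportions sum to 1.
    """
    n = diet.size
    loadings = np.array([0.0, -1.0, 1.0, 0.0, 0.0, 0.0])  # fruit leaves insects bamboo gum flowers
    base = np.array([0.8, 0.3, 0.3, -1.5, -1.5, -0.5])
    logits = base[None, :] + diet[:, None] * loadings[None, :]
    logits = logits + 0.35 * rng.standard_normal((n, 6))
    expl = np.exp(logits - logits.max(axis=1, keepdims=True))
    return expl / expl.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------

def _deep_clade_membership(
    tree: dendropy.Tree, tau_deep: float, tip_order: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Group tips by their deepest ancestor above relative depth ``tau_deep``.

    Returns ``(clade_id, is_deep)`` aligned with ``tip_order``; a tip is
    deep-loaded when that ancestor subtends >= 2 tips.
    """
    depths = _tree.node_depths(tree)
    height = max(depths[leaf] for leaf in tree.leaf_node_iter())
    threshold = tau_deep * height
    index = {lab: i for i, lab in enumerate(tip_order)}
    clade_id = np.full(len(tip_order), -1, dtype=int)
    is_deep = np.zeros(len(tip_order), dtype=bool)
    next_id = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        # stem crosses the threshold: parent above, node at/below
        if depths[parent] < threshold <= depths[node] or (
            node.is_leaf() and depths[node] < threshold
        ):
            tips = (
                [node.taxon.label]
                if node.is_leaf()
                else [leaf.taxon.label for leaf in node.leaf_iter()]
            )
            idx = [index[t] for t in tips if t in index]
            if not idx or clade_id[idx[0]] >= 0:
                continue
            clade_id[idx] = next_id
            if len(idx) >= 2:
                is_deep[idx] = True
            next_id += 1
    return clade_id, is_deep


def simulate_community(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset under ``cfg`` (seed-deterministic)."""
    cfg.validate()
    master = cfg.seed
    host_tree, meta_map = _build_host_tree(cfg, derive_seed(master, "host_tree"))
    species = meta_map["species"]
    s_count = len(species)

    asv_width = len(str(cfg.n_asvs))
    asv_ids = [f"asv{j + 1:0{asv_width}d}" for j in range(cfg.n_asvs)]
    microbial_tree = simulate_yule_tree(
        cfg.n_asvs, derive_seed(master, "microbial_tree"), labels=asv_ids
    )

    # diet trait (phylogenetically structured) and habitat (unstructured)
    diet_raw = simulate_bm_trait(
        host_tree, rate=1.0, lam=cfg.lambda_diet, seed=derive_seed(master, "diet")
    )
    diet = np.asarray([diet_raw[s] for s in species])
    sd = diet.std()
    if sd > 0:
        diet = (diet - diet.mean()) / sd
    rng_traits = np.random.default_rng(derive_seed(master, "traits"))
    habitat = rng_traits.standard_normal(s_count)
    props = _diet_proportions(diet, rng_traits)
    traits = TraitMatrix(
        np.column_stack([props, habitat]),
        species,
        list(DIET_ITEMS) + ["habitat"],
    )

    # per-ASV effects
    vcv, _ = _tree.vcv_matrix(host_tree, species)
    chol = np.linalg.cholesky(vcv + 1e-12 * np.eye(s_count))
    rng_asv = np.random.default_rng(derive_seed(master, "asv_effects"))
    alpha = cfg.alpha_sd * rng_asv.standard_normal(cfg.n_asvs)
    g = cfg.sigma_phy * (chol @ rng_asv.standard_normal((s_count, cfg.n_asvs)))

    clade_id, is_deep = _deep_clade_membership(microbial_tree, cfg.tau_deep, asv_ids)
    n_clades = clade_id.max() + 1 if clade_id.size else 0
    clade_loading = rng_asv.standard_normal(max(n_clades, 1))
    u = np.where(is_deep, clade_loading[np.maximum(clade_id, 0)], 0.0)
    diet_effect = cfg.beta_diet * np.outer(diet, u)

    eta_species = (
        alpha[None, :]
        + g
        + diet_effect
        + cfg.sigma_noise * rng_asv.standard_normal((s_count, cfg.n_asvs))
    )

    # samples
    rng_samp = np.random.default_rng(derive_seed(master, "samples"))
    lo, hi = cfg.samples_per_species
    n_per = rng_samp.integers(lo, hi + 1, size=s_count)
    contaminant_ids = asv_ids[cfg.n_asvs - cfg.n_contaminants:] if cfg.n_contaminants else []
    contam_cols = np.arange(cfg.n_asvs - cfg.n_contaminants, cfg.n_asvs)

    rows = []
    sample_ids = []
    meta: list[SampleInfo] = []
    for si, sp in enumerate(species):
        for k in range(n_per[si]):
            sid = f"{sp}_s{k + 1:02d}"
            eta = eta_species[si] + cfg.sigma_individual * rng_samp.standard_normal(
                cfg.n_asvs
            )
            if cfg.n_contaminants:
                # contaminant tips are reserved: real signal never uses them
                eta = eta.copy()
                eta[contam_cols] = -np.inf
            p = np.exp(eta - eta[np.isfinite(eta)].max())
            p[~np.isfinite(p)] = 0.0
            p /= p.sum()
            depth = int(rng_samp.integers(cfg.read_depth[0], cfg.read_depth[1] + 1))
            counts = rng_samp.multinomial(depth, p)
            if cfg.n_contaminants:
                counts[contam_cols] += rng_samp.poisson(5.0, size=cfg.n_contaminants)
            rows.append(counts)
            sample_ids.append(sid)
            meta.append(
                SampleInfo(
                    sample_id=sid,
                    host_species=sp,
                    host_genus=meta_map["genus"][sp],
                    host_family=meta_map["family"][sp],
                    site="site1",
                    is_control=False,
                )
            )
    for c in range(cfg.n_controls):
        sid = f"control_{c + 1:02d}"
        counts = np.zeros(cfg.n_asvs, dtype=np.int64)
        if cfg.n_contaminants:
            depth = int(rng_samp.integers(2000, 5001))
            counts[contam_cols] = rng_samp.multinomial(
                depth, np.full(cfg.n_contaminants, 1.0 / cfg.n_contaminants)
            )
        rows.append(counts)
        sample_ids.append(sid)
        meta.append(
            SampleInfo(
                sample_id=sid,
                host_species="",
                host_genus="",
                host_family="",
                site="lab",
                is_control=True,
            )
        )
    table = AsvTable(np.asarray(rows, dtype=np.int64), sample_ids, asv_ids)
    return SyntheticDataset(host_tree, microbial_tree, table, meta, traits, cfg)


# ---------------------------------------------------------------------------
# Named study regimes
# ---------------------------------------------------------------------------

def phylosymbiosis_regime(seed: int = 0, **overrides) -> SimulationConfig:
    """Strong phylosymbiosis, no diet effect: host-structured ASV effects
    dominate both noise terms (positive control for the congruence tests)."""
    cfg = SimulationConfig(
        samples_per_species=(1, 3),
        n_asvs=150,
        read_depth=(1000, 2000),
        sigma_phy=1.6,
        beta_diet=0.0,
        sigma_noise=0.05,
        sigma_individual=0.05,
        alpha_sd=1.5,
        n_controls=0,
        n_contaminants=0,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def null_regime(seed: int = 0, **overrides) -> SimulationConfig:
    """No phylosymbiosis and no diet effect: communities differ only by
    unstructured species/individual noise (negative control)."""
    cfg = SimulationConfig(
        samples_per_species=(1, 3),
        n_asvs=150,
        read_depth=(1000, 2000),
        sigma_phy=0.0,
        beta_diet=0.0,
        sigma_noise=1.0,
        sigma_individual=0.2,
        alpha_sd=1.5,
        n_controls=0,
        n_contaminants=0,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def deep_diet_regime(seed: int = 0, **overrides) -> SimulationConfig:
    """Diet acting on deep microbial clades against strong per-ASV host
    structure.

    Per-ASV Brownian effects (``sigma_phy = 2``) recompose communities
    within clades, which partially cancels in deep-clade totals, while
    the diet effect (``beta_diet = 1``) is shared across each deep clade
    (``tau_deep = 0.2``).  Branch-weighted (UniFrac) metrics therefore
    see a better diet signal-to-noise ratio than metrics that weight
    every ASV equally.
    """
    cfg = SimulationConfig(
        samples_per_species=(1, 3),
        n_asvs=300,
        read_depth=(1000, 2000),
        sigma_phy=2.0,
        beta_diet=1.0,
        tau_deep=0.2,
        sigma_noise=0.5,
        sigma_individual=0.2,
        alpha_sd=1.5,
        n_controls=0,
        n_contaminants=0,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def write_bundle(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the full input bundle (TSVs, Newicks, config YAML) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "asv_table.tsv",
        "metadata": outdir / "metadata.tsv",
        "host_tree": outdir / "host_tree.nwk",
        "microbial_tree": outdir / "microbial_tree.nwk",
        "traits": outdir / "traits.tsv",
        "config": outdir / "config.yaml",
    }
    write_asv_table(dataset.table, paths["table"])
    write_metadata(dataset.meta, paths["metadata"])
    write_newick(dataset.host_tree, paths["host_tree"])
    write_newick(dataset.microbial_tree, paths["microbial_tree"])
    write_traits(dataset.traits, paths["traits"])
    cfg = asdict(dataset.true_params)
    for key in ("family_sizes", "samples_per_species", "read_depth"):
        cfg[key] = list(cfg[key])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths
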