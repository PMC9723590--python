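"""End-to-end phylosymbiosis analysis.

``run_phylosymbiosis`` executes the full grid: QC and rarefaction, the
four beta-diversity metrics plus Faith's PD, species-level aggregation
(one species-average table and ``n_random_pick`` random-pick
replicates), UPGMA + RF randomization + Mantel per dataset x metric,
phylogenetic signal (Blomberg's K, Pagel's lambda) on the first
``k_axes`` principal coordinates and on Faith's PD, PGLS of each
metric's PCo1 on diet and habitat PC1s, and sample-level PERMANOVA and
PERMDISP.  With the default four metrics and 10 random picks this is
the 44-test grid (4 metrics x 11 species-level datasets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation, diversity, phylosymbiosis, signal_traits
from .data_model import (
    AsvTable,
    TipNameMap,
    TraitMatrix,
    derive_seed,
    filter_min_depth,
    prune_and_rename,
    rarefy,
    read_asv_table,
    read_metadata,
    read_newick,
    read_traits,
    remove_control_asvs,
)
from .synthetic import SimulationConfig, SyntheticDataset, simulate_community

logger = logging.getLogger("phylosym")

__all__ = ["RunConfig", "PipelineResult", "run_phylosymbiosis", "load_inputs"]

DIET_ITEMS = ("fruit", "leaves", "insects", "bamboo", "gum", "flowers")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (defaults follow the study)."""

    # inputs: file paths ...
    table_path: str | None = None
    metadata_path: str | None = None
    host_tree_path: str | None = None
    microbial_tree_path: str | None = None
    traits_path: str | None = None
    # ... or a synthetic-data configuration
    synthetic: SimulationConfig | None = None

    rarefaction_depth: int = 2000
    metrics: tuple[str, ...] = diversity.BETA_METRICS
    include_faith_pd: bool = True
    n_random_pick: int = 10
    n_null_trees: int = 10000
    mantel_permutations: int = 999
    adonis_permutations: int = 999
    permdisp_permutations: int = 999
    signal_permutations: int = 1000
    k_axes: int = 5
    species_agg: str = "re_rarefy"  # or "renormalize"
    scale_diet_pca: bool = False
    tip_name_map: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "rarefaction_depth",
            "n_random_pick",
            "n_null_trees",
            "mantel_permutations",
            "adonis_permutations",
            "permdisp_permutations",
            "k_axes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        bad = [m for m in self.metrics if m not in diversity.BETA_METRICS]
        if bad:
            raise ValueError(f"unknown metrics: {bad}")
        if self.species_agg not in ("re_rarefy", "renormalize"):
            raise ValueError("species_agg must be 're_rarefy' or 'renormalize'")


@dataclass
class PipelineResult:
    """All result tables of a pipeline run."""

    rf_mantel: pd.DataFrame
    signal: pd.DataFrame
    pgls: pd.DataFrame
    adonis: pd.DataFrame
    permdisp: pd.DataFrame
    alpha: pd.DataFrame
    summary: pd.DataFrame
    trait_pcs: pd.DataFrame
    pcoa_coordinates: pd.DataFrame
    n_samples_retained: int
    seeds_used: dict[str, int]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spec = {
            "rf_mantel.tsv": self.rf_mantel,
            "signal.tsv": self.signal,
            "pgls.tsv": self.pgls,
            "adonis.tsv": self.adonis,
            "permdisp.tsv": self.permdisp,
            "alpha_diversity.tsv": self.alpha,
            "summary.tsv": self.summary,
            "trait_pcs.tsv": self.trait_pcs,
            "pcoa_coordinates.tsv": self.pcoa_coordinates,
        }
        for name, frame in spec.items():
            frame.to_csv(outdir / name, sep="\t", index=False, na_rep="NA")
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write(f"samples_retained\t{self.n_samples_retained}\n")
            for label, s in sorted(self.seeds_used.items()):
                fh.write(f"seed\t{label}\t{s}\n")


def load_inputs(cfg: RunConfig) -> SyntheticDataset:
    """Load the input bundle from files or simulate it."""
    if cfg.synthetic is not None:
        return simulate_community(cfg.synthetic)
    needed = ("table_path", "metadata_path", "host_tree_path", "microbial_tree_path", "traits_path")
    missing = [nm for nm in needed if getattr(cfg, nm) is None]
    if missing:
        raise ValueError(f"missing input paths (or set cfg.synthetic): {missing}")
    table = read_asv_table(cfg.table_path)
    meta = read_metadata(cfg.metadata_path)
    host = read_newick(cfg.host_tree_path)
    microbial = read_newick(cfg.microbial_tree_path)
    traits = read_traits(cfg.traits_path)
    return SyntheticDataset(host, microbial, table, meta, traits, None)


def _renormalize(table: AsvTable, depth: int) -> AsvTable:
    """Scale each row to sum ``depth`` with largest-remainder rounding."""
    counts = table.counts.astype(float)
    out = np.zeros_like(counts, dtype=np.int64)
    for i in range(table.n_samples):
        row = counts[i] * depth / counts[i].sum()
        base = np.floor(row).astype(np.int64)
        short = depth - base.sum()
        if short > 0:
            frac = row - base
            order = np.argsort(-frac, kind="stable")
            base[order[:short]] += 1
        out[i] = base
    return AsvTable(out, table.sample_ids, table.asv_ids)


def _trait_pc1s(traits: TraitMatrix, scale_diet: bool, species: list[str]) -> pd.DataFrame:
    frame = traits.to_frame().loc[species]
    diet_cols = [c for c in DIET_ITEMS if c in frame.columns]
    if len(diet_cols) >= 2:
        diet_tm = TraitMatrix.from_frame(frame[diet_cols])
        diet_pc1 = signal_traits.trait_pca(diet_tm, scale=scale_diet).pc(1)
    elif "diet" in frame.columns:
        diet_pc1 = frame["diet"] - frame["diet"].mean()
    else:
        raise ValueError("trait table lacks diet items or a 'diet' column")
    hab_cols = [c for c in frame.columns if c.startswith("habitat")]
    if len(hab_cols) >= 2:
        hab_tm = TraitMatrix.from_frame(frame[hab_cols])
        habitat_pc1 = signal_traits.trait_pca(hab_tm, scale=True).pc(1)
    elif len(hab_cols) == 1:
        habitat_pc1 = frame[hab_cols[0]] - frame[hab_cols[0]].mean()
    else:
        raise ValueError("trait table lacks habitat columns")
    return pd.DataFrame({"Diet_PC1": diet_pc1, "Habitat_PC1": habitat_pc1})


def run_phylosymbiosis(cfg: RunConfig, outdir=None) -> PipelineResult:
    """Run the full analysis; optionally write all result TSVs to ``outdir``."""
    cfg.validate()
    seeds: dict[str, int] = {}

    def stage_seed(label: str) -> int:
        s = derive_seed(cfg.seed, label)
        seeds[label] = s
        return s

    data = load_inputs(cfg)
    logger.info("inputs: %d samples x %d ASVs", data.table.n_samples, data.table.n_asvs)

    # ----- QC ------------------------------------------------------------
    table = data.table
    if any(m.is_control for m in data.meta):
        table = remove_control_asvs(table, data.meta)
    table = filter_min_depth(table, cfg.rarefaction_depth)
    table = rarefy(table, cfg.rarefaction_depth, stage_seed("rarefy"))
    table = table.drop_empty_asvs()
    if table.n_samples < 3:
        raise RuntimeError("QC: fewer than 3 samples retained")
    logger.info("after QC: %d samples x %d ASVs", table.n_samples, table.n_asvs)

    meta_by_id = {m.sample_id: m for m in data.meta}
    species = sorted({meta_by_id[s].host_species for s in table.sample_ids})

    # ----- host tree -----------------------------------------------------
    name_map = TipNameMap(cfg.tip_name_map) if cfg.tip_name_map else None
    host = data.host_tree
    try:
        host = prune_and_rename(host, species, name_map)
    except KeyError as exc:
        raise RuntimeError(f"host-tree pruning failed: {exc}") from exc
    host_patristic = phylosymbiosis.patristic_distances(host)

    # ----- species-level datasets ---------------------------------------
    avg = aggregation.mean_ceiling(table, data.meta)
    if cfg.species_agg == "re_rarefy":
        avg = rarefy(avg, cfg.rarefaction_depth, stage_seed("re_rarefy_species"))
    else:
        avg = _renormalize(avg, cfg.rarefaction_depth)
    picks = aggregation.random_pick(
        table, data.meta, cfg.n_random_pick, stage_seed("random_pick")
    )
    datasets: list[tuple[str, AsvTable]] = [("species_average", avg)]
    datasets += [
        (f"random_pick_{r + 1:02d}", picks[r]) for r in range(cfg.n_random_pick)
    ]

    # ----- traits --------------------------------------------------------
    trait_pcs = _trait_pc1s(data.traits, cfg.scale_diet_pca, species)

    # ----- per-dataset, per-metric tests ---------------------------------
    rf_rows = []
    signal_rows = []
    pgls_rows = []
    alpha_rows = []
    pcoa_frames = []
    for ds_name, ds_table in datasets:
        ds_table = ds_table.drop_empty_asvs()
        for metric in cfg.metrics:
            dm = diversity.beta_diversity(metric, ds_table, data.microbial_tree)
            dendro = phylosymbiosis.upgma(dm)
            rf = phylosymbiosis.rf_randomization_test(
                host, dendro, cfg.n_null_trees, stage_seed(f"rf:{ds_name}:{metric}")
            )
            man = phylosymbiosis.mantel(
                host_patristic.reorder(dm.labels),
                dm,
                cfg.mantel_permutations,
                stage_seed(f"mantel:{ds_name}:{metric}"),
            )
            rf_rows.append(
                (ds_name, metric, rf.observed_rf, rf.p_value, man.r, man.p_value)
            )
            ord_res = signal_traits.pcoa(dm, k=cfg.k_axes)
            n_axes = ord_res.coordinates.shape[1]
            if ds_name == "species_average":
                coords = pd.DataFrame(
                    ord_res.coordinates,
                    index=ord_res.labels,
                    columns=[f"PCo{a + 1}" for a in range(n_axes)],
                )
                coords.insert(0, "metric", metric)
                coords.insert(0, "species", coords.index)
                pcoa_frames.append(coords.reset_index(drop=True))
            for axis in range(1, n_axes + 1):
                vals = ord_res.axis(axis)
                k_res = signal_traits.blomberg_k(
                    host,
                    vals,
                    cfg.signal_permutations,
                    stage_seed(f"k:{ds_name}:{metric}:{axis}"),
                )
                l_res = signal_traits.pagel_lambda(host, vals)
                signal_rows.append(
                    (ds_name, metric, f"PCo{axis}", "blomberg_k", k_res.estimate, k_res.p_value)
                )
                signal_rows.append(
                    (ds_name, metric, f"PCo{axis}", "pagel_lambda", l_res.estimate, l_res.p_value)
                )
            resp = ord_res.axis(1)
            fit = signal_traits.pgls(host, resp, trait_pcs, interaction=True)
            pgls_rows.append(
                (
                    ds_name,
                    metric,
                    fit.coefficient_p_values.get("Diet_PC1", np.nan),
                    fit.coefficient_p_values.get("Habitat_PC1", np.nan),
                    fit.coefficient_p_values.get("Diet_PC1:Habitat_PC1", np.nan),
                    fit.model_p_value,
                    fit.aic,
                )
            )
        if cfg.include_faith_pd:
            pd_vec = diversity.faith_pd(ds_table, data.microbial_tree)
            series = pd_vec.to_series()
            for sp, val in series.items():
                alpha_rows.append((ds_name, sp, val))
            k_res = signal_traits.blomberg_k(
                host, series, cfg.signal_permutations, stage_seed(f"k:{ds_name}:faith_pd")
            )
            l_res = signal_traits.pagel_lambda(host, series)
            signal_rows.append(
                (ds_name, "faith_pd", "PD", "blomberg_k", k_res.estimate, k_res.p_value)
            )
            signal_rows.append(
                (ds_name, "faith_pd", "PD", "pagel_lambda", l_res.estimate, l_res.p_value)
            )
            fit = signal_traits.pgls(host, series, trait_pcs, interaction=True)
            pgls_rows.append(
                (
                    ds_name,
                    "faith_pd",
                    fit.coefficient_p_values.get("Diet_PC1", np.nan),
                    fit.coefficient_p_values.get("Habitat_PC1", np.nan),
                    fit.coefficient_p_values.get("Diet_PC1:Habitat_PC1", np.nan),
                    fit.model_p_value,
                    fit.aic,
                )
            )

    # ----- sample-level PERMANOVA / PERMDISP -----------------------------
    sample_design = pd.DataFrame(
        {
            "host_family": [meta_by_id[s].host_family for s in table.sample_ids],
            "host_genus": [meta_by_id[s].host_genus for s in table.sample_ids],
            "host_species": [meta_by_id[s].host_species for s in table.sample_ids],
            "Diet_PC1": [
                trait_pcs.loc[meta_by_id[s].host_species, "Diet_PC1"]
                for s in table.sample_ids
            ],
            "Habitat_PC1": [
                trait_pcs.loc[meta_by_id[s].host_species, "Habitat_PC1"]
                for s in table.sample_ids
            ],
        },
        index=table.sample_ids,
    )
    formula = "Diet_PC1*Habitat_PC1 + host_family/host_genus/host_species"
    adonis_rows = []
    disp_rows = []
    for metric in cfg.metrics:
        dm = diversity.beta_diversity(metric, table, data.microbial_tree)
        res = signal_traits.permanova(
            dm,
            sample_design,
            formula,
            cfg.adonis_permutations,
            stage_seed(f"adonis:{metric}"),
        )
        for term, row in res.table.iterrows():
            adonis_rows.append(
                (metric, term, row["df"], row["sum_sq"], row["r2"], row["pseudo_f"], row["p_value"])
            )
        for level in ("host_family", "host_genus", "host_species"):
            groups = sample_design[level]
            if (groups.value_counts() >= 2).sum() < 2:
                continue
            disp = signal_traits.permdisp(
                dm,
                groups,
                cfg.permdisp_permutations,
                stage_seed(f"permdisp:{metric}:{level}"),
            )
            disp_rows.append((metric, level, disp.f_statistic, disp.p_value))

    # ----- assemble ------------------------------------------------------
    rf_mantel = pd.DataFrame(
        rf_rows,
        columns=["dataset", "metric", "rf", "rf_p", "mantel_r", "mantel_p"],
    )
    summary = (
        rf_mantel[rf_mantel["dataset"] == "species_average"]
        .rename(
            columns={
                "metric": "distance_matrix",
                "rf": "RF",
                "rf_p": "RF_p",
                "mantel_r": "Mantel_r",
                "mantel_p": "Mantel_p",
            }
        )
        .drop(columns="dataset")
        .reset_index(drop=True)
    )
    result = PipelineResult(
        rf_mantel=rf_mantel,
        signal=pd.DataFrame(
            signal_rows,
            columns=["dataset", "metric", "axis", "statistic", "estimate", "p_value"],
        ),
        pgls=pd.DataFrame(
            pgls_rows,
            columns=[
                "dataset",
                "metric",
                "diet_p",
                "habitat_p",
                "interaction_p",
                "model_p",
                "aic",
            ],
        ),
        adonis=pd.DataFrame(
            adonis_rows,
            columns=["metric", "term", "df", "sum_sq", "r2", "pseudo_f", "p_value"],
        ),
        permdisp=pd.DataFrame(
            disp_rows, columns=["metric", "grouping", "f_statistic", "p_value"]
        ),
        alpha=pd.DataFrame(alpha_rows, columns=["dataset", "species", "faith_pd"]),
        summary=summary,
        trait_pcs=trait_pcs.rename_axis("species").reset_index(),
        pcoa_coordinates=(
            pd.concat(pcoa_frames, ignore_index=True) if pcoa_frames else pd.DataFrame()
        ),
        n_samples_retained=table.n_samples,
        seeds_used=seeds,
    )
    if outdir is not None:
        result.write(outdir)
    return result
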