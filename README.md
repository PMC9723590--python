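# phylosym

Phylosymbiosis analysis of host-associated microbiomes: from an ASV
count table and a pair of phylogenies to dendrogram-congruence tests,
distance-matrix correlations, phylogenetic signal, and
phylogenetically-informed trait regression.

**Phylosymbiosis** is the pattern in which more closely related host
species harbor more similar microbial communities. The package
implements the comparative workflow used to test it in multi-species
gut-microbiome studies (the motivating design is a 15-species,
3-family clade of wild lemurs sampled across contrasting habitats),
and ships a synthetic-data generator so the entire pipeline is testable
without any sequence data.

## What it computes

Given a samples × ASVs count table, per-sample host metadata, a rooted
microbial phylogeny, a host phylogeny, and a per-species trait table:

1. **QC** — remove every ASV detected in PCR negative controls, drop
   samples with fewer than 2000 reads, rarefy to 2000 reads per sample
   (multivariate-hypergeometric subsampling, stable per-sample seeds).
2. **Diversity** — Bray-Curtis, Jaccard, unweighted and weighted
   UniFrac between samples; Faith's phylogenetic diversity (PD) per
   sample. For communities A and B over branches *e* with lengths
   *bₑ*:

   - unweighted UniFrac = Σ*bₑ*[branch leads to exactly one of A, B] / Σ*bₑ*[branch leads to either],
   - weighted UniFrac = Σ*bₑ*·|p<sub>e</sub><sup>A</sup> − p<sub>e</sub><sup>B</sup>|, where p<sub>e</sub><sup>X</sup> is the fraction of X's reads descending through *e*.

3. **Aggregation** — one community per host species, by the
   "mean ceiling" (⌈mean count⌉ across the species' samples) and by
   repeated random picking of one sample per species (10 replicates,
   without replacement when a species has enough samples).
4. **Congruence** — UPGMA dendrogram per dataset × metric; normalized
   Robinson-Foulds distance to the host tree with significance from
   10,000 randomized topologies (add-one permutation p); Mantel test
   (Pearson, 999 permutations, one-tailed) between each beta-diversity
   matrix and host patristic distances.
5. **Signal** — Blomberg's *K* (K = 1 under Brownian motion;
   permutation test) and Pagel's λ (ML over [0, 1]; likelihood-ratio
   test) on the first five principal coordinates of each metric and on
   Faith's PD.
6. **Trait models** — PGLS of each metric's PCo1 (and PD) on
   Diet_PC1 × Habitat_PC1 under a Brownian residual covariance;
   PERMANOVA (adonis-style sequential SS, 999 permutations) with the
   formula `Diet_PC1*Habitat_PC1 + Family/Genus/Species`; PERMDISP
   dispersion-homogeneity checks.

With the default four metrics and 10 random-pick replicates the
congruence grid is 4 × 11 = 44 RF tests and 44 Mantel tests.

## Worked example

```python
from phylosym import SimulationConfig, RunConfig, run_phylosymbiosis

cfg = RunConfig(
    synthetic=SimulationConfig(seed=11),  # 15 species, 3 families, 1-30 samples each
    n_null_trees=1000,
    seed=11,
)
result = run_phylosymbiosis(cfg, outdir="results/demo")
print(result.summary.to_string(index=False))
```

prints the species-average congruence table (one row per metric):

```
   distance_matrix       RF     RF_p  Mantel_r  Mantel_p
       bray_curtis 0.500000 0.000999  0.760393     0.001
           jaccard 0.500000 0.000999  0.531617     0.001
unweighted_unifrac 0.750000 0.002997  0.414874     0.001
  weighted_unifrac 0.583333 0.000999  0.648467     0.001
```

`RF` is the normalized Robinson-Foulds distance between the UPGMA
dendrogram of the species-average microbiomes and the host phylogeny
(0 = identical branching order, 1 = no shared bipartitions); `RF_p` is
the fraction of randomized topologies at least as congruent (add-one
rule). `Mantel_r` is the Pearson correlation between microbiome
distance and host patristic distance over all species pairs; all four
metrics here detect phylosymbiosis, as designed into the generator's
default regime (host-structured ASV effects with σ_phy = 2).
`result` also carries the per-axis signal table, PGLS and PERMANOVA
tables, Faith's PD, and PCoA coordinates; `outdir` receives one TSV
per table plus a log of every seed consumed.

The same analysis is scriptable from a shell:

```bash
phylosym simulate --seed 11 --outdir bundle/
phylosym run --indir bundle/ --seed 11 --outdir results/
```

## Layout

- `phylosym.data_model` — tables, metadata, distance matrices, traits,
  Newick I/O, QC filters, rarefaction
- `phylosym.diversity` — the four beta metrics and Faith's PD
- `phylosym.aggregation` — mean-ceiling and random-pick species tables
- `phylosym.phylosymbiosis` — UPGMA, Robinson-Foulds + randomization
  null, patristic distances, Mantel
- `phylosym.signal_traits` — PCoA, Blomberg's K, Pagel's λ, PGLS,
  PERMANOVA, PERMDISP, trait PCA
- `phylosym.synthetic` — host/microbial tree, trait, and read-count
  simulator with named regimes
- `phylosym.pipeline` / `phylosym.cli` — orchestration and the
  `phylosym` command

See `docs/methods.md` for the statistical details and design choices.
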