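# Methods

This note documents the statistical machinery, the synthetic-data
model, the numerical choices, and the limits of what the test suite
demonstrates.

## The analysis model

The package tests three predictions of phylosymbiosis against a host
phylogeny, plus ecological trait correlates, for a multi-species
microbiome survey.

**Congruence.** Each species-level beta-diversity matrix is clustered
with UPGMA (average linkage; merge height = half the average-linkage
distance, so the dendrogram's cophenetic distances reproduce an
ultrametric input exactly). Congruence with the host tree is the
normalized Robinson-Foulds distance: the number of non-trivial unrooted
bipartitions present in exactly one tree, divided by the total number
of non-trivial bipartitions in both trees. For two fully resolved
trees on *n* tips this denominator equals 2(*n* − 3); stating it as the
both-trees total also covers multifurcating dendrograms arising from
tied merges. Significance compares the observed RF to RF distances
between the host tree and randomized topologies (coalescent-style
random joins of a permuted label set, the same null as the standard
random-tree generators), with the add-one estimate
p = (1 + #{null ≤ observed}) / (1 + n_null). The add-one rule avoids
p = 0 and makes the smallest attainable p at 10,000 draws just below
10⁻⁴.

**Distance correlation.** The Mantel statistic is the Pearson
correlation of the n(n−1)/2 off-diagonal entries of the microbiome and
host-patristic matrices; the permutation p (one-tailed "greater",
since phylosymbiosis predicts a positive correlation) jointly permutes
rows and columns of one matrix.

**Phylogenetic signal.** Beta diversity is reduced to univariate
species scores via principal coordinates (classical scaling of
−½D² double-centered; coordinates from positive eigenvalues only;
negative eigenvalues are reported untouched — no Cailliez/Lingoes
correction). On each of the first five axes, and on Faith's PD:

- *Blomberg's K* = (MSE₀/MSE) / E_BM[MSE₀/MSE], with MSE₀ the mean
  square about the GLS (phylogenetic) mean, MSE the generalized mean
  square under the Brownian covariance V, and
  E_BM = (tr V − n/(1ᵀV⁻¹1))/(n − 1). K is exactly 1 on a star
  phylogeny and centers on 1 under Brownian motion. The p-value
  shuffles trait values across tips (default 1000 permutations,
  one-tailed on K_perm ≥ K_obs).
- *Pagel's λ* multiplies the off-diagonal entries of V; the ML
  estimate profiles λ on [0, 1] (off-diagonals cannot exceed the tip
  variance on an ultrametric tree; a wider bound can be passed
  explicitly), maximizing the Brownian likelihood with rate and root
  state profiled analytically. p is a χ²(1) likelihood-ratio test
  against λ = 0. A star phylogeny is flagged unidentifiable.

**Trait models.** PGLS regresses a univariate response (a metric's
PCo1, or PD) on Diet_PC1, Habitat_PC1 and their product, with residual
covariance V(λ_used); λ_used defaults to 1 (pure Brownian motion, the
common tool default) with an `"ml"` option. The GLS solve is
statsmodels'; AIC is −2·logLik + 2(p + 2), counting coefficients plus
the rate. PERMANOVA decomposes the Gower-centered inner-product matrix
sequentially over the expanded formula
`Diet_PC1*Habitat_PC1 + Family/Genus/Species`
(A\*B → A + B + A:B; A/B/C → A + A:B + A:B:C), each term tested by
pseudo-F against the residual under free permutation of sample labels.
PERMDISP embeds samples by PCoA (negative-eigenvalue axes kept as
imaginary coordinates whose squared distances subtract), computes each
sample's distance to its group centroid, and permutes those distances
across samples for a one-way F test. Dispersion checks run on the
family/genus/species groupings; continuous predictors are not binned.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| rarefaction depth | 2000 reads | common depth after QC; samples below it are dropped |
| random-pick replicates | 10 | species-level datasets besides the mean-ceiling table |
| n_null_trees | 10,000 | randomized topologies per RF test |
| Mantel / adonis / PERMDISP permutations | 999 | permutation-test resolution (min p = 0.001) |
| signal permutations | 1000 | Blomberg's K null |
| k_axes | 5 | principal coordinates tested for signal |
| PGLS λ_used | 1.0 | Brownian residual covariance |

Seeds: a single master seed fans out to every stage (and to every
sample within the rarefaction stage) by SHA-256 hashing of a stage
label, so results are independent of iteration order and replayable
stage by stage; the run log records each derived seed.

## The synthetic-data generator

The generator emulates the motivating study design: 15 host species in
three monophyletic families (5 + 7 + 3), 1–30 samples per species,
read depths uniform on [2000, 10000] to exercise rarefaction, optional
PCR negative controls carrying a designated contaminant ASV set (also
spiked into real samples, so control filtering is testable end to end).

Host tree: three Yule subtrees joined on a fixed backbone (family
stems diverging at relative depths 0 and 0.15, family crowns starting
at 0.5), rescaled to unit depth; genera are clades whose stem crosses
depth 0.8. Microbial tree: a Yule tree over the ASVs.

Per-ASV log-abundance for species *s*:

η(s, j) = α_j + g_j(s) + β_diet·d_s·u_j·[j deep] + ε_species + ε_individual

- α_j ~ N(0, α_sd²): baseline unevenness of the community;
- g_j ~ BM(σ_phy) on the host tree: host-structured effects, the
  source of phylosymbiosis;
- d_s: diet trait, Brownian with Pagel damping λ_diet = 0.7 (the
  habitat trait is unstructured, matching the empirical finding that
  habitat carries no phylogenetic signal); the six food-item
  proportions are a softmax of an insects-vs-leaves axis driven by
  d_s;
- u_j: a loading shared by all members of a *deep clade* — a microbial
  clade of ≥ 2 tips whose stem crosses relative depth τ_deep — so diet
  moves old clades coherently;
- softmax over ASVs → relative abundances → multinomial reads.

Defaults (σ_phy = 2.0, α_sd = 3.0, 400 ASVs, σ_noise = σ_ind = 0.3,
β_diet = 1.0, τ_deep = 0.3) were calibrated once, at design time, so
that the default regime reproduces the empirical picture: all four
metrics detect phylosymbiosis (RF roughly 0.4–0.9 with significant
randomization tests; Mantel r roughly 0.4–0.9), including the
presence-based metrics — which requires a wide abundance distribution,
since with evenly abundant ASVs at depth 2000 presence saturates and
Jaccard/unweighted UniFrac carry no host signal.

Three named regimes freeze the study conditions for testing:
`phylosymbiosis_regime` (strong host structure, no diet effect),
`null_regime` (no host structure, noise only), and `deep_diet_regime`
(σ_phy = 2, β_diet = 1, τ_deep = 0.2, σ_noise = 0.5, 300 ASVs). In the
deep-diet regime, independent per-ASV Brownian effects partially
cancel in deep-clade totals while the clade-shared diet effect does
not, so branch-weighted (UniFrac) metrics see a better diet
signal-to-noise ratio than star-phylogeny metrics — the pattern the
acceptance suite verifies with PGLS on PCo1 over 100 simulations.

**What the generator does not emulate:** sequencing error and chimeras
(counts are exact multinomials), taxonomic structure of contamination,
seasonal or site effects, overdispersion beyond the softmax-normal
link, correlation between diet and habitat, and real diets' multi-axis
variation (the synthetic diet is one latent axis, so its PCA PC1 share
is higher than typical empirical values). Passing tests demonstrate
the statistical machinery is correct and calibrated under this model —
not that any particular empirical dataset will show phylosymbiosis.

## Numerical choices

- UPGMA ties break toward the pair whose member labels sort first
  (deterministic across platforms).
- Rarefaction uses the multivariate hypergeometric distribution
  (without replacement), per-sample seeded by a stable hash, so a
  table's rarefaction is invariant to sample order. Species-average
  (mean-ceiling) tables are re-rarefied to the common depth by default
  (row sums exceed the depth after the ceiling); a largest-remainder
  renormalization is available by flag.
- Distance matrices must be symmetric within 1e-12 with a zero
  diagonal; pairs of all-zero samples are an error, not silently 0.
- Weighted UniFrac defaults to the unnormalized sum (the common tool
  convention); the normalized variant is a flag. Faith's PD includes
  the stem path to the root by default (tool convention); a no-root
  variant is a flag.
- PCoA eigenvalues below 1e-10 (relative) are treated as zero;
  requesting more axes than positive eigenvalues truncates with a
  warning.
- The λ likelihood returns −∞ for non-positive-definite covariances,
  so the bounded search stays inside the feasible region.
- p-values of all permutation tests use the add-one rule.

## Known limitations

- The RF randomization test is conservative for moderate tip counts:
  random 15-tip topologies share on average only ~0.15 bipartitions,
  so the null RF distribution is concentrated near 1 and the
  achievable rejection probability at nominal α = 0.05 is about
  0.02–0.03. This is a property of the discrete statistic, not of the
  implementation; the Mantel, PERMANOVA and PERMDISP tests are
  correctly calibrated at the 5% level in simulation.
- PGLS fixes λ_used rather than profiling it by default; for traits
  with weak signal this can overcorrect.
- PERMANOVA permutes labels freely (no strata/blocks), as in the
  additive-SS convention it follows; nested designs with few
  upper-level units can be liberal.
- The formula mini-language supports `+`, `*`, `:`, `/` only.
- The RF denominator choice (both-trees total) is a declared
  convention; other normalizations exist for non-binary trees.
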