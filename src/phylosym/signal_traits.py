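"""Ordination, phylogenetic signal, and trait-correlation models.

The microbiome enters these analyses as univariate summaries (principal
coordinates of a beta-diversity matrix, or Faith's PD), which are then
tested for phylogenetic signal (Blomberg's K, Pagel's lambda) and
regressed on ecological traits with phylogenetically generalized least
squares (PGLS).  Multivariate counterparts operate directly on the
distance matrix: PERMANOVA (adonis-style sequential decomposition) and
PERMDISP (homogeneity of within-group dispersions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
import statsmodels.api as sm

from . import _tree
from .data_model import DistanceMatrix, TraitMatrix, derive_seed

__all__ = [
    "PcoaResult",
    "PcaResult",
    "SignalResult",
    "PglsResult",
    "PermanovaResult",
    "PermdispResult",
    "pcoa",
    "blomberg_k",
    "pagel_lambda",
    "pgls",
    "permanova",
    "permdisp",
    "trait_pca",
    "expand_formula",
]


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Classical-scaling (PCoA) result.

    ``coordinates`` holds one column per retained positive-eigenvalue
    axis; ``eigenvalues`` lists all eigenvalues in non-increasing order
    (negative ones flag a non-Euclidean input and are excluded from
    ``proportion_explained``).
    """

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def axis(self, k: int) -> pd.Series:
        """1-based principal coordinate axis as a labelled series."""
        return pd.Series(self.coordinates[:, k - 1], index=self.labels, name=f"PCo{k}")


def pcoa(dm: DistanceMatrix, k: int | None = None) -> PcoaResult:
    """Principal coordinate analysis by classical scaling.

    Double-centers ``-0.5 * D**2``, eigendecomposes, and scales the
    eigenvectors of positive eigenvalues by the square root of their
    eigenvalue.  For Euclidean-embeddable input the coordinates
    reproduce the distances exactly.  No negative-eigenvalue correction
    is applied; negative eigenvalues are reported as such.
    """
    n = dm.n
    d2 = dm.values**2
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    gower = -0.5 * centering @ d2 @ centering
    gower = 0.5 * (gower + gower.T)
    eigval, eigvec = np.linalg.eigh(gower)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval).max() if n else 0.0)
    positive = eigval > tol
    n_pos = int(positive.sum())
    if k is None:
        k_eff = n_pos
    else:
        if k > n_pos:
            warnings.warn(
                f"requested {k} axes but only {n_pos} positive eigenvalues; truncating"
            )
        k_eff = min(k, n_pos)
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    pos_sum = eigval[positive].sum() if n_pos else 1.0
    proportions = eigval[:k_eff] / pos_sum
    return PcoaResult(list(dm.labels), coords, eigval, proportions)


@dataclass
class PcaResult:
    """PCA of a trait table: per-species scores, loadings, variance shares."""

    species_ids: list[str]
    trait_names: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    proportion_explained: np.ndarray

    def pc(self, k: int) -> pd.Series:
        return pd.Series(self.scores[:, k - 1], index=self.species_ids, name=f"PC{k}")


def trait_pca(traits: TraitMatrix, scale: bool = False) -> PcaResult:
    """Column-centered (optionally standardized) PCA of a trait matrix."""
    x = np.asarray(traits.values, dtype=float)
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("trait PCA needs >= 3 species and >= 2 traits")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = [t for t, s in zip(traits.trait_names, sd) if s == 0]
        if zero:
            raise ValueError(f"zero-variance traits cannot be standardized: {zero}")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2
    proportions = var / var.sum() if var.sum() > 0 else var
    return PcaResult(
        list(traits.species_ids), list(traits.trait_names), scores, vt.T, proportions
    )


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    """A phylogenetic-signal statistic with its test."""

    statistic_name: str
    estimate: float
    p_value: float
    n_permutations: int | None = None
    lr_statistic: float | None = None
    log_likelihood: float | None = None
    identifiable: bool = True


def _trait_vector(tree: dendropy.Tree, trait) -> tuple[np.ndarray, np.ndarray]:
    """Align a per-species trait with the tree tips; return (x, V)."""
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    labels = _tree.tip_labels(tree)
    missing = [lab for lab in labels if lab not in trait]
    if missing:
        raise KeyError(f"trait missing for tips: {missing}")
    x = np.asarray([float(trait[lab]) for lab in labels])
    vcv, _ = _tree.vcv_matrix(tree, labels)
    return x, vcv


def blomberg_k(
    tree: dendropy.Tree,
    trait,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SignalResult:
    """Blomberg's K with a tip-shuffling permutation test.

    K is the ratio of the observed mean squared deviation from the
    phylogenetic (GLS) mean over the Brownian-motion mean square,
    standardized by its expectation under Brownian motion, so K = 1 for
    a trait evolving by pure drift; K > 1 means close relatives are more
    similar than drift predicts.  The one-tailed p-value counts
    permutations with K at least as large as observed.
    """
    x, vcv = _trait_vector(tree, trait)
    n = x.size
    if np.allclose(x, x[0]):
        raise ValueError("trait has zero variance")
    vinv = np.linalg.inv(vcv)
    w = vinv @ np.ones(n)
    denom_w = w.sum()
    expected = (np.trace(vcv) - n / denom_w) / (n - 1)

    def k_stat(mat: np.ndarray) -> np.ndarray:
        # mat: n x m column-wise traits
        ahat = (w @ mat) / denom_w
        dev = mat - ahat
        mse0 = (dev**2).sum(axis=0) / (n - 1)
        mse = np.einsum("im,ij,jm->m", dev, vinv, dev) / (n - 1)
        return (mse0 / mse) / expected

    k_obs = float(k_stat(x[:, None])[0])
    p = np.nan
    if n_permutations and n_permutations > 0:
        rng = np.random.default_rng(derive_seed(seed, "blomberg_k"))
        perms = np.column_stack(
            [x[rng.permutation(n)] for _ in range(n_permutations)]
        )
        k_perm = k_stat(perms)
        p = float((1.0 + np.sum(k_perm >= k_obs - 1e-12)) / (1.0 + n_permutations))
    return SignalResult("blomberg_k", k_obs, p, n_permutations=n_permutations)


def _bm_loglik(x: np.ndarray, v: np.ndarray) -> float:
    """Profile ML log-likelihood of a Brownian model with covariance
    ``sigma2 * v`` (root state and rate maximized analytically)."""
    n = x.size
    try:
        cho = linalg.cho_factor(v, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    vinv_one = linalg.cho_solve(cho, np.ones(n))
    ahat = (vinv_one @ x) / vinv_one.sum()
    dev = x - ahat
    quad = dev @ linalg.cho_solve(cho, dev)
    sigma2 = quad / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def _lambda_cov(vcv: np.ndarray, lam: float) -> np.ndarray:
    out = lam * vcv
    np.fill_diagonal(out, np.diag(vcv))
    return out


def pagel_lambda(
    tree: dendropy.Tree,
    trait,
    lambda_max: float = 1.0,
) -> SignalResult:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test.

    Lambda scales the off-diagonal (shared-history) entries of the
    Brownian covariance: 0 means the trait is independent of the
    phylogeny, 1 means pure Brownian motion.  The search is bounded to
    ``[0, lambda_max]`` (1 for an ultrametric tree, where off-diagonals
    cannot exceed the tip variance).  p compares the ML fit against
    lambda = 0 with a chi-squared(1) likelihood ratio.
    """
    x, vcv = _trait_vector(tree, trait)
    if np.allclose(x, x[0]):
        raise ValueError("trait has zero variance")
    offdiag = vcv - np.diag(np.diag(vcv))
    if np.abs(offdiag).max() < 1e-12 * np.diag(vcv).max():
        # star phylogeny: likelihood is flat in lambda
        return SignalResult(
            "pagel_lambda", np.nan, np.nan, lr_statistic=np.nan, identifiable=False
        )

    def nll(lam: float) -> float:
        return -_bm_loglik(x, _lambda_cov(vcv, lam))

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, lambda_max), method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [(nll(0.0), 0.0), (nll(lambda_max), lambda_max), (res.fun, res.x)]
    best_nll, best_lam = min(candidates)
    ll0 = _bm_loglik(x, _lambda_cov(vcv, 0.0))
    lr = max(0.0, 2.0 * (-best_nll - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult(
        "pagel_lambda",
        float(best_lam),
        p,
        lr_statistic=float(lr),
        log_likelihood=float(-best_nll),
    )


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PglsResult:
    """Phylogenetic generalized least squares fit."""

    coefficients: pd.Series
    coefficient_p_values: pd.Series
    model_p_value: float
    aic: float
    lambda_used: float
    log_likelihood: float
    residual_df: int
    perfect_fit: bool = False


def pgls(
    tree: dendropy.Tree,
    response,
    predictors: TraitMatrix | pd.DataFrame,
    interaction: bool = False,
    lambda_used: float | str = 1.0,
) -> PglsResult:
    """Regression of a per-species response on traits under a
    phylogenetic residual covariance.

    ``lambda_used`` is the Pagel transform applied to the Brownian
    covariance (default 1 = pure Brownian motion, the usual tool
    default); ``"ml"`` profiles lambda by maximum likelihood.  With
    ``interaction=True`` all pairwise products of the predictor columns
    are appended.  AIC counts the coefficients, the root state being in
    them, plus the rate: ``-2 logLik + 2 (p + 2)``.
    """
    if isinstance(predictors, TraitMatrix):
        xframe = predictors.to_frame()
    else:
        xframe = predictors.copy()
    if isinstance(response, pd.Series):
        y_by = response.to_dict()
    else:
        y_by = dict(response)
    labels = _tree.tip_labels(tree)
    missing = [lab for lab in labels if lab not in y_by or lab not in xframe.index]
    if missing:
        raise KeyError(f"response or predictors missing for tips: {missing}")
    xframe = xframe.loc[labels]
    if interaction:
        cols = list(xframe.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                xframe[f"{cols[i]}:{cols[j]}"] = (
                    xframe[cols[i]] * xframe[cols[j]]
                )
    y = np.asarray([y_by[lab] for lab in labels], dtype=float)
    n, p = xframe.shape
    if n <= p + 2:
        raise ValueError(f"too few species ({n}) for {p} predictors")
    design = sm.add_constant(xframe.to_numpy(dtype=float), has_constant="add")
    names = ["intercept"] + list(xframe.columns)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns by greedy rank check
        bad = []
        kept = design[:, :1]
        for jcol, name in enumerate(names[1:], start=1):
            cand = np.column_stack([kept, design[:, jcol]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(name)
            else:
                kept = cand
        raise ValueError(f"singular design; collinear columns: {bad}")
    vcv, _ = _tree.vcv_matrix(tree, labels)

    def fit_for(lam: float):
        v = _lambda_cov(vcv, lam)
        return sm.GLS(y, design, sigma=v).fit()

    if lambda_used == "ml":
        res = optimize.minimize_scalar(
            lambda lam: -fit_for(lam).llf, bounds=(0.0, 1.0), method="bounded"
        )
        cands = [(-fit_for(0.0).llf, 0.0), (-fit_for(1.0).llf, 1.0), (res.fun, res.x)]
        _, lam = min(cands)
    else:
        lam = float(lambda_used)
    fit = fit_for(lam)
    perfect = bool(fit.ssr < 1e-12 * max(1.0, float(y @ y)))
    if perfect:
        warnings.warn("residual sum of squares is ~0; inference is degenerate")
    coeffs = pd.Series(fit.params, index=names)
    pvals = pd.Series(fit.pvalues, index=names)
    aic = -2.0 * fit.llf + 2.0 * (p + 2)
    return PglsResult(
        coefficients=coeffs,
        coefficient_p_values=pvals,
        model_p_value=float(fit.f_pvalue) if p > 0 else np.nan,
        aic=float(aic),
        lambda_used=float(lam),
        log_likelihood=float(fit.llf),
        residual_df=int(n - p - 1),
        perfect_fit=perfect,
    )


# ---------------------------------------------------------------------------
# PERMANOVA (adonis) and PERMDISP
# ---------------------------------------------------------------------------

def expand_formula(formula: str | Sequence[str]) -> list[str]:
    """Expand an adonis-style formula into an ordered term list.

    ``A*B`` becomes ``A + B + A:B``; nesting ``A/B/C`` becomes
    ``A + A:B + A:B:C``; explicit ``A:B`` terms pass through.
    """
    if isinstance(formula, str):
        tokens = [t.strip() for t in formula.split("+") if t.strip()]
    else:
        tokens = [str(t) for t in formula]
    terms: list[str] = []

    def push(term: str) -> None:
        if term not in terms:
            terms.append(term)

    for tok in tokens:
        if "*" in tok:
            parts = [p.strip() for p in tok.split("*")]
            for p in parts:
                push(p)
            push(":".join(parts))
        elif "/" in tok:
            parts = [p.strip() for p in tok.split("/")]
            for i in range(len(parts)):
                push(":".join(parts[: i + 1]))
        else:
            push(tok)
    return terms


def _term_columns(term: str, design: pd.DataFrame) -> np.ndarray:
    """Model-matrix columns for one term (full dummy sets for factors)."""
    blocks: list[np.ndarray] = []
    for comp in term.split(":"):
        if comp not in design.columns:
            raise KeyError(f"formula component {comp!r} not in design table")
        col = design[comp]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col.astype(str))
            blocks.append(dummies.to_numpy(dtype=float))
    out = blocks[0]
    for blk in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, blk).reshape(len(design), -1)
    return out


@dataclass
class PermanovaResult:
    """Sequential (additive-SS) distance-based permutational ANOVA."""

    table: pd.DataFrame  # rows: terms + Residual + Total
    n_permutations: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    formula: str | Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Adonis-style PERMANOVA with sequential sums of squares.

    Terms are fit in formula order on the Gower-centered inner-product
    matrix; each term's pseudo-F is tested against the residual by free
    permutation of sample labels, with the add-one p-value.  Factors
    with a single level are dropped with a warning.
    """
    design = design.loc[dm.labels]
    terms = expand_formula(formula)
    kept_terms = []
    for t in terms:
        levels_ok = True
        for comp in t.split(":"):
            col = design[comp]
            if not pd.api.types.is_numeric_dtype(col) and col.nunique() < 2:
                levels_ok = False
        if levels_ok:
            kept_terms.append(t)
        else:
            warnings.warn(f"term {t!r} has a single level and was dropped")
    terms = kept_terms
    if not terms:
        raise ValueError("no usable terms in formula")
    n = dm.n
    d2 = dm.values**2
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    gower = -0.5 * centering @ d2 @ centering
    gower = 0.5 * (gower + gower.T)
    total_ss = float(np.trace(gower))

    # orthonormal bases per sequential term (residualized against earlier terms)
    ones = np.ones((n, 1)) / np.sqrt(n)
    basis = ones
    blocks: list[np.ndarray] = []
    dfs: list[int] = []
    for t in terms:
        cols = _term_columns(t, design)
        resid = cols - basis @ (basis.T @ cols)
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        keep = s > 1e-9 * max(1.0, s[0] if s.size else 1.0)
        q = u[:, keep]
        blocks.append(q)
        dfs.append(int(keep.sum()))
        if q.size:
            basis = np.column_stack([basis, q])
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    qall = np.column_stack([b for b in blocks if b.size]) if any(b.size for b in blocks) else np.zeros((n, 0))
    starts = np.cumsum([0] + dfs)

    def term_ss(g: np.ndarray) -> np.ndarray:
        m = g @ qall
        per_col = np.einsum("ij,ij->j", qall, m)
        return np.asarray([per_col[starts[i]: starts[i + 1]].sum() for i in range(len(terms))])

    ss_obs = term_ss(gower)
    ss_res = total_ss - ss_obs.sum()
    f_obs = (ss_obs / np.maximum(dfs, 1)) / (ss_res / df_res)

    rng = np.random.default_rng(derive_seed(seed, "permanova"))
    counts = np.zeros(len(terms))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = gower[np.ix_(perm, perm)]
        ss_p = term_ss(gp)
        res_p = total_ss - ss_p.sum()
        f_p = (ss_p / np.maximum(dfs, 1)) / (res_p / df_res)
        counts += f_p >= f_obs - 1e-12
    pvals = (1.0 + counts) / (1.0 + n_permutations)

    rows = []
    for i, t in enumerate(terms):
        rows.append(
            (t, dfs[i], ss_obs[i], ss_obs[i] / total_ss, f_obs[i], pvals[i])
        )
    rows.append(("Residual", df_res, ss_res, ss_res / total_ss, np.nan, np.nan))
    rows.append(("Total", n - 1, total_ss, 1.0, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "sum_sq", "r2", "pseudo_f", "p_value"]
    ).set_index("term")
    return PermanovaResult(table, n_permutations)


@dataclass
class PermdispResult:
    """Permutation test of multivariate dispersion homogeneity."""

    groups: pd.Series
    distances_to_centroid: pd.Series
    f_statistic: float
    p_value: float
    n_permutations: int


def permdisp(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermdispResult:
    """Distance-based homogeneity of dispersions (betadisper-style).

    Samples are embedded by PCoA keeping negative-eigenvalue axes as
    imaginary coordinates whose squared distances subtract; each
    sample's distance to its group spatial centroid feeds a one-way F
    statistic, tested by permutation of group labels.
    """
    if isinstance(groups, pd.Series):
        groups = groups.loc[dm.labels]
    else:
        groups = pd.Series(list(groups), index=dm.labels)
    sizes = groups.value_counts()
    if (sizes >= 2).sum() < 2 or len(sizes) < 2:
        raise ValueError("PERMDISP needs >= 2 groups with >= 2 members")
    n = dm.n
    d2 = dm.values**2
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    gower = -0.5 * centering @ d2 @ centering
    gower = 0.5 * (gower + gower.T)
    eigval, eigvec = np.linalg.eigh(gower)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = 1e-10 * max(1.0, abs(eigval).max())
    pos = eigval > tol
    neg = eigval < -tol
    xr = eigvec[:, pos] * np.sqrt(eigval[pos])
    xi = eigvec[:, neg] * np.sqrt(-eigval[neg])

    codes, uniq = pd.factorize(groups)

    def dispersions(code_vec: np.ndarray) -> np.ndarray:
        z = np.empty(n)
        for g in range(len(uniq)):
            mask = code_vec == g
            cr = xr[mask].mean(axis=0)
            ci = xi[mask].mean(axis=0) if xi.size else 0.0
            d2r = ((xr[mask] - cr) ** 2).sum(axis=1)
            d2i = ((xi[mask] - ci) ** 2).sum(axis=1) if xi.size else 0.0
            z[mask] = np.sqrt(np.maximum(d2r - d2i, 0.0))
        return z

    def anova_f(z: np.ndarray, code_vec: np.ndarray) -> float:
        grand = z.mean()
        ss_between = 0.0
        ss_within = 0.0
        for g in range(len(uniq)):
            zg = z[code_vec == g]
            ss_between += zg.size * (zg.mean() - grand) ** 2
            ss_within += ((zg - zg.mean()) ** 2).sum()
        df_b = len(uniq) - 1
        df_w = n - len(uniq)
        if ss_within == 0:
            return np.inf
        return (ss_between / df_b) / (ss_within / df_w)

    z_obs = dispersions(codes)
    f_obs = anova_f(z_obs, codes)
    # permute the centroid distances across samples (betadisper convention)
    rng = np.random.default_rng(derive_seed(seed, "permdisp"))
    count = 0
    for _ in range(n_permutations):
        z_p = z_obs[rng.permutation(n)]
        count += anova_f(z_p, codes) >= f_obs - 1e-12
    p = (1.0 + count) / (1.0 + n_permutations)
    return PermdispResult(
        groups=groups,
        distances_to_centroid=pd.Series(z_obs, index=dm.labels),
        f_statistic=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
    )
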