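import numpy as np
import pandas as pd
import pytest

from phylosym.data_model import DistanceMatrix, TraitMatrix, read_newick
from phylosym.signal_traits import (
    blomberg_k,
    expand_formula,
    pagel_lambda,
    pcoa,
    permanova,
    permdisp,
    pgls,
    trait_pca,
)

TRAIT_X = dict(a=1.2, b=0.9, c=-0.5, d=-0.1, e=0.3, f=-1.0, g=-0.7)
TRAIT_Z = dict(a=0.5, b=0.1, c=-0.2, d=0.9, e=-0.4, f=0.3, g=-0.8)


def euclidean_dm(pts, labels):
    pts = np.asarray(pts, dtype=float)
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return DistanceMatrix(d, labels)


class TestPcoa:
    def test_euclidean_distances_recovered(self):
        dm = euclidean_dm([(0, 0), (3, 0), (0, 4)], ["p", "q", "r"])
        res = pcoa(dm)
        rec = np.sqrt(
            ((res.coordinates[:, None] - res.coordinates[None, :]) ** 2).sum(-1)
        )
        np.testing.assert_allclose(rec, dm.values, atol=1e-9)

    def test_identical_objects_share_coordinates(self):
        dm = euclidean_dm([(0, 0), (0, 0), (2, 1)], ["p", "q", "r"])
        res = pcoa(dm)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_non_euclidean_reports_negative_eigenvalues(self):
        # metric but not Euclidean-embeddable: two long pairs among short ones
        values = np.full((4, 4), 1.1)
        np.fill_diagonal(values, 0.0)
        values[0, 1] = values[1, 0] = 2.0
        values[2, 3] = values[3, 2] = 2.0
        res = pcoa(DistanceMatrix(values, list("wxyz")))
        assert res.eigenvalues.min() < -1e-8
        assert (res.proportion_explained > 0).all()

    def test_truncation_warns(self):
        dm = euclidean_dm([(0, 0), (1, 0), (0, 1)], ["p", "q", "r"])
        with pytest.warns(UserWarning, match="truncating"):
            res = pcoa(dm, k=5)
        assert res.coordinates.shape[1] <= 2

    def test_matches_scikit_bio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(7)
        dm = euclidean_dm(rng.normal(size=(8, 3)), [f"s{i}" for i in range(8)])
        ours = pcoa(dm)
        ref = skbio_pcoa(dm.values, number_of_dimensions=0)
        np.testing.assert_allclose(
            np.abs(ours.coordinates[:, :3]),
            np.abs(ref.samples.to_numpy()[:, :3]),
            atol=1e-8,
        )


class TestBlombergK:
    def test_star_tree_k_is_one(self):
        star = read_newick("(a:1,b:1,c:1,d:1,e:1,f:1);")
        rng = np.random.default_rng(0)
        for _ in range(5):
            trait = dict(zip("abcdef", rng.normal(size=6)))
            res = blomberg_k(star, trait, n_permutations=0)
            assert res.estimate == pytest.approx(1.0, abs=1e-10)

    def test_frozen_phytools_value(self, seven_tip_tree):
        res = blomberg_k(seven_tip_tree, TRAIT_X, n_permutations=0)
        assert res.estimate == pytest.approx(1.5600443191, abs=1e-8)

    def test_affine_invariance(self, seven_tip_tree):
        base = blomberg_k(seven_tip_tree, TRAIT_X, n_permutations=0).estimate
        scaled = {k: 3.0 * v - 7.0 for k, v in TRAIT_X.items()}
        assert blomberg_k(seven_tip_tree, scaled, n_permutations=0).estimate == (
            pytest.approx(base, abs=1e-10)
        )

    def test_permutation_p_detects_signal(self, seven_tip_tree):
        res = blomberg_k(seven_tip_tree, TRAIT_X, n_permutations=500, seed=1)
        assert 0 < res.p_value <= 0.2

    def test_zero_variance_rejected(self, seven_tip_tree):
        with pytest.raises(ValueError, match="variance"):
            blomberg_k(seven_tip_tree, {k: 1.0 for k in TRAIT_X}, 10)


class TestPagelLambda:
    def test_frozen_phytools_value(self, seven_tip_tree):
        res = pagel_lambda(seven_tip_tree, TRAIT_X, lambda_max=1.2)
        assert res.estimate == pytest.approx(1.1695892201, abs=1e-4)
        assert res.log_likelihood == pytest.approx(-5.8926126398, abs=1e-6)
        assert res.p_value == pytest.approx(0.0377575152, abs=1e-5)

    def test_estimate_within_bounds(self, seven_tip_tree):
        res = pagel_lambda(seven_tip_tree, TRAIT_X)
        assert 0.0 <= res.estimate <= 1.0

    def test_affine_invariance(self, seven_tip_tree):
        base = pagel_lambda(seven_tip_tree, TRAIT_X).estimate
        scaled = {k: -2.0 * v + 1.0 for k, v in TRAIT_X.items()}
        assert pagel_lambda(seven_tip_tree, scaled).estimate == pytest.approx(
            base, abs=1e-6
        )

    def test_star_tree_unidentifiable(self):
        star = read_newick("(a:1,b:1,c:1,d:1);")
        res = pagel_lambda(star, dict(a=0.1, b=0.5, c=-0.3, d=0.2))
        assert not res.identifiable


class TestPgls:
    def test_frozen_nlme_values(self, seven_tip_tree):
        fit = pgls(
            seven_tip_tree,
            pd.Series(TRAIT_X),
            pd.DataFrame({"z": pd.Series(TRAIT_Z)}),
        )
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), [0.1598051, 0.1022736], atol=1e-6
        )
        np.testing.assert_allclose(
            fit.coefficient_p_values.to_numpy(), [0.7525717, 0.8042158], atol=1e-6
        )
        assert fit.log_likelihood == pytest.approx(-6.1258886629, abs=1e-8)
        assert fit.aic == pytest.approx(-2 * -6.1258886629 + 2 * 3, abs=1e-6)
        assert fit.residual_df == 5

    def test_star_tree_equals_ols(self):
        star = read_newick("(a:1,b:1,c:1,d:1,e:1,f:1,g:1);")
        fit = pgls(star, pd.Series(TRAIT_X), pd.DataFrame({"z": pd.Series(TRAIT_Z)}))
        x = np.array([TRAIT_Z[k] for k in "abcdefg"])
        y = np.array([TRAIT_X[k] for k in "abcdefg"])
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.coefficients["z"] == pytest.approx(slope, abs=1e-9)
        assert fit.coefficients["intercept"] == pytest.approx(intercept, abs=1e-9)

    def test_response_as_predictor_flags_perfect_fit(self, seven_tip_tree):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = pgls(
                seven_tip_tree,
                pd.Series(TRAIT_X),
                pd.DataFrame({"self": pd.Series(TRAIT_X)}),
            )
        assert fit.perfect_fit
        assert fit.coefficients["self"] == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-8)

    def test_singular_design_names_columns(self, seven_tip_tree):
        z = pd.Series(TRAIT_Z)
        with pytest.raises(ValueError, match="z_copy"):
            pgls(
                seven_tip_tree,
                pd.Series(TRAIT_X),
                pd.DataFrame({"z": z, "z_copy": 2.0 * z}),
            )

    def test_interaction_column_added(self, seven_tip_tree):
        w = pd.Series({k: i * 0.31 % 1 for i, k in enumerate(TRAIT_X)})
        fit = pgls(
            seven_tip_tree,
            pd.Series(TRAIT_X),
            pd.DataFrame({"z": pd.Series(TRAIT_Z), "w": w}),
            interaction=True,
        )
        assert "z:w" in fit.coefficients.index


ADONIS_POINTS = np.array(
    [
        [1.370958447146668480, -1.388860701112339280],
        [-0.564698171396088688, -0.278788766817371358],
        [0.363128411337339196, -0.133321336393658035],
        [0.632862604961040409, 0.635950398070074363],
        [0.404268323140999031, -0.284252921416072390],
        [-0.106124516091484031, -2.656455420904775711],
        [1.511521997438938891, -2.440466928575519390],
        [-0.094659038413097557, 1.320113345730192123],
        [2.018423713877041781, -0.306638594078474547],
        [-0.062714099052420993, -1.781308433980000050],
        [1.304869654223485220, -0.171917355759621360],
        [2.286645392701106783, 1.214674699172598737],
    ]
)


class TestPermanova:
    def _design(self):
        return pd.DataFrame(
            {
                "grp": ["u"] * 6 + ["v"] * 6,
                "cov1": np.linspace(0.1, 1.2, 12),
            },
            index=[f"s{i}" for i in range(12)],
        )

    def test_frozen_vegan_adonis(self):
        dm = euclidean_dm(ADONIS_POINTS, [f"s{i}" for i in range(12)])
        res = permanova(dm, self._design(), "grp + cov1", n_permutations=9, seed=0)
        t = res.table
        assert t.loc["grp", "sum_sq"] == pytest.approx(2.284985387202, abs=1e-9)
        assert t.loc["cov1", "sum_sq"] == pytest.approx(0.347209092389, abs=1e-9)
        assert t.loc["Residual", "sum_sq"] == pytest.approx(25.488947720556, abs=1e-9)
        assert t.loc["Total", "sum_sq"] == pytest.approx(28.121142200147, abs=1e-9)
        assert t.loc["grp", "pseudo_f"] == pytest.approx(0.806815122785, abs=1e-9)
        assert t.loc["cov1", "pseudo_f"] == pytest.approx(0.122597522101, abs=1e-9)

    def test_single_factor_matches_group_sum_oracle(self):
        # classical pseudo-F from group sums of squared distances
        rng = np.random.default_rng(5)
        for _ in range(10):
            n_per = int(rng.integers(3, 7))
            labels = [f"s{i}" for i in range(2 * n_per)]
            pts = rng.normal(size=(2 * n_per, 3))
            pts[n_per:] += rng.normal(scale=0.5, size=3)
            dm = euclidean_dm(pts, labels)
            design = pd.DataFrame(
                {"grp": ["u"] * n_per + ["v"] * n_per}, index=labels
            )
            res = permanova(dm, design, "grp", n_permutations=9, seed=0)
            d2 = dm.values**2
            n = 2 * n_per
            ss_total = d2[np.triu_indices(n, 1)].sum() / n
            ss_within = 0.0
            for sl in (slice(0, n_per), slice(n_per, n)):
                block = d2[sl, sl]
                ss_within += block[np.triu_indices(n_per, 1)].sum() / n_per
            f_oracle = (ss_total - ss_within) / (ss_within / (n - 2))
            assert res.table.loc["grp", "pseudo_f"] == pytest.approx(
                f_oracle, abs=1e-10
            )

    def test_r2_decomposition_sums_to_one(self):
        dm = euclidean_dm(ADONIS_POINTS, [f"s{i}" for i in range(12)])
        res = permanova(
            dm, self._design(), "grp*cov1", n_permutations=9, seed=0
        )
        r2 = res.table["r2"]
        assert r2.drop("Total").sum() == pytest.approx(1.0, abs=1e-9)

    def test_separated_clouds_reach_minimal_p(self):
        rng = np.random.default_rng(11)
        pts = np.vstack([rng.normal(size=(8, 2)), rng.normal(size=(8, 2)) + 12.0])
        labels = [f"s{i}" for i in range(16)]
        dm = euclidean_dm(pts, labels)
        design = pd.DataFrame({"grp": ["u"] * 8 + ["v"] * 8}, index=labels)
        res = permanova(dm, design, "grp", n_permutations=999, seed=0)
        assert res.table.loc["grp", "p_value"] == pytest.approx(0.001)

    def test_single_level_term_dropped(self):
        dm = euclidean_dm(ADONIS_POINTS[:6], [f"s{i}" for i in range(6)])
        design = pd.DataFrame(
            {"grp": ["u"] * 6, "cov1": np.arange(6.0)}, index=[f"s{i}" for i in range(6)]
        )
        with pytest.warns(UserWarning, match="single level"):
            res = permanova(dm, design, "grp + cov1", n_permutations=9, seed=0)
        assert "grp" not in res.table.index

    def test_formula_expansion(self):
        assert expand_formula("A*B + C/D/E") == ["A", "B", "A:B", "C", "C:D", "C:D:E"]
        assert expand_formula(["A", "B:C"]) == ["A", "B:C"]


class TestPermdisp:
    def test_distances_nonnegative_and_detects_spread(self):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [rng.normal(scale=1.0, size=(15, 2)), rng.normal(scale=4.0, size=(15, 2))]
        )
        labels = [f"s{i}" for i in range(30)]
        dm = euclidean_dm(pts, labels)
        groups = pd.Series(["u"] * 15 + ["v"] * 15, index=labels)
        res = permdisp(dm, groups, n_permutations=499, seed=0)
        assert (res.distances_to_centroid >= 0).all()
        assert res.p_value <= 0.05

    def test_identical_groups_not_flagged(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(24, 2))
        labels = [f"s{i}" for i in range(24)]
        dm = euclidean_dm(pts, labels)
        groups = pd.Series(["u", "v"] * 12, index=labels)
        res = permdisp(dm, groups, n_permutations=199, seed=0)
        assert res.p_value > 0.05

    def test_singleton_groups_rejected(self):
        dm = euclidean_dm(ADONIS_POINTS[:4], list("wxyz"))
        with pytest.raises(ValueError, match="2 groups"):
            permdisp(dm, ["a", "b", "c", "d"], 9, 0)


class TestTraitPca:
    def _traits(self):
        rng = np.random.default_rng(6)
        vals = rng.random(size=(10, 4))
        return TraitMatrix(vals, [f"sp{i}" for i in range(10)], list("wxyz"))

    def test_proportions_sum_to_one(self):
        res = trait_pca(self._traits())
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_correlated_traits_collapse_to_pc1(self):
        base = np.linspace(0, 1, 8)
        vals = np.column_stack([base, 2 * base + 5])
        tm = TraitMatrix(vals, [f"sp{i}" for i in range(8)], ["t1", "t2"])
        res = trait_pca(tm, scale=True)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_zero_variance_scale_rejected(self):
        vals = np.column_stack([np.ones(5), np.arange(5.0)])
        tm = TraitMatrix(vals, [f"sp{i}" for i in range(5)], ["flat", "ramp"])
        with pytest.raises(ValueError, match="flat"):
            trait_pca(tm, scale=True)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        tm = self._traits()
        res = trait_pca(tm)
        ref = PCA().fit(tm.values)
        np.testing.assert_allclose(
            np.abs(res.scores), np.abs(ref.transform(tm.values)), atol=1e-9
        )
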