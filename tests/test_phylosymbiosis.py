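import itertools

import dendropy
import numpy as np
import pytest

from phylosym.data_model import DistanceMatrix, newick_string, read_newick
from phylosym.phylosymbiosis import (
    _random_topology_splits,
    _splits,
    mantel,
    patristic_distances,
    random_topology,
    rf_randomization_test,
    robinson_foulds,
    upgma,
)

from .conftest import random_tree


def cophenetic_from_tree(tree):
    return patristic_distances(tree)


class TestUpgma:
    def test_two_labels(self):
        dm = DistanceMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"])
        tree = upgma(dm)
        d = patristic_distances(tree)
        assert d[("a", "b")] == pytest.approx(3.0)
        # both tips at height d/2
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(1.5)

    def test_three_point_hand_execution(self):
        values = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]])
        dm = DistanceMatrix(values, ["a", "b", "c"])
        tree = upgma(dm)
        d = patristic_distances(tree)
        assert d[("a", "b")] == pytest.approx(2.0)
        assert d[("a", "c")] == pytest.approx(8.0)
        # (a,b) merge at height 1, joined with c at height 4
        heights = sorted(
            leaf.edge.length for leaf in tree.leaf_node_iter()
        )
        assert heights == pytest.approx([1.0, 1.0, 4.0])

    def test_ultrametric_input_reproduced_exactly(self):
        rng = np.random.default_rng(2)
        # a random ultrametric tree's patristic matrix is recovered by UPGMA
        from phylosym.synthetic import simulate_yule_tree

        source = simulate_yule_tree(9, seed=17)
        dm = patristic_distances(source)
        tree = upgma(dm)
        out = patristic_distances(tree).reorder(dm.labels)
        np.testing.assert_allclose(out.values, dm.values, atol=1e-9)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            pts = rng.normal(size=(n, 3))
            cond = squareform(
                np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)), checks=False
            )
            labels = [f"L{i}" for i in range(n)]
            dm = DistanceMatrix(
                np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)) * (1 - np.eye(n)),
                labels,
            )
            ours = patristic_distances(upgma(dm)).reorder(labels).values
            ref = squareform(cophenet(linkage(cond, method="average")))
            np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_nan_rejected(self):
        values = np.zeros((2, 2))
        dm = DistanceMatrix(values, ["a", "b"])
        dm.values[0, 1] = dm.values[1, 0] = np.nan
        with pytest.raises(ValueError):
            upgma(dm)


def all_five_tip_topologies():
    """The 15 distinct unrooted binary topologies on 5 tips."""
    tips = list("abcde")
    seen = {}
    seed = 0
    while len(seen) < 15 and seed < 3000:
        tree = random_topology(tips, seed)
        key = frozenset(_splits(tree)[0])
        seen.setdefault(key, tree)
        seed += 1
    assert len(seen) == 15
    return list(seen.values())


class TestRobinsonFoulds:
    def test_identical_topologies(self, seven_tip_tree):
        assert robinson_foulds(seven_tip_tree, seven_tip_tree) == 0.0

    def test_conflicting_quartets(self):
        t1 = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = read_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert robinson_foulds(t1, t2) == 1.0
        assert robinson_foulds(t1, t2, normalized=False) == 2.0

    def test_star_versus_resolved(self):
        star = read_newick("(a:1,b:1,c:1,d:1,e:1);")
        resolved = read_newick("(((a:1,b:1):1,c:1):1,(d:1,e:1):1);")
        # star has 0 non-trivial splits, resolved has 2 -> 2/2
        assert robinson_foulds(star, resolved) == 1.0

    def test_frozen_phangorn_value(self):
        t1 = read_newick("(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):1);")
        t2 = read_newick("(((a:1,c:1):1,(b:1,d:1):1):1,(e:1,f:1):1);")
        # normalized RF from phangorn RF.dist on the unrooted pair
        assert robinson_foulds(t1, t2) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_mismatched_tips_listed(self):
        t1 = read_newick("((a:1,b:1):1,c:1);")
        t2 = read_newick("((a:1,b:1):1,d:1);")
        with pytest.raises(ValueError, match="c.*d|d.*c"):
            robinson_foulds(t1, t2)

    def test_is_a_metric_on_five_tip_topologies(self):
        trees = all_five_tip_topologies()
        n = len(trees)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d[i, j] = robinson_foulds(trees[i], trees[j], normalized=False)
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d[~np.eye(n, dtype=bool)] > 0)
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_matches_dendropy_symmetric_difference(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(4, 9))
            t1 = random_tree(n, rng)
            t2 = random_tree(n, rng)
            ours = robinson_foulds(t1, t2, normalized=False)
            ns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=newick_string(t1), schema="newick", taxon_namespace=ns
            )
            d2 = dendropy.Tree.get(
                data=newick_string(t2), schema="newick", taxon_namespace=ns
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            ref = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert ours == ref


class TestRandomTopology:
    def test_tip_set_and_determinism(self):
        labels = [f"t{i}" for i in range(15)]
        t1 = random_topology(labels, seed=5)
        assert sorted(l.taxon.label for l in t1.leaf_node_iter()) == sorted(labels)
        t2 = random_topology(labels, seed=5)
        assert robinson_foulds(t1, t2) == 0.0
        t3 = random_topology(labels, seed=6)
        assert robinson_foulds(t1, t3) > 0.0

    def test_split_shortcut_matches_tree(self):
        labels = [f"t{i}" for i in range(12)]
        for seed in range(25):
            fast = _random_topology_splits(labels, seed)
            slow = _splits(random_topology(labels, seed))[0]
            assert fast == slow

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            random_topology(["a", "b"], seed=0)

    def test_random_pairs_share_almost_no_splits(self):
        # mean normalized RF between random 15-tip trees is close to 1
        labels = [f"t{i}" for i in range(15)]
        fixed = _splits(random_topology(labels, seed=0))[0]
        vals = []
        for seed in range(1, 1001):
            other = _random_topology_splits(labels, seed)
            vals.append(len(fixed ^ other) / (len(fixed) + len(other)))
        assert np.mean(vals) > 0.95


class TestRfRandomizationTest:
    def test_identical_trees_minimal_p(self):
        host = random_topology([f"t{i}" for i in range(15)], seed=3)
        res = rf_randomization_test(host, host, n_null=500, seed=1)
        assert res.observed_rf == 0.0
        assert res.p_value == pytest.approx(1.0 / 501.0)
        assert len(res.null_rf) == 500

    def test_zero_null_rejected(self):
        host = random_topology(list("abcde"), seed=0)
        with pytest.raises(ValueError):
            rf_randomization_test(host, host, n_null=0, seed=0)

    def test_null_p_roughly_uniform(self):
        # a random dendrogram should not look congruent
        labels = [f"t{i}" for i in range(12)]
        host = random_topology(labels, seed=100)
        pvals = [
            rf_randomization_test(
                host, random_topology(labels, seed=200 + k), n_null=99, seed=k
            ).p_value
            for k in range(60)
        ]
        assert np.mean(np.asarray(pvals) <= 0.5) < 0.9
        assert min(pvals) > 0.001


class TestPatristic:
    def test_hand_worked(self):
        cherry = read_newick("(a:1,b:2);")
        assert patristic_distances(cherry)[("a", "b")] == pytest.approx(3.0)
        tree = read_newick("((a:1,b:1):2,c:4);")
        d = patristic_distances(tree)
        assert d[("a", "c")] == pytest.approx(7.0)
        assert d[("a", "b")] == pytest.approx(2.0)

    def test_ultrametric_is_twice_mrca_height(self, seven_tip_tree):
        d = patristic_distances(seven_tip_tree)
        assert d[("f", "g")] == pytest.approx(0.6)  # MRCA at depth 0.7 from root
        assert d[("a", "g")] == pytest.approx(2.0)

    def test_matches_dendropy(self):
        rng = np.random.default_rng(44)
        tree = random_tree(9, rng)
        ours = patristic_distances(tree)
        pdm = tree.phylogenetic_distance_matrix()
        for t1 in tree.taxon_namespace:
            for t2 in tree.taxon_namespace:
                assert ours[(t1.label, t2.label)] == pytest.approx(
                    pdm.patristic_distance(t1, t2), abs=1e-10
                )


class TestMantel:
    def _euclidean(self, pts, labels):
        pts = np.asarray(pts, dtype=float)
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return DistanceMatrix(d, labels)

    def test_identity_r_one(self):
        rng = np.random.default_rng(1)
        dm = self._euclidean(rng.normal(size=(6, 2)), list("abcdef"))
        res = mantel(dm, dm, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        dm = self._euclidean(rng.normal(size=(7, 2)), list("abcdefg"))
        dm2 = DistanceMatrix(3.0 * dm.values + 0.5 * (1 - np.eye(7)), dm.labels)
        res = mantel(dm, dm2, n_permutations=9, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_frozen_vegan_value(self):
        pts1 = [(0, 0), (1, 0), (0, 2), (3, 1), (2, 2)]
        pts2 = [(0, 1), (1, 1), (1, 3), (2, 0), (3, 3)]
        labels = list("abcde")
        res = mantel(
            self._euclidean(pts1, labels),
            self._euclidean(pts2, labels),
            n_permutations=9,
            seed=0,
        )
        assert res.r == pytest.approx(0.4844102094, abs=1e-9)

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        labels = list("abcdefgh")
        dm1 = self._euclidean(rng.normal(size=(8, 2)), labels)
        dm2 = self._euclidean(rng.normal(size=(8, 2)), labels)
        r0 = mantel(dm1, dm2, n_permutations=1, seed=0).r
        shuffled = list(np.random.default_rng(0).permutation(labels))
        r1 = mantel(dm1.reorder(shuffled), dm2.reorder(shuffled), 1, 0).r
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_errors(self):
        dm1 = self._euclidean([(0, 0), (1, 0), (0, 1), (1, 1)], list("abcd"))
        dm2 = self._euclidean([(0, 0), (1, 0), (0, 1), (1, 1)], list("abcx"))
        with pytest.raises(ValueError, match="label"):
            mantel(dm1, dm2, 9, 0)
        small = self._euclidean([(0, 0), (1, 0), (0, 1)], list("abc"))
        with pytest.raises(ValueError, match="at least 4"):
            mantel(small, small, 9, 0)


class TestPipelineRecovery:
    def test_strong_phylosymbiosis_is_detected(self):
        """With host-structured effects dominating noise, both the RF
        randomization test and the Mantel test should detect
        phylosymbiosis in nearly every simulated dataset."""
        from phylosym import SimulationConfig, simulate_community
        from phylosym.data_model import rarefy, remove_control_asvs
        from phylosym.diversity import bray_curtis

        n_sims = 40
        rf_hits = 0
        mantel_pos = 0
        for k in range(n_sims):
            cfg = SimulationConfig(
                samples_per_species=(1, 1),
                n_asvs=120,
                read_depth=(1500, 2500),
                sigma_phy=1.6,
                beta_diet=0.0,
                sigma_noise=0.05,
                sigma_individual=0.05,
                n_controls=0,
                n_contaminants=0,
                seed=1000 + k,
            )
            data = simulate_community(cfg)
            table = rarefy(data.table, 1000, seed=k).drop_empty_asvs()
            species = sorted({m.host_species for m in data.meta})
            renamed = table.select_samples(table.sample_ids)
            renamed.sample_ids = [s.rsplit("_s", 1)[0] for s in table.sample_ids]
            dm = bray_curtis(renamed)
            host_d = patristic_distances(data.host_tree)
            rf = rf_randomization_test(
                data.host_tree, upgma(dm), n_null=199, seed=k
            )
            man = mantel(host_d.reorder(dm.labels), dm, n_permutations=199, seed=k)
            rf_hits += rf.p_value < 0.05
            mantel_pos += (man.r > 0) and (man.p_value < 0.05)
        assert rf_hits >= 0.9 * n_sims
        assert mantel_pos >= 0.9 * n_sims
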