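"""Diversity measures: hand-worked values, kernel invariants, oracle routes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from coresweep import diversity as dv
from coresweep import synth
from coresweep.errors import ParameterError, UndefinedValueError
from coresweep.io import FeatureTable
from coresweep.tree import Phylogeny

from . import conftest as oracle
from .conftest import random_table


class TestEdgeMasses:
    def test_single_lineage_path(self, four_leaf_tree):
        mass = dv.edge_masses({"A": 1.0}, four_leaf_tree)
        nonzero = {four_leaf_tree.labels[v] for v in np.flatnonzero(mass > 0)
                   if four_leaf_tree.is_leaf[v]}
        assert nonzero == {"A"}
        assert np.sort(mass[mass > 0]).tolist() == [1.0, 1.0, 1.0]  # A, (AB), root

    def test_cherry_masses(self, four_leaf_tree):
        mass = dv.edge_masses({"A": 0.5, "B": 0.5}, four_leaf_tree)
        vals = sorted(mass[mass > 0].tolist())
        assert vals == [0.5, 0.5, 1.0, 1.0]  # A, B, (AB), root

    def test_uniform_four_leaves(self, four_leaf_tree, abcd):
        mass = dv.edge_masses({t: 0.25 for t in abcd}, four_leaf_tree)
        assert sorted(mass.tolist()) == [0.25] * 4 + [0.5, 0.5, 1.0]

    def test_root_mass_conservation_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_taxa = int(rng.integers(3, 16))
            tree = synth.generate_tree(n_taxa, seed=int(rng.integers(2**31)))
            table = random_table(rng, 4, n_taxa)
            mass = dv.edge_mass_matrix(
                table.relative_abundances(), tree.leaf_labels, tree
            )
            assert np.allclose(mass[tree.root], 1.0, atol=1e-12)
            child_sum = sum(mass[c] for c in tree.children(tree.root))
            assert np.allclose(child_sum, 1.0, atol=1e-12)


class TestAlphaHandWorked:
    def test_observed_richness(self):
        assert dv.observed_richness(np.array([3, 0, 1, 2])) == 3
        assert dv.observed_richness(np.zeros(4)) == 0

    def test_shannon_values(self):
        assert dv.shannon(np.array([1, 1])) == pytest.approx(np.log(2))
        assert dv.shannon(np.array([7])) == 0.0
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert dv.shannon(np.array([2, 1, 1])) == pytest.approx(expected)

    def test_shannon_empty_sample_raises(self):
        with pytest.raises(UndefinedValueError):
            dv.shannon(np.zeros(3))

    def test_faith_pd_enumerated_branches(self, four_leaf_tree, abcd):
        assert dv.faith_pd(np.array([1, 1, 0, 0]), abcd, four_leaf_tree) == 3.0
        assert dv.faith_pd(np.array([1, 1, 1, 1]), abcd, four_leaf_tree) == 6.0
        assert dv.faith_pd(np.array([5, 0, 0, 0]), abcd, four_leaf_tree) == 2.0

    @pytest.mark.parametrize("theta", [0.0, 0.25, 0.5, 1.0])
    def test_bwpd_single_taxon_is_zero(self, four_leaf_tree, abcd, theta):
        assert dv.bwpd(np.array([9, 0, 0, 0]), abcd, four_leaf_tree, theta) == 0.0

    @pytest.mark.parametrize("theta", [0.0, 0.5, 1.0])
    def test_bwpd_balanced_cherry(self, four_leaf_tree, abcd, theta):
        # A and B at 0.5 each: their two unit edges get weight (2*0.5)^theta = 1
        assert dv.bwpd(np.array([1, 1, 0, 0]), abcd, four_leaf_tree, theta) == pytest.approx(2.0)

    def test_bwpd_uniform_theta_one(self, four_leaf_tree, abcd):
        assert dv.bwpd(np.array([1, 1, 1, 1]), abcd, four_leaf_tree, 1.0) == pytest.approx(4.0)

    def test_bwpd_theta_out_of_range(self, four_leaf_tree, abcd):
        with pytest.raises(ParameterError):
            dv.bwpd(np.array([1, 1, 0, 0]), abcd, four_leaf_tree, 1.5)


class TestBetaHandWorked:
    def test_jaccard(self):
        assert dv.jaccard(np.array([1, 1, 1, 0]), np.array([0, 1, 1, 1])) == 0.5
        assert dv.jaccard(np.array([1, 0]), np.array([0, 1])) == 1.0
        assert dv.jaccard(np.array([2, 3]), np.array([5, 1])) == 0.0

    def test_morisita_disjoint_and_identical(self):
        assert dv.morisita(np.array([5, 0]), np.array([0, 5])) == 1.0
        assert dv.morisita(np.array([10, 10]), np.array([10, 10])) == 0.0
        raw = dv.morisita(np.array([10, 10]), np.array([10, 10]), clamp=False)
        assert raw == pytest.approx(1 - 380 / 360)

    def test_morisita_matches_independent_transcription(self):
        x, y = np.array([10, 0]), np.array([9, 1])
        assert dv.morisita(x, y) == pytest.approx(oracle.naive_morisita(x, y), abs=1e-12)

    def test_morisita_rejects_non_integers_and_tiny_totals(self):
        with pytest.raises(ParameterError):
            dv.morisita(np.array([1.5, 1.0]), np.array([1, 1]))
        with pytest.raises(UndefinedValueError):
            dv.morisita(np.array([1, 0]), np.array([1, 1]))

    def test_unweighted_unifrac_enumerated(self, four_leaf_tree, abcd):
        a, b = np.array([1, 0, 0, 0]), np.array([0, 1, 0, 0])
        assert dv.unweighted_unifrac(a, b, abcd, four_leaf_tree) == pytest.approx(2 / 3)
        ab, cd = np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])
        assert dv.unweighted_unifrac(ab, cd, abcd, four_leaf_tree) == 1.0
        assert dv.unweighted_unifrac(ab, ab, abcd, four_leaf_tree) == 0.0

    def test_weighted_unifrac_enumerated(self, four_leaf_tree, abcd):
        a, b = np.array([3, 0, 0, 0]), np.array([0, 7, 0, 0])
        assert dv.weighted_unifrac(a, b, abcd, four_leaf_tree, normalized=False) == pytest.approx(2.0)
        assert dv.weighted_unifrac(a, b, abcd, four_leaf_tree) == pytest.approx(0.5)
        assert dv.weighted_unifrac(a, a, abcd, four_leaf_tree) == 0.0

    def test_bray_curtis(self):
        assert dv.bray_curtis(np.array([2, 2]), np.array([2, 2])) == 0.0
        assert dv.bray_curtis(np.array([2, 0]), np.array([0, 3])) == 1.0
        assert dv.bray_curtis(np.array([2, 2]), np.array([2, 0])) == pytest.approx(1 / 3)


class TestStarTreeDegeneracy:
    """On a unit star tree each taxon is one unit edge, so phylogeny adds nothing."""

    def setup_method(self):
        self.ids = [f"t{i}" for i in range(6)]
        self.tree = Phylogeny.from_newick(
            "(" + ",".join(f"{t}:1" for t in self.ids) + "):0;"
        )

    def test_faith_equals_richness(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            row = rng.integers(0, 4, size=6)
            if row.sum() == 0:
                continue
            assert dv.faith_pd(row, self.ids, self.tree) == dv.observed_richness(row)

    def test_unweighted_unifrac_equals_jaccard(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            x, y = rng.integers(0, 3, size=6), rng.integers(0, 3, size=6)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert dv.unweighted_unifrac(x, y, self.ids, self.tree) == pytest.approx(
                dv.jaccard(x, y)
            )


class TestScikitBioCrossCheck:
    """Independent library route for the phylogenetic metrics."""

    def _skbio_tree(self, tree):
        import io as _io

        from skbio import TreeNode

        return TreeNode.read(_io.StringIO(tree.to_newick()))

    def test_faith_and_unifracs_match_skbio(self):
        from skbio.diversity.alpha import faith_pd as sk_faith
        from skbio.diversity.beta import unweighted_unifrac as sk_uu
        from skbio.diversity.beta import weighted_unifrac as sk_wu

        rng = np.random.default_rng(11)
        for _ in range(5):
            n = int(rng.integers(4, 12))
            tree = synth.generate_tree(n, seed=int(rng.integers(2**31)))
            sk_tree = self._skbio_tree(tree)
            ids = tree.leaf_labels
            table = random_table(rng, 2, n)
            x, y = table.counts
            assert dv.faith_pd(x, ids, tree) == pytest.approx(
                sk_faith(x, ids, sk_tree), abs=1e-9
            )
            assert dv.unweighted_unifrac(x, y, ids, tree) == pytest.approx(
                sk_uu(x, y, taxa=ids, tree=sk_tree), abs=1e-9
            )
            assert dv.weighted_unifrac(x, y, ids, tree) == pytest.approx(
                sk_wu(x, y, taxa=ids, tree=sk_tree, normalized=True), abs=1e-9
            )


class TestPairwiseMatrix:
    def test_identical_samples_zero_matrix(self, four_leaf_tree, abcd):
        table = FeatureTable(["a", "b", "c"], abcd, np.tile([2, 1, 0, 3], (3, 1)))
        for metric in dv.BETA_METRICS:
            mat = dv.pairwise_matrix(table, tree=four_leaf_tree, metric=metric)
            assert np.allclose(mat.data, 0.0, atol=1e-12)

    def test_entries_match_scalar_ops(self, four_leaf_tree, abcd):
        rng = np.random.default_rng(3)
        table = random_table(rng, 5, 4)
        table = FeatureTable(table.sample_ids, abcd, table.counts)
        scalar = {
            "jaccard": lambda x, y: dv.jaccard(x, y),
            "morisita": lambda x, y: dv.morisita(x, y),
            "bray-curtis": lambda x, y: dv.bray_curtis(x, y),
            "unweighted-unifrac": lambda x, y: dv.unweighted_unifrac(x, y, abcd, four_leaf_tree),
            "weighted-unifrac": lambda x, y: dv.weighted_unifrac(x, y, abcd, four_leaf_tree),
        }
        for metric, fn in scalar.items():
            mat = dv.pairwise_matrix(table, tree=four_leaf_tree, metric=metric)
            assert np.allclose(mat.data, mat.data.T)
            for i in range(5):
                for j in range(i + 1, 5):
                    assert mat.data[i, j] == pytest.approx(
                        fn(table.counts[i], table.counts[j]), abs=1e-12
                    )

    def test_bounded_metrics_stay_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n_taxa = int(rng.integers(4, 12))
            tree = synth.generate_tree(n_taxa, seed=int(rng.integers(2**31)))
            table = random_table(rng, 6, n_taxa)
            table = FeatureTable(table.sample_ids, tree.leaf_labels, table.counts)
            for metric in dv.BETA_METRICS:
                mat = dv.pairwise_matrix(table, tree=tree, metric=metric)
                assert np.all(mat.data >= 0) and np.all(mat.data <= 1 + 1e-12)

    def test_zero_total_samples_excluded(self, four_leaf_tree, abcd, caplog):
        counts = np.array([[1, 1, 0, 0], [0, 0, 0, 0], [0, 1, 1, 0]])
        table = FeatureTable(["a", "b", "c"], abcd, counts)
        with caplog.at_level("WARNING"):
            mat = dv.pairwise_matrix(table, metric="jaccard")
        assert mat.sample_ids == ["a", "c"]
        assert "excluding" in caplog.text

    def test_unknown_metric(self, four_leaf_tree):
        table = FeatureTable(["a", "b"], ["A", "B"], np.ones((2, 2), dtype=int))
        with pytest.raises(ParameterError, match="unknown metric"):
            dv.pairwise_matrix(table, metric="euclidean")


class TestMeanDissimilarity:
    def test_two_and_three_samples(self):
        m = dv.DissimilarityMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        assert dv.mean_dissimilarity_per_sample(m).tolist() == [0.4, 0.4]
        m3 = dv.DissimilarityMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.2, 0.6], [0.2, 0, 0.4], [0.6, 0.4, 0]]),
        )
        assert dv.mean_dissimilarity_per_sample(m3)["a"] == pytest.approx(0.4)

    def test_single_sample_undefined(self):
        m = dv.DissimilarityMatrix(["a"], np.zeros((1, 1)))
        with pytest.raises(UndefinedValueError):
            dv.mean_dissimilarity_per_sample(m)


class TestMetricBoundsProperty:
    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=12),
        st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=12),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_nonphylogenetic_beta_in_unit_interval(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        if x.sum() < 2 or y.sum() < 2:
            return
        assert 0.0 <= dv.jaccard(x, y) <= 1.0
        assert 0.0 <= dv.bray_curtis(x, y) <= 1.0
        if (x * (x - 1)).sum() + (y * (y - 1)).sum() > 0:
            assert 0.0 <= dv.morisita(x, y) <= 1.0


class TestBrayCurtisJaccardAssociation:
    def test_association_along_compositional_gradient(self):
        """Where samples differ in composition, Bray-Curtis and Jaccard rank
        pairs concordantly (the redundancy that motivates using Morisita
        instead).  A compositional gradient is induced by pooling two
        metacommunities; exchangeable same-metacommunity tables carry no
        gradient for either metric to track."""
        import pandas as pd

        d1 = synth.generate_table(synth.SynthParams(
            label="a", n_taxa=300, n_samples=15, sigma=1.8, depth=2000, seed=5))
        d2 = synth.generate_table(synth.SynthParams(
            label="b", n_taxa=300, n_samples=15, sigma=1.8, depth=2000, seed=99))
        merged = pd.concat([d1.table.to_frame(), d2.table.to_frame()]).fillna(0)
        table = FeatureTable(
            list(merged.index), list(merged.columns), merged.to_numpy().astype(int)
        )
        bc = dv.pairwise_matrix(table, metric="bray-curtis").condensed()
        jc = dv.pairwise_matrix(table, metric="jaccard").condensed()
        assert spearmanr(bc, jc).statistic > 0.6
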