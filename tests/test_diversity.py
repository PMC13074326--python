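"""Distances, UPGMA/NJ trees and PCA."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj
from sklearn.metrics import adjusted_rand_score

from indelmark.diversity import (
    cut_ultrametric,
    genetic_distance,
    neighbor_joining,
    pca,
    tip_distances,
    to_newick,
    upgma,
)


def _square(values, labels):
    return pd.DataFrame(np.asarray(values, dtype=float), index=list(labels),
                        columns=list(labels))


class TestDistance:
    def test_identical_and_fully_different_rows(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3], [2, 1, 1]],
                         index=["a", "b", "c"], columns=["x", "y", "z"])
        d = genetic_distance(m)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0

    def test_pairwise_deletion_of_missing(self):
        m = pd.DataFrame([[1, 2, 3, 0], [1, 2, 1, 2]], index=["a", "b"],
                         columns=list("wxyz"))
        assert genetic_distance(m).loc["a", "b"] == pytest.approx(1 / 3)

    def test_no_comparable_markers_is_flagged_undefined(self):
        m = pd.DataFrame([[1, 0], [0, 2]], index=["a", "b"], columns=["x", "y"])
        assert np.isnan(genetic_distance(m).loc["a", "b"])

    def test_semimetric_properties(self, panel_population):
        d = genetic_distance(panel_population.matrix)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert (arr >= 0).all() and (arr <= 1).all()


class TestUpgma:
    def test_three_taxon_hand_agglomeration(self):
        d = _square([[0, 2, 4], [2, 0, 4], [4, 4, 0]], "ABC")
        assert to_newick(upgma(d)) == "(C:2.0,(A:1.0,B:1.0):1.0);"

    def test_two_taxa(self):
        d = _square([[0, 2], [2, 0]], "AB")
        assert to_newick(upgma(d)) == "(A:1.0,B:1.0);"

    def test_output_is_ultrametric_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 7
            x = rng.uniform(0.1, 1.0, size=(n, 12))
            d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
            tree = upgma(_square(d, [f"t{i}" for i in range(n)]))
            depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
            assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_reproduces_cophenetic_matrix_of_ultrametric_input(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(6, 9))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(6)]
        coph = tip_distances(upgma(_square(d, labels))).loc[labels, labels]
        again = tip_distances(upgma(coph)).loc[labels, labels]
        assert np.allclose(coph.to_numpy(), again.to_numpy(), atol=1e-9)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(0.2, 1.0, size=(8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = upgma(_square(d, [f"t{i}" for i in range(8)]))

        def height(node):
            h, cur = 0.0, node
            while not cur.is_tip():
                cur = cur.children[0]
                h += cur.length
            return h

        for node in tree.non_tips(include_self=True):
            for child in node.children:
                if not child.is_tip():
                    assert height(node) >= height(child) - 1e-12

    def test_recovers_planted_groups(self):
        from indelmark import SimPopulationConfig, simulate_population

        pop = simulate_population(SimPopulationConfig(
            n_accessions=40, K_true=2, fst=0.5, n_markers=100, seed=17,
            third_allele_rate=0.0,
        ))
        tree = upgma(genetic_distance(pop.matrix))
        clusters = cut_ultrametric(tree, 2)
        labels = [clusters[a] for a in pop.matrix.index]
        assert adjusted_rand_score(pop.memberships, labels) >= 0.9


class TestNeighborJoining:
    additive = _square(
        [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], "ABCD"
    )  # tree ((A:1,B:2):1,(C:3,D:1))

    def test_round_trips_additive_matrix(self):
        tree = neighbor_joining(self.additive)
        got = tip_distances(tree).loc[list("ABCD"), list("ABCD")]
        assert np.allclose(got.to_numpy(), self.additive.to_numpy(), atol=1e-9)
        # the (A,B) cherry is recovered with its branch lengths
        a = next(t for t in tree.tips() if t.name == "A")
        b = next(t for t in tree.tips() if t.name == "B")
        assert a.parent is b.parent
        assert (a.length, b.length) == (1.0, 2.0)

    def test_star_three_taxa(self):
        d = _square([[0, 2, 2], [2, 0, 2], [2, 2, 0]], "ABC")
        tree = neighbor_joining(d)
        assert {t.length for t in tree.tips()} == {1.0}

    def test_matches_skbio_on_random_additive_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(3):
            # build an additive matrix from a random tree via random splits
            n = 6
            x = rng.uniform(0.2, 1.0, size=(n, 4))
            d = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
            labels = [f"t{i}" for i in range(n)]
            mine = neighbor_joining(_square(d, labels))
            ref = skbio_nj(DistanceMatrix(d, labels))
            got = tip_distances(mine).loc[labels, labels].to_numpy()
            want = ref.tip_tip_distances(labels).data
            assert np.allclose(got, want, atol=1e-6)

    def test_agrees_with_upgma_on_ultrametric_input(self):
        rng = np.random.default_rng(29)
        x = rng.uniform(size=(7, 9))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(7)]
        ultra = tip_distances(upgma(_square(d, labels))).loc[labels, labels]
        nj_tree = neighbor_joining(ultra)
        up_tree = upgma(ultra)
        # same path-length metric implies same topology
        assert np.allclose(
            tip_distances(nj_tree).loc[labels, labels].to_numpy(),
            ultra.to_numpy(), atol=1e-9,
        )
        # unrooted comparison: NJ leaves a trifurcating root where UPGMA roots
        assert up_tree.compare_rfd(nj_tree, rooted=False) == 0

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(_square([[0, 1], [1, 0]], "AB"))


class TestPca:
    def test_two_duplicated_clusters_load_entirely_on_pc1(self):
        m = pd.DataFrame(
            [[1, 1, 2, 2]] * 4 + [[2, 2, 1, 1]] * 4,
            index=[f"a{i}" for i in range(8)], columns=list("wxyz"),
        )
        result = pca(m, n_components=2)
        assert result.explained_variance_fraction[0] == pytest.approx(1.0)
        pc1 = result.coordinates["PC1"]
        assert len(set(np.sign(pc1[:4]))) == 1
        assert set(np.sign(pc1[:4])) != set(np.sign(pc1[4:]))

    def test_constant_matrix_has_zero_variance(self):
        m = pd.DataFrame([[1, 2, 1]] * 5, index=[f"a{i}" for i in range(5)],
                         columns=list("xyz"))
        result = pca(m)
        assert np.allclose(result.coordinates.to_numpy(), 0.0)
        assert np.allclose(result.explained_variance_fraction, 0.0)

    def test_coordinates_invariant_under_row_permutation(self, panel_population):
        m = panel_population.matrix
        base = pca(m, 2).coordinates
        perm = m.sample(frac=1.0, random_state=0)
        shuffled = pca(perm, 2).coordinates.loc[base.index]
        assert np.allclose(np.abs(base.to_numpy()), np.abs(shuffled.to_numpy()),
                           atol=1e-8)

    def test_explained_fractions_non_increasing_and_bounded(self, panel_population):
        result = pca(panel_population.matrix, 5)
        f = result.explained_variance_fraction
        assert np.all(np.diff(f) <= 1e-12)
        assert f.sum() <= 1.0 + 1e-9
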