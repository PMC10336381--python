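"""Quartet dissimilarity, PCoA, disparity and clade recovery."""

import numpy as np
import pytest

from topodissect.treespace import (
    clade_recovery,
    disparity,
    dissimilarity_matrix,
    pcoa,
    quartet_dissimilarity,
    subsample_null,
)
from topodissect.trees import Phylogeny

from conftest import bipartition_quartet_dissimilarity, random_binary_newick


class TestQuartetDissimilarity:
    def test_identical_trees_are_zero(self, rng):
        nw = random_binary_newick([f"s{i}" for i in range(6)], rng)
        t = Phylogeny.from_newick(nw)
        assert quartet_dissimilarity(t, t.clone()) == 0.0

    def test_opposing_four_tip_trees_are_one(self):
        a = Phylogeny.from_newick("((A,B),(C,D));")
        b = Phylogeny.from_newick("((A,C),(B,D));")
        assert quartet_dissimilarity(a, b) == 1.0

    def test_five_tip_example_against_enumeration(self):
        t1 = Phylogeny.from_newick("((A,B),(C,(D,E)));")
        t2 = Phylogeny.from_newick("((A,C),(B,(D,E)));")
        val = quartet_dissimilarity(t1, t2)
        oracle = bipartition_quartet_dissimilarity(t1, t2)
        assert val == oracle
        # explicit enumeration: of the 5 quartets only ABCD and ABCE differ
        assert val == pytest.approx(2 / 5)

    def test_symmetry_and_shared_taxon_pruning(self, rng):
        t1 = Phylogeny.from_newick(
            random_binary_newick([f"s{i}" for i in range(8)], rng)
        )
        t2 = Phylogeny.from_newick(
            random_binary_newick([f"s{i}" for i in range(4, 12)], rng)
        )
        d12 = quartet_dissimilarity(t1, t2)
        d21 = quartet_dissimilarity(t2, t1)
        assert d12 == d21
        assert d12 == bipartition_quartet_dissimilarity(t1, t2)

    def test_fewer_than_four_shared_tips_is_undefined(self):
        t1 = Phylogeny.from_newick("((A,B),(C,X1),(X2,X3));")
        t2 = Phylogeny.from_newick("((A,B),(C,Y1),(Y2,Y3));")
        assert quartet_dissimilarity(t1, t2) is None
        detailed = quartet_dissimilarity(t1, t2, detailed=True)
        assert detailed.flag == "lt4_shared"

    def test_polytomies_excluded_from_both_counts(self):
        star = Phylogeny.from_newick("(A,B,C,D,E);")
        resolved = Phylogeny.from_newick("((A,B),(C,(D,E)));")
        res = quartet_dissimilarity(star, resolved, detailed=True)
        assert res.n_mutually_resolved == 0
        assert res.value == 0.0
        assert res.flag == "no_mutually_resolved"

    def test_matrix_median_imputation(self, rng):
        trees = {
            f"g{i}": Phylogeny.from_newick(
                random_binary_newick([f"s{j}" for j in range(7)], rng)
            )
            for i in range(4)
        }
        trees["island"] = Phylogeny.from_newick("((z1,z2),(z3,s0));")
        D, ids, imputed = dissimilarity_matrix(trees)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        k = ids.index("island")
        assert imputed[k].sum() == len(ids) - 1


class TestPCoA:
    def test_equilateral_triangle(self):
        D = np.ones((3, 3))
        np.fill_diagonal(D, 0)
        res = pcoa(D)
        assert len(res.eigenvalues) == 2
        assert np.allclose(res.eigenvalues, res.eigenvalues[0])
        d01 = np.linalg.norm(res.coordinates[0] - res.coordinates[1])
        assert np.isclose(d01, 1.0)

    def test_collinear_points_give_single_axis(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        res = pcoa(D)
        assert len(res.eigenvalues) == 1

    def test_euclidean_self_consistency(self, rng):
        P = rng.normal(size=(10, 3))
        D = np.linalg.norm(P[:, None] - P[None, :], axis=2)
        res = pcoa(D)
        D2 = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=2
        )
        assert np.abs(D - D2).max() < 1e-8
        assert res.cailliez_constant == 0.0

    def test_matches_scikit_bio_on_euclidean_input(self, rng):
        """Independent implementation check on a Euclidean matrix."""
        from skbio.stats.ordination import pcoa as skbio_pcoa

        P = rng.normal(size=(8, 2))
        D = np.linalg.norm(P[:, None] - P[None, :], axis=2)
        mine = pcoa(D)
        theirs = skbio_pcoa(D, number_of_dimensions=2)
        ev_theirs = np.asarray(theirs.eigvals)[:2]
        assert np.allclose(np.sort(mine.eigenvalues)[::-1], ev_theirs,
                           atol=1e-8)

    def test_cailliez_correction_applied_to_non_euclidean(self):
        # violates the triangle inequality: needs correction
        D = np.array(
            [[0.0, 1.0, 0.1], [1.0, 0.0, 0.1], [0.1, 0.1, 0.0]]
        )
        D = np.array([[0, 5, 1, 1], [5, 0, 1, 1],
                      [1, 1, 0, 1], [1, 1, 1, 0]], dtype=float)
        res = pcoa(D)
        assert res.cailliez_constant > 0
        assert np.all(res.eigenvalues > 0)

    @pytest.mark.parametrize(
        "bad", [np.ones((3, 4)), np.array([[0, 1], [2, 0]])],
        ids=["non-square", "asymmetric"],
    )
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            pcoa(bad)


class TestDisparity:
    def test_single_point_is_zero(self):
        assert disparity(np.array([[1.0, 2.0]])) == 0.0

    def test_two_points_distance_two(self):
        assert disparity(np.array([[0.0, 0.0], [2.0, 0.0]])) == 1.0

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(20, 3))
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        assert np.isclose(disparity(X), disparity(X @ R.T))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            disparity(np.ones((3, 2)), [])


class TestSubsampleNull:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 2))
        obs = disparity(X, np.arange(10))
        a = subsample_null(X, 10, obs, n_reps=50, seed=42)
        b = subsample_null(X, 10, obs, n_reps=50, seed=42)
        assert np.array_equal(a["null"], b["null"])

    def test_near_centroid_subset_has_extreme_percentile(self, rng):
        X = rng.normal(size=(60, 2))
        centroid = X.mean(axis=0)
        nearest = np.argsort(np.linalg.norm(X - centroid, axis=1))[:15]
        obs = disparity(X, nearest)
        res = subsample_null(X, 15, obs, n_reps=200, seed=1)
        assert res["percentile_p"] <= 0.01
        assert res["significant_reduction"]

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError):
            subsample_null(np.ones((5, 2)), 6, 0.0)


class TestCladeRecovery:
    def test_recovered_and_not_recovered(self):
        g = Phylogeny.from_newick("((A,B),(C,D),(E,F));")
        rec = clade_recovery(g, {"ab": {"A", "B"}, "ac": {"A", "C"}})
        assert rec.status == {"ab": "recovered", "ac": "not_recovered"}
        assert rec.proportion_recovered == 0.5

    def test_single_sampled_member_untestable(self):
        g = Phylogeny.from_newick("((A,B),(C,D),(E,F));")
        rec = clade_recovery(
            g, {"solo": {"A", "Z9"}, "ab": {"A", "B"}}
        )
        assert rec.status["solo"] == "untestable"
        # proportion over testable clades only
        assert rec.proportion_recovered == 1.0

    def test_all_untestable_gives_nan(self):
        g = Phylogeny.from_newick("((A,B),(C,D));")
        rec = clade_recovery(g, {"x": {"Q", "R"}})
        assert np.isnan(rec.proportion_recovered)

    def test_nni_perturbed_half_is_tighter_than_random(self, rng):
        """Trees one NNI from a base tree cluster tighter in treespace
        than random trees, so their disparity is lower."""
        from topodissect.simulate import _nni_perturb
        from topodissect.treespace import build_treespace

        labels = [f"s{i}" for i in range(10)]
        base = Phylogeny.from_newick(random_binary_newick(labels, rng))
        trees = {}
        for i in range(10):
            t, _ = _nni_perturb(base, rng)
            trees[f"nni{i}"] = t
        for i in range(10):
            trees[f"rand{i}"] = Phylogeny.from_newick(
                random_binary_newick(labels, rng)
            )
        ts = build_treespace(
            trees, subsets={"nni": [f"nni{i}" for i in range(10)]},
            n_reps=200, seed=0,
        )
        assert ts.subset_disparities["nni"] < ts.disparity_full
        assert ts.percentile_p["nni"] <= 0.05
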