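"""Gene-property panel and the usefulness ranking."""

import numpy as np
import pandas as pd
import pytest

from topodissect.alignment import LocusAlignment
from topodissect.properties import (
    PROPERTY_NAMES,
    compute_properties,
    mean_site_entropy,
    p_distance_matrix,
    proportion_parsimony_informative,
    proportion_variable_sites,
    rcfv,
    records_to_frame,
    saturation,
    subset_by_usefulness,
    usefulness_sort,
)
from topodissect.trees import Phylogeny

from conftest import random_alignment, random_binary_newick


def star_tree(labels, bl=1e-8):
    return Phylogeny.from_newick(
        "(" + ",".join(f"{t}:{bl}" for t in labels) + ");"
    )


class TestAlignmentMetrics:
    def test_identical_sequences_on_star_tree(self):
        aln = LocusAlignment("x", list("ABCD"), ["ARND"] * 4)
        tree = star_tree(list("ABCD"))
        rec = compute_properties(aln, tree, None)
        assert rec.prop_variable_sites == 0.0
        assert rec.prop_parsimony_informative == 0.0
        assert rec.treeness == 0.0
        assert rec.total_tree_length < 1e-6
        assert rec.rcfv == 0.0

    def test_variable_and_informative_proportions(self):
        aln = LocusAlignment(
            "x", list("ABCD"), ["AARA", "AARR", "ARRA", "ARRR"]
        )
        # col0 constant; col1 A/R 2+2 (informative); col2 constant R;
        # col3 A/R 2+2 (informative)
        assert proportion_variable_sites(aln) == 0.5
        assert proportion_parsimony_informative(aln) == 0.5
        singleton = LocusAlignment("y", list("ABCD"), ["A", "A", "A", "R"])
        assert proportion_variable_sites(singleton) == 1.0
        assert proportion_parsimony_informative(singleton) == 0.0

    def test_entropy_of_uniform_binary_column(self):
        aln = LocusAlignment("x", list("ABCD"), ["A", "A", "R", "R"])
        assert np.isclose(mean_site_entropy(aln), 1.0)  # 1 bit

    def test_rcfv_two_taxon_disjoint_compositions(self):
        """All-A vs all-R: each taxon deviates by 0.5 in two states."""
        aln = LocusAlignment("x", ["t1", "t2"], ["AAAA", "RRRR"])
        # mean freq = (0.5, 0.5, 0, ...); each taxon: |1-0.5| + |0-0.5| = 1
        assert np.isclose(rcfv(aln), 1.0)

    def test_rcfv_invariant_to_taxon_order(self, rng):
        aln = random_alignment(list("ABCDE"), 40, rng)
        perm = LocusAlignment(
            "p", aln.taxa[::-1], aln.sequences[::-1]
        )
        assert np.isclose(rcfv(aln), rcfv(perm))

    def test_p_distance_ignores_pairwise_missing(self):
        aln = LocusAlignment("x", ["a", "b"], ["ARX-ND", "AR-XNR"])
        D = p_distance_matrix(aln)
        # comparable columns: 0,1,4,5 -> one mismatch in 4... cols 2,3 have
        # missing on one side each; col 5 N vs R mismatch
        assert np.isclose(D[0, 1], 1 / 4)


class TestSaturation:
    def test_perfect_proportionality_closed_form(self):
        """Exact least squares: slope = sum(xy)/sum(x^2) through origin."""
        tree = Phylogeny.from_newick(
            "((A:0.05,B:0.05):0.02,(C:0.05,D:0.05):0.02);"
        )
        aln = LocusAlignment("x", list("ABCD"),
                             ["AAAA", "AAAR", "AARA", "AARR"])
        val = saturation(aln, tree)
        P = p_distance_matrix(aln)
        T = tree.patristic_distances(list("ABCD"))
        iu = np.triu_indices(4, k=1)
        slope = np.sum(T[iu] * P[iu]) / np.sum(T[iu] ** 2)
        assert np.isclose(val, 1 - slope)

    def test_low_divergence_has_low_saturation(self, rng):
        from conftest import simulate_on_tree
        from topodissect.models import get_model

        tree = Phylogeny.from_newick(
            "((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01,E:0.02);"
        )
        aln = simulate_on_tree(tree, get_model("LG"), 5000, rng)
        assert abs(saturation(aln, tree)) < 0.1

    def test_scaling_patristic_increases_saturation(self):
        tree1 = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tree10 = Phylogeny.from_newick("((A:10,B:10):10,(C:10,D:10):10);")
        aln = LocusAlignment("x", list("ABCD"),
                             ["AARR", "ARRA", "RARA", "RRAA"])
        assert saturation(aln, tree10) > saturation(aln, tree1)


class TestTreeMetrics:
    def test_ultrametric_tree_zero_root_to_tip_variance(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        rec = compute_properties(
            LocusAlignment("x", list("ABCD"), ["ARND"] * 4), tree, None
        )
        assert rec.root_to_tip_variance < 1e-12

    def test_reference_identity_gives_rf_similarity_one(self, rng):
        nw = random_binary_newick([f"s{i}" for i in range(8)], rng)
        tree = Phylogeny.from_newick(nw)
        aln = random_alignment([f"s{i}" for i in range(8)], 30, rng)
        rec = compute_properties(aln, tree, tree.clone())
        assert rec.rf_similarity == 1.0

    def test_small_tree_leaves_tree_fields_missing(self):
        aln = LocusAlignment("x", list("ABC"), ["AR", "AR", "AR"])
        rec = compute_properties(aln, None, None)
        assert rec.alignment_length == 2.0
        assert np.isnan(rec.avg_bootstrap)
        assert np.isnan(rec.treeness)

    def test_column_order_invariance(self, rng):
        labels = [f"s{i}" for i in range(6)]
        aln = random_alignment(labels, 30, rng)
        tree = Phylogeny.from_newick(random_binary_newick(labels, rng))
        rec1 = compute_properties(aln, tree, tree)
        perm = rng.permutation(30)
        shuffled = LocusAlignment(
            aln.locus_id, aln.taxa,
            ["".join(s[j] for j in perm) for s in aln.sequences],
        )
        rec2 = compute_properties(shuffled, tree, tree)
        for name in PROPERTY_NAMES:
            v1, v2 = getattr(rec1, name), getattr(rec2, name)
            assert (np.isnan(v1) and np.isnan(v2)) or np.isclose(v1, v2)


def synthetic_panel(rng, n=60):
    """Panel where 'good' loci have high bootstrap/rf and low bias metrics."""
    quality = rng.uniform(0, 1, n)  # latent usefulness
    frame = pd.DataFrame({"locus_id": [f"L{i:03d}" for i in range(n)]})
    noise = lambda s: rng.normal(0, s, n)
    frame["alignment_length"] = 200 + 200 * rng.uniform(size=n)
    frame["pct_missing"] = 20 + noise(5)
    frame["prop_variable_sites"] = 0.5 + noise(0.05)
    frame["prop_parsimony_informative"] = 0.3 + noise(0.05)
    frame["n_taxa"] = 30 + rng.integers(0, 9, n)
    frame["avg_bootstrap"] = 50 + 45 * quality + noise(4)
    frame["rf_similarity"] = 0.3 + 0.6 * quality + noise(0.04)
    frame["root_to_tip_variance"] = 0.5 - 0.4 * quality + noise(0.04)
    frame["saturation"] = 0.8 - 0.6 * quality + noise(0.04)
    frame["rcfv"] = 0.4 - 0.3 * quality + noise(0.03)
    frame["total_tree_length"] = 3 + noise(0.5)
    frame["avg_patristic_distance"] = 1 + noise(0.2)
    frame["treeness"] = 0.4 + noise(0.05)
    frame["treeness_over_rcfv"] = frame["treeness"] / frame["rcfv"].clip(0.01)
    frame["mean_site_entropy"] = 2 + noise(0.3)
    return frame, quality


class TestUsefulnessSort:
    def test_top_decile_enriched_for_good_loci(self, rng):
        frame, quality = synthetic_panel(rng)
        res = usefulness_sort(frame)
        good = set(frame.loc[quality > 0.7, "locus_id"])
        top = set(res.ranked_ids[: len(frame) // 10])
        base_rate = len(good) / len(frame)
        hit_rate = len(top & good) / len(top)
        assert hit_rate >= 3 * base_rate

    def test_deterministic_and_duplicate_rows_adjacent(self, rng):
        frame, _ = synthetic_panel(rng)
        dup = frame.iloc[[5]].assign(locus_id="L005dup")
        frame2 = pd.concat([frame, dup], ignore_index=True)
        res = usefulness_sort(frame2)
        res_again = usefulness_sort(frame2)
        assert res.ranked_ids == res_again.ranked_ids
        i = res.ranked_ids.index("L005")
        assert res.ranked_ids[i + 1] == "L005dup"

    def test_no_matching_axis_raises(self, rng):
        frame, _ = synthetic_panel(rng)
        # destroy the pattern: make a bias metric identical to a signal one
        frame["root_to_tip_variance"] = frame["avg_bootstrap"]
        frame["saturation"] = frame["avg_bootstrap"] + rng.normal(0, 0.01, len(frame))
        frame["rcfv"] = frame["avg_bootstrap"]
        with pytest.raises(ValueError, match="axis"):
            usefulness_sort(frame)

    def test_too_few_loci_rejected(self, rng):
        frame, _ = synthetic_panel(rng, n=5)
        with pytest.raises(ValueError):
            usefulness_sort(frame)


class TestSubsetByUsefulness:
    def test_half_and_quarter_of_1100(self):
        ids = [f"g{i}" for i in range(1100)]
        assert len(subset_by_usefulness(ids, fraction=0.5)) == 550
        assert len(subset_by_usefulness(ids, fraction=0.25)) == 275
        assert len(subset_by_usefulness(ids, count=225)) == 225

    def test_fraction_one_is_identity(self):
        ids = list("abcde")
        assert subset_by_usefulness(ids, fraction=1.0) == ids

    def test_ceiling_behaviour_and_validation(self):
        ids = list("abcde")
        assert len(subset_by_usefulness(ids, fraction=0.5)) == 3
        with pytest.raises(ValueError):
            subset_by_usefulness(ids, fraction=0.0)
        with pytest.raises(ValueError):
            subset_by_usefulness(ids)
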