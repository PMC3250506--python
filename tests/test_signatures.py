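"""Clustering, signature extraction, scoring, stratification, centroids."""

import numpy as np
import pandas as pd
import pytest

from hetint.signatures import (
    GeneSignature,
    centroid_values,
    correlate_signatures,
    cut_two_groups,
    extract_induced_genes,
    hierarchical_cluster,
    map_signature,
    signature_score,
    split_by_gene_threshold,
    split_by_score_sign,
    uncentered_correlation,
)
from hetint.simulate import CoCultureSimSpec, simulate_coculture

from conftest import make_matrix


class TestUncenteredCorrelation:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
            ([1.0, 0.0], [0.0, 1.0], 0.0),
            ([1.0, 1.0], [1.0, -1.0], 0.0),
            ([1.0, 2.0], [-1.0, -2.0], -1.0),
        ],
    )
    def test_examples(self, x, y, expected):
        assert uncentered_correlation(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_all_zero_vector_defined_as_zero(self):
        assert uncentered_correlation(np.zeros(3), np.ones(3)) == 0.0

    def test_too_few_paired_entries(self):
        x = np.array([1.0, np.nan, np.nan])
        y = np.array([1.0, 1.0, np.nan])
        with pytest.raises(ValueError):
            uncentered_correlation(x, y)

    def test_no_mean_subtraction(self):
        # constant vectors correlate perfectly under the Eisen convention
        assert uncentered_correlation(np.full(4, 2.0), np.full(4, 9.0)) == pytest.approx(1.0)


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        m = make_matrix([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [5.0, -1.0, 0.0]])
        tree = hierarchical_cluster(m, axis="genes")
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_tree_has_n_minus_1_merges(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(0, 1, (9, 5)))
        tree = hierarchical_cluster(m)
        assert tree.n_merges == 8 and tree.n_items == 9

    def test_planted_groups_recovered_at_top_split(self):
        rng = np.random.default_rng(1)
        a = rng.normal(3, 0.2, (4, 6))
        b = rng.normal(-3, 0.2, (4, 6))
        m = make_matrix(np.vstack([a, b]))
        split = cut_two_groups(hierarchical_cluster(m))
        assert set(split.high) == {"g0", "g1", "g2", "g3"}
        assert set(split.low) == {"g4", "g5", "g6", "g7"}

    def test_permutation_invariance_of_partition(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(0, 1, (12, 5)))
        perm = rng.permutation(12)
        shuffled = m.iloc[perm]
        s1 = cut_two_groups(hierarchical_cluster(m))
        s2 = cut_two_groups(hierarchical_cluster(shuffled))
        assert {frozenset(s1.high), frozenset(s1.low)} == {
            frozenset(s2.high),
            frozenset(s2.low),
        }

    def test_items_with_too_few_values_excluded(self):
        m = make_matrix([[1.0, np.nan, np.nan], [1.0, 2.0, 3.0], [2.0, 1.0, 0.5]])
        with pytest.warns(UserWarning, match="excluding"):
            tree = hierarchical_cluster(m)
        assert tree.n_items == 2

    def test_newick_export_parses(self):
        from io import StringIO

        from Bio import Phylo

        m = make_matrix(np.random.default_rng(3).normal(0, 1, (5, 4)))
        tree = hierarchical_cluster(m)
        phylo = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert len(phylo.get_terminals()) == 5


class TestCutTwoGroups:
    def test_singleton_branch(self):
        m = make_matrix([[0.0, 0.1, 0.0], [0.1, 0.0, 0.1], [9.0, -9.0, 8.0]])
        split = cut_two_groups(hierarchical_cluster(m))
        sizes = sorted([len(split.high), len(split.low)])
        assert sizes == [1, 2]

    def test_label_swaps_under_global_sign_flip(self):
        rng = np.random.default_rng(4)
        a = rng.normal(2, 0.2, (3, 5))
        b = rng.normal(-2, 0.2, (3, 5))
        m = make_matrix(np.vstack([a, b]))
        s = cut_two_groups(hierarchical_cluster(m))
        s_flipped = cut_two_groups(hierarchical_cluster(-m))
        assert set(s.high) == set(s_flipped.low)
        assert set(s.low) == set(s_flipped.high)


class TestExtractInducedGenes:
    def test_rule_examples(self, small_design):
        m = make_matrix(
            [
                [0.0, 0.2, 1.0, 0.8, 2.0, 2.1],  # co always above both monos
                [0.0, 0.1, 2.0, 2.1, 1.0, 1.1],  # co intermediate
            ],
            samples=["monoA_r1", "monoA_r2", "monoB_r1", "monoB_r2", "co_r1", "co_r2"],
        )
        sig = extract_induced_genes(m, small_design)
        assert sig.gene_ids == ["g0"]

    def test_margin_excludes_weak_induction(self, small_design):
        m = make_matrix(
            [[0.0, 0.0, 0.0, 0.0, 0.3, 0.3]],
            samples=["monoA_r1", "monoA_r2", "monoB_r1", "monoB_r2", "co_r1", "co_r2"],
        )
        with pytest.raises(ValueError):
            extract_induced_genes(m, small_design, delta=0.5)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(5)
        planted = tuple(int(i) for i in rng.choice(2000, 80, replace=False))
        spec = CoCultureSimSpec(
            n_genes=2000, induced_sets=((planted, 4.0),), noise_cv=0.1, seed=6
        )
        sim = simulate_coculture(spec)
        sig = extract_induced_genes(sim.matrix, sim.design)
        planted_ids = set(sim.truth["induced_genes"])
        recovered = set(sig.gene_ids)
        assert len(recovered & planted_ids) / len(planted_ids) >= 0.9
        fpr = len(recovered - planted_ids) / (2000 - len(planted_ids))
        assert fpr < 0.05


class TestMapSignature:
    def test_duplicates_collapsed_then_mapped(self):
        sig = GeneSignature("s", [("a", 1), ("a", 1), ("b", -1), ("c", 1)])
        assert len(sig) == 3  # collapsed on construction
        cohort = make_matrix(np.zeros((2, 3)), genes=["p1", "p2"])
        id_map = pd.DataFrame(
            {"gene_id": ["a", "a", "b"], "probe_id": ["p1", "p2", "p1"]}
        )
        mapped, report = map_signature(sig, cohort, id_map)
        # a takes p1 (first match); b falls through to nothing free in cohort
        assert [g for g, _ in mapped.members] == ["p1"]
        assert report["n_mapped"] == 1
        assert set(report["unmapped"]) == {"b", "c"}
        assert report["multimap"]["a"] == ["p1", "p2"]

    def test_direction_carried_through(self):
        sig = GeneSignature("s", [("a", -1)])
        cohort = make_matrix(np.zeros((1, 2)), genes=["p1"])
        id_map = pd.DataFrame({"gene_id": ["a"], "probe_id": ["p1"]})
        mapped, _ = map_signature(sig, cohort, id_map)
        assert mapped.members == [("p1", -1)]

    def test_all_unmapped_is_error(self):
        sig = GeneSignature("s", [("a", 1)])
        cohort = make_matrix(np.zeros((1, 2)), genes=["p1"])
        id_map = pd.DataFrame({"gene_id": ["z"], "probe_id": ["p1"]})
        with pytest.raises(ValueError, match="mapped"):
            map_signature(sig, cohort, id_map)


class TestSignatureScore:
    def test_hand_sum(self):
        m = make_matrix([[1.0], [-0.5], [0.5]], genes=["a", "b", "c"], samples=["s"])
        sig = GeneSignature("s", [("a", 1), ("b", 1), ("c", 1)])
        scores, n = signature_score(m, sig)
        assert scores["s"] == pytest.approx(1.0)
        assert n["s"] == 3

    def test_direction_sign(self):
        m = make_matrix([[1.0]], genes=["a"], samples=["s"])
        sig = GeneSignature("s", [("a", -1)])
        scores, _ = signature_score(m, sig)
        assert scores["s"] == pytest.approx(-1.0)

    def test_all_zero_matrix(self):
        m = make_matrix(np.zeros((3, 2)), genes=["a", "b", "c"])
        sig = GeneSignature("s", [("a", 1), ("b", -1)])
        scores, _ = signature_score(m, sig)
        assert (scores == 0).all()

    def test_missing_contributes_zero_and_is_counted(self):
        m = make_matrix([[1.0, np.nan]], genes=["a"])
        sig = GeneSignature("s", [("a", 1)])
        scores, n = signature_score(m, sig)
        assert scores.iloc[1] == 0.0 and n.iloc[1] == 0

    def test_additive_over_disjoint_signatures(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(0, 1, (6, 4)), genes=list("abcdef"))
        s1 = GeneSignature("s1", [("a", 1), ("b", -1), ("c", 1)])
        s2 = GeneSignature("s2", [("d", -1), ("e", 1), ("f", 1)])
        union = GeneSignature("u", s1.members + s2.members)
        total = signature_score(m, union).scores
        parts = signature_score(m, s1).scores + signature_score(m, s2).scores
        assert np.allclose(total, parts)


class TestSplits:
    def test_score_sign_counts(self):
        scores = pd.Series([-1.0, -2.0, 3.0], index=["a", "b", "c"])
        split = split_by_score_sign(scores)
        assert split.counts == (2, 1)

    def test_zero_score_goes_above(self):
        split = split_by_score_sign(pd.Series([0.0], index=["a"]))
        assert split.above == ["a"] and split.below == []

    def test_paper_scale_group_separation(self):
        # two branches with score means -3.9 and +3.8, SD ~5.3: the sign split
        # misclassifies fewer than a quarter of the samples
        rng = np.random.default_rng(7)
        low = rng.normal(-3.93, 5.3, 500)
        high = rng.normal(3.8, 5.4, 500)
        scores = pd.Series(
            np.concatenate([low, high]),
            index=[f"p{i}" for i in range(1000)],
        )
        split = split_by_score_sign(scores)
        mis = sum(1 for i in range(500) if f"p{i}" in set(split.above))
        mis += sum(1 for i in range(500, 1000) if f"p{i}" in set(split.below))
        assert mis / 1000 < 0.25

    def test_gene_threshold_split(self):
        m = make_matrix([[-0.2, 0.1, -1.0]], genes=["IL6"])
        split = split_by_gene_threshold(m, "IL6")
        assert split.counts == (2, 1)

    def test_gene_threshold_degenerate_warns(self):
        m = make_matrix([[-0.2, -0.1]], genes=["IL6"])
        with pytest.warns(UserWarning):
            split = split_by_gene_threshold(m, "IL6")
        assert split.counts == (2, 0)

    def test_absent_gene_errors(self):
        m = make_matrix([[0.0]], genes=["a"])
        with pytest.raises(KeyError):
            split_by_gene_threshold(m, "IL6")


class TestCentroids:
    def test_single_gene_centroid_is_row(self):
        m = make_matrix([[1.0, 2.0, 3.0]], genes=["a"])
        sig = GeneSignature("s", [("a", 1)])
        assert list(centroid_values(sig, m)) == [1.0, 2.0, 3.0]

    def test_two_gene_mean(self):
        m = make_matrix([[1.0], [3.0]], genes=["a", "b"], samples=["p"])
        sig = GeneSignature("s", [("a", 1), ("b", 1)])
        assert centroid_values(sig, m)["p"] == pytest.approx(2.0)

    def test_centered_matrix_gives_near_zero_mean_profile(self):
        from hetint.io import mean_center_genes

        rng = np.random.default_rng(8)
        m = mean_center_genes(make_matrix(rng.normal(0, 1, (10, 30))))
        sig = GeneSignature("s", [(f"g{i}", 1) for i in range(10)])
        profile = centroid_values(sig, m)
        assert abs(profile.mean()) < 1e-12

    def test_correlations(self):
        p1 = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert correlate_signatures(p1, p1) == pytest.approx(1.0)
        assert correlate_signatures(p1, -p1) == pytest.approx(-1.0)
        assert correlate_signatures(p1, 2 * p1) == pytest.approx(1.0)
        assert correlate_signatures(p1, 0.5 * p1 + 3) == pytest.approx(1.0)

    def test_zero_variance_profile_is_nan_with_warning(self):
        p1 = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        flat = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.warns(UserWarning):
            assert np.isnan(correlate_signatures(p1, flat))

    def test_too_few_patients_errors(self):
        p1 = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            correlate_signatures(p1, p1)


class TestSignatureIO:
    def test_tsv_round_trip(self, tmp_path):
        sig = GeneSignature("mysig", [("a", 1), ("b", -1)])
        path = tmp_path / "sig.tsv"
        sig.to_tsv(path)
        back = GeneSignature.from_tsv(path, name="mysig")
        assert back.members == sig.members

    def test_duplicates_collapsed_on_load(self, tmp_path):
        path = tmp_path / "sig.tsv"
        path.write_text("gene_id\tdirection\na\t1\na\t1\nb\t-1\n")
        sig = GeneSignature.from_tsv(path)
        assert len(sig) == 2
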