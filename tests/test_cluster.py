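"""Ward clustering, dendrogram cutting, median dichotomy, chi-square test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from chemosig import (ClusterPartition, DataError, ValidationError,
                      cut_dendrogram, dichotomize_response,
                      generate_grouped_panel, ward_cluster)
from chemosig import test_predictability as predictability_test
from oracles import (best_two_partition, chi2_hand, linkage_merge_sets,
                     same_partition, ward_brute)


def _panel_from(X, cells=None):
    X = np.asarray(X, float)
    cells = cells or [f"c{i}" for i in range(X.shape[0])]
    return pd.DataFrame(X.T, index=pd.Index([f"g{i}" for i in range(X.shape[1])],
                                            name="gene_id"), columns=cells)


def _partition(labels, cells=None):
    cells = cells or [f"c{i}" for i in range(len(labels))]
    assignment = pd.Series(labels, index=cells, name="cluster")
    k = int(max(labels))
    sizes = [int((assignment == c).sum()) for c in range(1, k + 1)]
    return ClusterPartition(k=k, assignment=assignment, sizes=sizes)


def _dichotomy(values, cells=None, **kw):
    cells = cells or [f"c{i}" for i in range(len(values))]
    return dichotomize_response(pd.Series(np.asarray(values, float),
                                          index=cells), **kw)


class TestWard:
    def test_two_leaves_merge_at_their_euclidean_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        dend = ward_cluster(_panel_from(X), standardize=False)
        assert dend.merges == [(0, 1, pytest.approx(5.0), 2)]

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_merge_sequence_matches_exhaustive_ess_agglomeration(self, n, rng):
        for _ in range(8):
            X = rng.normal(size=(n, 3))
            dend = ward_cluster(_panel_from(X), standardize=False)
            got = linkage_merge_sets(dend.linkage, n)
            expected = ward_brute(X)
            for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
                assert {ga, gb} == {ea, eb}
                assert gh == pytest.approx(eh, rel=1e-9)

    def test_two_planted_groups_recovered_and_match_exhaustive_cut(self, rng):
        centers = np.array([[0.0] * 4, [50.0] * 4])
        truth = np.array([0, 1, 0, 1, 1, 0])
        X = centers[truth] + rng.normal(size=(6, 4))
        dend = ward_cluster(_panel_from(X), standardize=False)
        part = cut_dendrogram(dend, 2)
        assert same_partition(part.assignment.to_numpy(), truth)
        assert same_partition(part.assignment.to_numpy(), best_two_partition(X))

    def test_heights_monotone_on_random_inputs(self, rng):
        for _ in range(50):
            X = rng.normal(size=(rng.integers(3, 12), 4))
            dend = ward_cluster(_panel_from(X), standardize=False)
            heights = dend.linkage[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)

    def test_zero_variance_gene_dropped_with_standardization(self, rng):
        X = rng.normal(size=(6, 3))
        X[:, 1] = 7.0
        dend = ward_cluster(_panel_from(X))  # standardize on: gene dropped
        assert dend.n_leaves == 6

    def test_all_zero_variance_genes_is_an_error(self):
        X = np.full((5, 2), 1.5)
        with pytest.raises(DataError, match="zero variance"):
            ward_cluster(_panel_from(X))

    def test_newick_round_trips_with_dendropy(self):
        import dendropy

        panel, _ = generate_grouped_panel(n_cell_lines=12, n_genes=5, seed=3)
        dend = ward_cluster(panel)
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set(panel.columns)
        # root-to-leaf depth equals the root merge height for every leaf
        root_height = dend.linkage[-1, 2]
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_height,
                                                              rel=1e-6)


class TestCut:
    def test_k_one_is_a_single_cluster(self, rng):
        X = rng.normal(size=(6, 3))
        part = cut_dendrogram(ward_cluster(_panel_from(X)), 1)
        assert part.sizes == [6]

    def test_k_equal_n_gives_singletons(self, rng):
        X = rng.normal(size=(6, 3))
        part = cut_dendrogram(ward_cluster(_panel_from(X)), 6)
        assert part.sizes == [1] * 6

    def test_k_out_of_range_rejected(self, rng):
        dend = ward_cluster(_panel_from(rng.normal(size=(6, 3))))
        for k in (0, 7, -1):
            with pytest.raises(ValidationError, match="k"):
                cut_dendrogram(dend, k)

    def test_four_planted_groups_recovered_at_k_four(self):
        panel, labels = generate_grouped_panel(n_cell_lines=47, n_genes=40,
                                               n_groups=4, shift=6.0,
                                               noise_sd=1.0, seed=21)
        part = cut_dendrogram(ward_cluster(panel), 4)
        assert same_partition(part.assignment.to_numpy(), labels.to_numpy())

    def test_cluster_ids_numbered_in_leaf_order(self, rng):
        X = rng.normal(size=(8, 3))
        dend = ward_cluster(_panel_from(X))
        part = cut_dendrogram(dend, 3)
        first_seen = []
        for cell in dend.leaf_order():
            c = part.assignment[cell]
            if c not in first_seen:
                first_seen.append(c)
        assert first_seen == [1, 2, 3]


class TestDichotomy:
    def test_even_split(self):
        d = _dichotomy([1.0, 2.0, 3.0, 4.0])
        assert d.median_cutoff == 2.5
        assert d.counts == {"sensitive": 2, "resistant": 2}

    def test_value_at_median_is_resistant_by_default(self):
        d = _dichotomy([1.0, 2.0, 3.0, 4.0, 5.0])
        assert d.labels["c2"] == "resistant"  # value 3.0 == median
        assert d.counts == {"sensitive": 2, "resistant": 3}

    def test_sensitive_tie_rule_flips_exactly_the_at_median_lines(self):
        values = [1.0, 2.0, 2.0, 3.0, 4.0, 2.0]
        hard = _dichotomy(values, tie_rule="resistant").labels
        soft = _dichotomy(values, tie_rule="sensitive").labels
        flipped = hard[hard != soft].index
        at_median = [f"c{i}" for i, v in enumerate(values) if v == 2.0]
        assert sorted(flipped) == sorted(at_median)

    def test_identical_values_rejected(self):
        with pytest.raises(DataError, match="identical"):
            _dichotomy([2.0] * 6)

    def test_too_few_finite_values_rejected(self):
        with pytest.raises(DataError):
            _dichotomy([1.0, 2.0, np.nan, np.nan, np.nan])


class TestPredictability:
    def test_homogeneous_table_has_zero_statistic(self):
        part = _partition([1, 1, 1, 1, 2, 2, 2, 2])
        dich = _dichotomy([1, 1, 3, 3, 1, 1, 3, 3])
        res = predictability_test(part, dich, mc_reps=0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_separation_two_by_two(self):
        part = _partition([1] * 10 + [2] * 10)
        dich = _dichotomy([0.0] * 10 + [2.0] * 10)
        res = predictability_test(part, dich, mc_reps=0)
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_statistic_matches_hand_formula_and_scipy(self, rng):
        for _ in range(20):
            labels = rng.integers(1, 5, size=40)
            values = rng.normal(size=40)
            part = _partition(labels)
            dich = _dichotomy(values)
            res = predictability_test(part, dich, mc_reps=0)
            obs = res.table.to_numpy()
            assert res.statistic == pytest.approx(chi2_hand(obs), rel=1e-12)
            stat, p, df, _ = chi2_contingency(obs, correction=False)
            assert res.statistic == pytest.approx(stat, rel=1e-12)
            assert res.p_value == pytest.approx(p, rel=1e-9)
            assert res.df == df

    def test_invariant_to_cluster_relabeling_and_column_swap(self):
        values = [0.1, 0.9, 0.2, 1.5, 0.3, 1.7, 0.2, 1.9]
        part = _partition([1, 1, 2, 2, 3, 3, 1, 2])
        relabeled = _partition([3, 3, 1, 1, 2, 2, 3, 1])
        base = predictability_test(part, _dichotomy(values), mc_reps=0)
        swapped = predictability_test(
            part, _dichotomy([-v for v in values]), mc_reps=0)
        relab = predictability_test(relabeled, _dichotomy(values), mc_reps=0)
        assert base.statistic == pytest.approx(relab.statistic)
        assert base.statistic == pytest.approx(swapped.statistic)

    def test_monte_carlo_p_added_when_expected_counts_small(self, rng):
        part = _partition(rng.integers(1, 5, size=12))
        res = predictability_test(part, _dichotomy(rng.normal(size=12)),
                                  seed=0)
        assert res.min_expected < 5
        assert res.mc_p_value is not None and res.mc_reps > 0

    def test_monte_carlo_agrees_with_asymptotic_on_large_balanced_table(self, rng):
        labels = np.repeat([1, 2], 150)
        values = rng.normal(size=300) + 0.35 * (labels == 2)
        res = predictability_test(_partition(labels), _dichotomy(values),
                                  mc_reps=20000, seed=1)
        assert res.mc_p_value == pytest.approx(res.p_value, abs=0.015)

    def test_empty_response_class_rejected(self):
        part = _partition([1, 1, 2, 2])
        dich = _dichotomy([1.0, 2.0, 3.0, 4.0])
        dich.labels[:] = "resistant"
        with pytest.raises(DataError, match="empty"):
            predictability_test(part, dich)

    def test_mismatched_cell_lines_rejected(self):
        part = _partition([1, 1, 2, 2], cells=list("abcd"))
        dich = _dichotomy([1.0, 2.0, 3.0, 4.0], cells=list("wxyz"))
        with pytest.raises(DataError, match="different cell lines"):
            predictability_test(part, dich)

    @given(seed=st.integers(0, 200))
    def test_statistic_nonnegative_and_margins_conserved(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(1, 4, size=20)
        labels[:3] = [1, 2, 3]  # every cluster non-empty
        values = rng.normal(size=20)
        res = predictability_test(_partition(labels), _dichotomy(values),
                                  mc_reps=0)
        assert res.statistic >= 0
        np.testing.assert_allclose(res.expected.sum(axis=1),
                                   res.table.sum(axis=1))
        np.testing.assert_allclose(res.expected.sum(axis=0),
                                   res.table.sum(axis=0))
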