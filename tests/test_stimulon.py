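"""Spearman thresholding, stimulon graph construction, suffix merging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimulome import (
    ActivityMatrix,
    activity_spearman,
    build_stimulon_graph,
    sum_suffixed,
)
from stimulome.datasets import BlockSpec, SyntheticDesign, generate_activities


def _activities(rows, names=None):
    rows = np.asarray(rows, dtype=float)
    names = names or [f"c{i}" for i in range(rows.shape[0])]
    return ActivityMatrix(
        pd.DataFrame(rows, index=names, columns=[f"s{i}" for i in range(rows.shape[1])])
    )


class TestSpearman:
    def test_diagonal_and_antitone_pair(self):
        a = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 7.0])
        A = _activities([a, -(a**3)])
        rho, _ = activity_spearman(A)
        assert rho.loc["c0", "c0"] == 1.0
        assert rho.loc["c0", "c1"] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        A = _activities([[1, 2, 3, 4, 5], [1, 3, 2, 5, 4]])
        rho, _ = activity_spearman(A)
        assert rho.loc["c0", "c1"] == pytest.approx(0.8)

    def test_small_n_p_value_matches_brute_force_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        A = _activities([x, y])
        _, p = activity_spearman(A)
        # independent oracle: enumerate all 5! pairings with scipy
        rhos = [
            stats.spearmanr(x, np.array(perm))[0]
            for perm in itertools.permutations(y)
        ]
        p_exact = np.mean([abs(r) >= 0.8 - 1e-12 for r in rhos])
        assert p.loc["c0", "c1"] == pytest.approx(p_exact)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=(3, 20))
        A = _activities(raw)
        B = _activities(np.exp(raw))
        rho_a, _ = activity_spearman(A)
        rho_b, _ = activity_spearman(B)
        pd.testing.assert_frame_equal(rho_a, rho_b)

    def test_constant_vector_is_recorded_missing_and_unclustered(self):
        rng = np.random.default_rng(3)
        A = _activities([np.ones(12), rng.normal(size=12), rng.normal(size=12)])
        rho, p = activity_spearman(A)
        assert np.isnan(rho.loc["c0", "c1"])
        graph = build_stimulon_graph(rho, p)
        assert "c0" not in [n for cl in graph.clusters for n in cl]

    def test_too_few_samples_rejected(self):
        A = _activities(np.ones((2, 4)))
        with pytest.raises(ValueError):
            activity_spearman(A)


class TestGraph:
    def _matrices(self, rho_vals, p_val=1e-6):
        names = [f"c{i}" for i in range(len(rho_vals))]
        rho = pd.DataFrame(rho_vals, index=names, columns=names, dtype=float)
        p = pd.DataFrame(p_val, index=names, columns=names)
        return rho, p

    def test_subthreshold_correlations_give_no_clusters(self):
        rho, p = self._matrices([[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1]])
        graph = build_stimulon_graph(rho, p)
        assert graph.clusters == []

    def test_negative_correlation_is_an_edge_and_a_cluster(self):
        rho, p = self._matrices([[1, -0.86], [-0.86, 1]])
        graph = build_stimulon_graph(rho, p)
        assert len(graph.clusters) == 1 and graph.clusters[0] == frozenset({"c0", "c1"})
        assert graph.opposition_edges == [("c0", "c1", -0.86, 1e-6)]

    def test_insignificant_p_blocks_the_edge(self):
        rho, p = self._matrices([[1, 0.9], [0.9, 1]], p_val=0.5)
        assert build_stimulon_graph(rho, p).clusters == []

    def test_planted_blocks_become_exactly_three_clusters(self):
        blocks = (
            BlockSpec(components=(0, 1, 2), signs=(1, -1, 1)),
            BlockSpec(components=(3, 4, 5)),
            BlockSpec(components=(6, 7)),
        )
        design = SyntheticDesign(
            n_genes=300, n_components=10, n_conditions=50, n_batch_conditions=15,
            replicates_per_condition=2, replicate_noise_sd=0.5, blocks=blocks,
        )
        A, _ = generate_activities(design, seed=12)
        rho, p = activity_spearman(ActivityMatrix(A))
        graph = build_stimulon_graph(rho, p)
        planted = {frozenset(f"comp{c:02d}" for c in b.components) for b in blocks}
        assert set(graph.clusters) == planted

    def test_cluster_named_by_size_then_degree_then_id(self):
        rho, p = self._matrices(
            [
                [1.0, 0.9, 0.9, 0.0],
                [0.9, 1.0, 0.9, 0.0],
                [0.9, 0.9, 1.0, 0.9],
                [0.0, 0.0, 0.9, 1.0],
            ]
        )
        # sizes: c2 biggest → wins; with equal sizes c2 has top degree;
        # with everything equal the lexicographically first id wins
        g_size = build_stimulon_graph(rho, p, member_sizes={"c0": 5, "c1": 5, "c2": 9, "c3": 1})
        assert g_size.names[0] == "c2"
        g_degree = build_stimulon_graph(rho, p, member_sizes={n: 3 for n in rho.index})
        assert g_degree.names[0] == "c2"  # degree 3 vs 2,2,1
        rho2, p2 = self._matrices([[1, 0.9], [0.9, 1]])
        g_lex = build_stimulon_graph(rho2, p2)
        assert g_lex.names[0] == "c0"

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(4)
        A = _activities(rng.normal(size=(6, 15)))
        rho, p = activity_spearman(A)
        edges = {
            thr: set(map(tuple, build_stimulon_graph(rho, p, rho_threshold=thr, p_cutoff=1.0).graph.edges()))
            for thr in (0.1, 0.3, 0.5, 0.7, 0.9)
        }
        thresholds = sorted(edges)
        for lo, hi in zip(thresholds, thresholds[1:]):
            assert edges[hi] <= edges[lo]

    def test_hierarchical_variant_recovers_clean_blocks(self):
        rho, p = self._matrices(
            [
                [1.0, 0.95, 0.1, 0.1],
                [0.95, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.9],
                [0.1, 0.1, 0.9, 1.0],
            ]
        )
        graph = build_stimulon_graph(rho, p, method="hierarchy")
        assert set(graph.clusters) == {frozenset({"c0", "c1"}), frozenset({"c2", "c3"})}


class TestSumSuffixed:
    def test_suffixed_rows_are_summed_and_renamed(self):
        A = _activities([[1, 2], [3, 4]], names=["Crp-1", "Crp-2"])
        merged = sum_suffixed(A, ["Crp"])
        np.testing.assert_allclose(merged.values.loc["Crp*"], [4.0, 6.0])
        assert list(merged.values.index) == ["Crp*"]

    def test_single_match_is_just_renamed(self):
        A = _activities([[1, 2], [9, 9]], names=["GadXW-1", "RpoS"])
        merged = sum_suffixed(A, ["GadXW"])
        np.testing.assert_allclose(merged.values.loc["GadXW*"], [1.0, 2.0])
        assert "RpoS" in merged.values.index

    def test_unmatched_base_rejected(self):
        A = _activities([[1, 2]], names=["RpoS"])
        with pytest.raises(ValueError, match="Fur"):
            sum_suffixed(A, ["Fur"])

    def test_merging_does_not_weaken_shared_factor_correlation(self):
        rng = np.random.default_rng(7)
        wins = 0
        for _ in range(100):
            z = rng.normal(size=60)
            part1 = z + rng.normal(0, 1.0, 60)
            part2 = z + rng.normal(0, 1.0, 60)
            A = _activities([part1, part2], names=["F-1", "F-2"])
            merged = sum_suffixed(A, ["F"])
            rho_merged = abs(stats.spearmanr(merged.values.loc["F*"], z)[0])
            rho_parts = max(
                abs(stats.spearmanr(part1, z)[0]), abs(stats.spearmanr(part2, z)[0])
            )
            wins += rho_merged >= rho_parts
        assert wins >= 90
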