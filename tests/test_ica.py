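"""Robust ICA: restart recovery, clustering, orientation, membership."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stimulome import (
    RobustICA,
    SyntheticDesign,
    center_to_reference,
    cluster_components,
    compute_activities,
    orient_component,
    run_ica_restarts,
    simulate_dataset,
    synthesize_expression,
    threshold_membership,
)
from stimulome.ica import match_components


class TestRestarts:
    def test_noiseless_restarts_recover_planted_columns(self):
        design = SyntheticDesign(
            n_genes=600, n_components=5, n_conditions=8, n_batch_conditions=3,
            expression_noise_fraction=0.0,
        )
        X, truth = simulate_dataset(design, seed=21)
        restarts = run_ica_restarts(X, dimensionality=5, n_restarts=3, seed=21)
        for W in restarts:
            est = pd.DataFrame(W, index=X.gene_ids)
            matching = match_components(est, truth.source_weights)
            assert matching["abs_pearson"].min() >= 0.99

    def test_same_seed_is_deterministic(self, small_dataset):
        X, _ = small_dataset
        a = run_ica_restarts(X, 5, n_restarts=2, seed=33)
        b = run_ica_restarts(X, 5, n_restarts=2, seed=33)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa, wb)

    def test_excessive_dimensionality_rejected(self, small_dataset):
        X, _ = small_dataset
        with pytest.raises(ValueError):
            run_ica_restarts(X, dimensionality=X.shape[1] + 1, n_restarts=2, seed=1)


class TestClustering:
    def test_identical_restarts_give_full_occurrence(self, small_dataset):
        X, truth = small_dataset
        W = truth.source_weights.to_numpy()
        model = cluster_components([W.copy() for _ in range(4)], gene_ids=X.gene_ids)
        assert model.n_components == truth.n_components
        assert (model.occurrence_fraction == 1.0).all()

    def test_sign_flipped_restarts_still_cluster(self, small_dataset):
        X, truth = small_dataset
        W = truth.source_weights.to_numpy()
        model = cluster_components([W, -W, W, -W], gene_ids=X.gene_ids)
        assert model.n_components == truth.n_components

    def test_spurious_column_is_dropped(self, small_dataset):
        X, truth = small_dataset
        W = truth.source_weights.to_numpy()
        rng = np.random.default_rng(0)
        junk = rng.normal(size=(W.shape[0], 1))
        junk /= np.linalg.norm(junk)
        restarts = [W, W, W, np.column_stack([W, junk])]
        model = cluster_components(restarts, min_occurrence=0.5, gene_ids=X.gene_ids)
        assert model.n_components == truth.n_components

    def test_planted_components_recovered_across_many_restarts(self):
        design = SyntheticDesign(
            n_genes=1000, n_components=8, n_conditions=12, n_batch_conditions=4,
            expression_noise_fraction=0.02,
        )
        X, truth = simulate_dataset(design, seed=8)
        restarts = run_ica_restarts(X, dimensionality=8, n_restarts=20, seed=8)
        model = cluster_components(restarts, gene_ids=X.gene_ids)
        assert model.n_components == 8
        matching = match_components(model.weights, truth.source_weights)
        assert matching["abs_pearson"].min() >= 0.95


class TestOrientation:
    @pytest.mark.parametrize(
        "vec,expected",
        [((-5.0, 1.0, 0.0), (5.0, -1.0, 0.0)), ((5.0, -1.0, 0.0), (5.0, -1.0, 0.0))],
    )
    def test_largest_entry_made_positive(self, vec, expected):
        np.testing.assert_array_equal(orient_component(np.array(vec)), expected)

    @given(
        hnp.arrays(
            float,
            st.integers(3, 30),
            elements=st.floats(-100, 100, allow_nan=False),
        ).filter(lambda v: np.any(v))
    )
    def test_orientation_kills_sign_indeterminacy(self, v):
        np.testing.assert_array_equal(orient_component(v), orient_component(-v))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            orient_component(np.zeros(5))


class TestMembership:
    def test_planted_outliers_are_exactly_the_members(self):
        rng = np.random.default_rng(1)
        w = rng.normal(0, 1, 1020)
        w[:20] = 10.0 * rng.choice([-1, 1], 20)
        weights = pd.Series(w, index=[f"g{i}" for i in range(1020)])
        members = threshold_membership(weights)
        assert members == frozenset(f"g{i}" for i in range(20))

    def test_pure_noise_yields_almost_no_members(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            weights = pd.Series(rng.normal(size=2000))
            weights.index = [f"g{i}" for i in range(2000)]
            assert len(threshold_membership(weights)) <= 20  # ≤1% of genes

    def test_members_are_a_prefix_of_the_abs_weight_ranking(self):
        rng = np.random.default_rng(3)
        w = rng.standard_t(df=3, size=500)
        weights = pd.Series(w, index=[f"g{i}" for i in range(500)])
        members = threshold_membership(weights)
        ranked = weights.abs().sort_values(ascending=False).index
        assert set(ranked[: len(members)]) == set(members)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            threshold_membership(pd.Series(np.ones(10)))


class TestActivities:
    def test_noiseless_activities_recovered_exactly(self, small_dataset):
        _, truth = small_dataset
        X0 = synthesize_expression(truth, noise_sd=0.0, seed=1)
        from stimulome.ica import ComponentModel

        model = ComponentModel(
            weights=truth.source_weights,
            member_sets={c: frozenset() for c in truth.source_weights.columns},
            occurrence_fraction=pd.Series(1.0, index=truth.source_weights.columns),
            dimensionality=truth.n_components,
            n_restarts=1,
        )
        A = compute_activities(X0, model)
        np.testing.assert_allclose(
            A.values.to_numpy(), truth.activity_profile.to_numpy(), atol=1e-8
        )

    def test_orthogonal_expression_gives_zero_activities(self, small_dataset):
        X, truth = small_dataset
        from stimulome.ica import ComponentModel
        from stimulome.expression import ExpressionMatrix

        S = truth.source_weights.to_numpy()
        # project X onto the orthogonal complement of span(S)
        proj = np.eye(S.shape[0]) - S @ np.linalg.pinv(S)
        Xo = ExpressionMatrix(
            pd.DataFrame(
                proj @ X.values.to_numpy(), index=X.gene_ids, columns=X.sample_ids
            ),
            X.metadata,
        )
        model = ComponentModel(
            weights=truth.source_weights,
            member_sets={c: frozenset() for c in truth.source_weights.columns},
            occurrence_fraction=pd.Series(1.0, index=truth.source_weights.columns),
            dimensionality=truth.n_components,
            n_restarts=1,
        )
        A = compute_activities(Xo, model)
        np.testing.assert_allclose(A.values.to_numpy(), 0.0, atol=1e-8)

    def test_rank_deficient_weights_rejected(self, small_dataset):
        X, truth = small_dataset
        from stimulome.ica import ComponentModel

        W = truth.source_weights.copy()
        W.iloc[:, 1] = W.iloc[:, 0]  # duplicate column
        model = ComponentModel(
            weights=W,
            member_sets={c: frozenset() for c in W.columns},
            occurrence_fraction=pd.Series(1.0, index=W.columns),
            dimensionality=truth.n_components,
            n_restarts=1,
        )
        with pytest.raises(np.linalg.LinAlgError):
            compute_activities(X, model)


class TestEndToEnd:
    def test_full_fit_recovers_planted_structure(self, fitted_small, small_dataset):
        _, truth, results = fitted_small
        assert results.components.n_components == truth.n_components
        matching = match_components(results.components.weights, truth.source_weights)
        assert matching["abs_pearson"].min() >= 0.9
        for i, name in enumerate(truth.source_weights.columns):
            planted = truth.member_sets[i]
            got = results.components.member_sets[matching.loc[name, "matched"]]
            jaccard = len(planted & got) / len(planted | got)
            assert jaccard >= 0.8

    def test_gene_shuffling_leaves_member_sets_invariant(self, small_dataset):
        from stimulome.expression import ExpressionMatrix

        X, truth = small_dataset
        rng = np.random.default_rng(5)
        order = rng.permutation(X.shape[0])
        Xs = ExpressionMatrix(X.values.iloc[order], X.metadata)
        res_orig = RobustICA(X, dimensionality=truth.n_components, n_restarts=4).fit(3)
        res_shuf = RobustICA(Xs, dimensionality=truth.n_components, n_restarts=4).fit(3)
        sets_orig = {frozenset(s) for s in res_orig.components.member_sets.values()}
        sets_shuf = {frozenset(s) for s in res_shuf.components.member_sets.values()}
        assert sets_orig == sets_shuf

    def test_refit_with_same_seed_reproduces_results(self, fitted_small):
        Xc, truth, results = fitted_small
        again = RobustICA(Xc, dimensionality=truth.n_components, n_restarts=6).fit(11)
        pd.testing.assert_frame_equal(results.components.weights, again.components.weights)
        pd.testing.assert_frame_equal(results.activities.values, again.activities.values)

    def test_summary_mentions_each_component(self, fitted_small):
        _, _, results = fitted_small
        text = results.summary()
        for name in results.components.names:
            assert name in text

    def test_activity_plot_renders(self, fitted_small):
        _, _, results = fitted_small
        ax = results.plot_activities(results.components.names[:2])
        assert len(ax.lines) == 2
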