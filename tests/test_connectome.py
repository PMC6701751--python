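"""Connectome decoding: matrices, edge selection, stability filtering,
cross-validation, permutation machinery, consensus models."""

import numpy as np
import pytest
from scipy import stats

from neurotraits.connectome import (CONSENSUS_WEIGHTS, EdgeSelection,
                                    apply_model, community_edge_summary,
                                    connectivity_from_timeseries,
                                    consensus_weights, crossval_predict,
                                    edge_sum_score, fold_assignment,
                                    loo_stability_filter, motion_edge_filter,
                                    neurotrait_overlap, permutation_test,
                                    select_edges_robust, truncate_volumes)
from neurotraits.robust import edgewise_regression
from neurotraits.simulate import (CohortConfig, generate_connectivity,
                                  generate_questionnaires)


# ---------------------------------------------------------------------------
# Matrices


class TestMatrices:
    def test_truncate_1110_volumes_leaves_990(self, rng):
        ts = rng.normal(size=(1110, 5))
        out = truncate_volumes(ts, 120)
        assert out.shape == (990, 5)
        assert np.array_equal(out, ts[120:])

    def test_truncate_zero_is_identity(self, rng):
        ts = rng.normal(size=(10, 2))
        assert np.array_equal(truncate_volumes(ts, 0), ts)

    def test_truncate_everything_is_error(self, rng):
        with pytest.raises(ValueError):
            truncate_volumes(rng.normal(size=(120, 2)), 120)

    def test_fisher_z_closed_form(self, rng):
        """r = 0.5 maps to z = arctanh(0.5) = 0.5*ln(3) = 0.549306..."""
        t = np.linspace(0, 8 * np.pi, 4000)
        a = np.sin(t) + rng.normal(size=t.size)
        # construct exact r=0.5 via orthogonalization
        b0 = rng.normal(size=t.size)
        b0 -= np.polyval(np.polyfit(a, b0, 1), a)
        a_z = (a - a.mean()) / a.std()
        b_z = (b0 - b0.mean()) / b0.std()
        y = 0.5 * a_z + np.sqrt(1 - 0.25) * b_z
        cm = connectivity_from_timeseries(np.column_stack([a_z, y]))
        assert cm.values[0, 1] == pytest.approx(0.5 * np.log(3), abs=1e-12)

    def test_identical_columns_clipped_and_flagged(self, rng):
        x = rng.normal(size=100)
        cm = connectivity_from_timeseries(np.column_stack([x, x, rng.normal(size=100)]))
        assert (0, 1) in cm.clipped_edges
        assert cm.values[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))
        assert np.isfinite(cm.values).all()

    def test_constant_column_flags_missing_edges(self, rng):
        ts = np.column_stack([np.ones(50), rng.normal(size=(50, 2))])
        cm = connectivity_from_timeseries(ts)
        assert (0, 1) in cm.missing_edges and (0, 2) in cm.missing_edges
        assert np.isnan(cm.values[0, 1])

    def test_symmetric_zero_diagonal(self, rng):
        cm = connectivity_from_timeseries(rng.normal(size=(60, 6)))
        assert np.allclose(cm.values, cm.values.T)
        assert np.all(np.diag(cm.values) == 0)


# ---------------------------------------------------------------------------
# Robust edge-wise regression


class TestEdgewiseRegression:
    def test_agrees_with_statsmodels_rlm(self, rng):
        """The IRLS kernel reproduces statsmodels RLM (bisquare, MAD scale,
        H1 covariance) slope and standard error on outlier-laden data."""
        import statsmodels.api as sm

        n, E = 37, 60
        x = rng.normal(size=n)
        Y = rng.normal(size=(n, E)) + np.outer(x, rng.normal(size=E) * 0.4)
        Y[2, :20] += 6  # leverage outliers
        # tight convergence for the oracle comparison (the default trades
        # the last digits for speed)
        slope, p, ok = edgewise_regression(x, Y, method="bisquare", tol=1e-9)
        X = sm.add_constant(x)
        for e in range(0, E, 7):
            r = sm.RLM(Y[:, e], X, M=sm.robust.norms.TukeyBiweight()).fit()
            assert slope[e] == pytest.approx(r.params[1], abs=1e-6)
            t_sm = r.params[1] / r.bse[1]
            p_sm = 2 * stats.t.sf(abs(t_sm), n - 2)
            assert p[e] == pytest.approx(p_sm, abs=1e-6)

    def test_ols_matches_pearson_t_test(self, rng):
        n = 30
        x = rng.normal(size=n)
        Y = rng.normal(size=(n, 5))
        slope, p, ok = edgewise_regression(x, Y, method="ols")
        for e in range(5):
            r, p_ref = stats.pearsonr(x, Y[:, e])
            assert p[e] == pytest.approx(p_ref, rel=1e-9)

    def test_constant_trait_is_error(self, rng):
        with pytest.raises(ValueError, match="constant"):
            edgewise_regression(np.ones(20), rng.normal(size=(20, 3)))

    def test_zero_variance_edge_skipped(self, rng):
        Y = rng.normal(size=(20, 3))
        Y[:, 1] = 5.0
        _, p, ok = edgewise_regression(rng.normal(size=20), Y, method="bisquare")
        assert not ok[1] and np.isnan(p[1])
        assert ok[0] and ok[2]


# ---------------------------------------------------------------------------
# Selection and stability


class TestSelection:
    def test_null_selection_rate_near_alpha(self):
        cfg = CohortConfig(n_nodes=60, edge_effect=0.0, n_sessions=1, seed=17)
        _, F = generate_questionnaires(cfg)
        conn, _ = generate_connectivity(cfg, F)
        sel = select_edges_robust(conn.session(0), F[:, 0], alpha=0.05)
        frac = sel.n_selected / conn.session(0).shape[1]
        assert 0.03 < frac < 0.075

    def test_planted_strong_edge_always_selected(self):
        cfg = CohortConfig(n_nodes=30, edge_effect=0.6, n_sessions=1,
                           planted_edges_per_trait=5, seed=23)
        _, F = generate_questionnaires(cfg)
        conn, planted = generate_connectivity(cfg, F)
        sel = select_edges_robust(conn.session(0), F[:, 0], alpha=0.05)
        assert np.isin(planted.positive[0], sel.positive).all()
        assert np.isin(planted.negative[0], sel.negative).all()

    def test_positive_negative_sets_disjoint(self, small_cohort):
        Y = small_cohort.connectivity.session(0)
        sel = select_edges_robust(Y, small_cohort.true_factor_scores[:, 0])
        assert np.intersect1d(sel.positive, sel.negative).size == 0

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            select_edges_robust(rng.normal(size=(5, 10)), rng.normal(size=5))

    def test_constant_trait_error(self, small_cohort):
        with pytest.raises(ValueError):
            select_edges_robust(small_cohort.connectivity.session(0),
                                np.ones(small_cohort.config.n_subjects))


class TestLooStability:
    def test_output_subset_of_full_selection(self, small_cohort):
        Y = small_cohort.connectivity.session(0)
        x = small_cohort.true_factor_scores[:, 0]
        full = select_edges_robust(Y, x)
        stable = loo_stability_filter(Y, x, selection=full)
        assert np.isin(stable.positive, full.positive).all()
        assert np.isin(stable.negative, full.negative).all()
        assert stable.n_selected <= full.n_selected

    def test_outlier_driven_edge_excluded(self, rng):
        """An edge whose association exists only through one leverage
        subject fails the leave-one-out filter."""
        n = 20
        x = np.concatenate([rng.normal(size=n - 1), [6.0]])
        edge = 0.02 * rng.normal(size=n)
        edge[-1] = 0.9  # single point drives the slope
        Y = np.column_stack([edge, x * 0.5 + 0.05 * rng.normal(size=n)])
        full = select_edges_robust(Y, x, alpha=0.05, method="ols")
        stable = loo_stability_filter(Y, x, alpha=0.05, method="ols",
                                      selection=full)
        assert 0 not in set(stable.positive) | set(stable.negative)
        assert 1 in stable.positive  # genuine edge survives

    def test_bisquare_and_ols_paths_agree_on_clean_signal(self, small_cohort):
        Y = small_cohort.connectivity.session(0)
        x = small_cohort.true_factor_scores[:, 0]
        planted = small_cohort.planted_edges
        sb = loo_stability_filter(Y, x, method="bisquare")
        so = loo_stability_filter(Y, x, method="ols")
        for s in (sb, so):
            # the filter is strict (40 refits must all pass), so allow one
            # marginal planted edge to drop out
            assert np.isin(planted.positive[0], s.positive).sum() >= 4


# ---------------------------------------------------------------------------
# Scoring and consensus


class TestEdgeSum:
    def test_matches_brute_force_loop(self, rng):
        """Oracle equivalence on random 10-node matrices: the vectorized sum
        equals an explicit loop over listed pairs, exactly."""
        P = 10
        iu, ju = np.triu_indices(P, 1)
        for _ in range(20):
            M = rng.normal(size=(P, P))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            v = M[iu, ju]
            edges = rng.choice(len(v), size=rng.integers(0, 20), replace=False)
            w = rng.uniform(0.1, 1, size=len(edges))
            import math

            brute = math.fsum(we * M[iu[e], ju[e]] for e, we in zip(edges, w))
            assert edge_sum_score(v, edges, w) == brute

    def test_empty_edge_set_scores_zero(self):
        assert edge_sum_score(np.arange(10.0), []) == 0.0

    def test_uniform_sum(self):
        assert edge_sum_score(np.array([0.1, 0.2, 0.3]), [0, 1, 2]) == pytest.approx(0.6)

    def test_consensus_weight_dot_product(self):
        z = np.ones(3)
        w = [1.0, 0.66, 0.33]
        assert edge_sum_score(z, [0, 1, 2], w) == pytest.approx(1.99)

    def test_unknown_edge_raises(self):
        with pytest.raises(KeyError):
            edge_sum_score(np.arange(3.0), [7])


class TestConsensus:
    def _sel(self, pos, neg=()):
        return EdgeSelection(np.array(sorted(pos), int), np.array(sorted(neg), int))

    def test_weight_table(self):
        folds = [self._sel({1, 2, 3}), self._sel({1, 2}), self._sel({1, 9})]
        model = consensus_weights(folds, "positive", n_nodes=10)
        assert model.weights[1] == 1.0
        assert model.weights[2] == 0.66
        assert model.weights[3] == 0.33
        assert model.weights[9] == 0.33
        assert 5 not in model.weights
        assert list(model.most_stable) == [1]

    def test_weights_only_from_fixed_table(self):
        folds = [self._sel({k for k in range(10)}), self._sel({0, 1}),
                 self._sel({0})]
        model = consensus_weights(folds, "positive", n_nodes=10)
        assert set(model.weights.values()) <= set(CONSENSUS_WEIGHTS.values())

    def test_sign_conflict_excluded(self):
        folds = [self._sel({1, 2}), self._sel({2}, neg={1}), self._sel({2})]
        model = consensus_weights(folds, "positive", n_nodes=10)
        assert 1 not in model.weights
        assert model.weights[2] == 1.0

    def test_requires_three_folds(self):
        with pytest.raises(ValueError):
            consensus_weights([self._sel({1})], "positive")


class TestOverlapAndCommunities:
    def _model(self, edges, n_nodes=272):
        from neurotraits.connectome import NeurotraitModel

        return NeurotraitModel("t", "positive", {int(e): 1.0 for e in edges},
                               n_nodes)

    def test_identical_models_full_overlap(self):
        m = self._model(range(100))
        ov = neurotrait_overlap(m, m)
        assert ov["fraction_of_a"] == 1.0 and ov["jaccard"] == 1.0

    def test_disjoint_models_zero_overlap(self):
        ov = neurotrait_overlap(self._model(range(50)),
                                self._model(range(50, 80)))
        assert ov["n_shared"] == 0 and ov["fraction_of_a"] == 0.0

    def test_reported_ratio_convention(self):
        """108 shared out of 1326 is 8.1% of the first network's edges."""
        a = self._model(range(1326))
        b = self._model(list(range(108)) + list(range(5000, 5892)))
        ov = neurotrait_overlap(a, b)
        assert ov["n_shared"] == 108
        assert ov["fraction_of_a"] == pytest.approx(108 / 1326)
        assert round(100 * ov["fraction_of_a"], 1) == 8.1

    def test_community_counts_hand_example(self):
        # 4 nodes, communities [A, A, B, B]; edges (0,1) within-A, (0,2) A-B
        P = 4
        iu, ju = np.triu_indices(P, 1)
        pairs = list(zip(iu, ju))
        e01 = pairs.index((0, 1))
        e02 = pairs.index((0, 2))
        m = self._model([e01, e02], n_nodes=P)
        M = community_edge_summary(m, np.array([0, 0, 1, 1])).values
        assert M[0, 0] == 1 and M[0, 1] == 1 and M[1, 1] == 0

    def test_count_conservation(self, small_cohort):
        Y = small_cohort.connectivity.session(0)
        x = small_cohort.true_factor_scores[:, 0]
        res = crossval_predict(Y, x, k=3, seed=0, method="ols")
        model = consensus_weights(res.fold_selections, "positive",
                                  n_nodes=small_cohort.config.n_nodes)
        comm = small_cohort.nodes["community"].values
        M = community_edge_summary(model, comm).values
        assert np.allclose(M, M.T)
        assert np.triu(M).sum() == model.n_edges

    def test_unlabeled_node_error(self):
        m = self._model([0], n_nodes=4)
        with pytest.raises(ValueError):
            community_edge_summary(m, np.array([0, -1, 1, 1]))


# ---------------------------------------------------------------------------
# Cross-validation


class TestCrossval:
    def test_fold_assignment_balanced_and_deterministic(self):
        f1 = fold_assignment(62, 3, seed=4)
        f2 = fold_assignment(62, 3, seed=4)
        assert np.array_equal(f1, f2)
        sizes = np.bincount(f1)
        assert sizes.max() - sizes.min() <= 1
        assert not np.array_equal(f1, fold_assignment(62, 3, seed=5))

    def test_every_subject_in_exactly_one_test_fold(self, small_cohort):
        Y = small_cohort.connectivity.session(0)
        x = small_cohort.true_factor_scores[:, 0]
        res = crossval_predict(Y, x, k=3, seed=0, method="ols")
        assert np.bincount(res.folds).sum() == len(x)
        assert res.available["positive"].all()

    def test_planted_signal_predicts_heldout(self, small_cohort):
        Y = small_cohort.connectivity.session(0)
        x = small_cohort.true_factor_scores[:, 0]
        res = crossval_predict(Y, x, k=3, seed=0, method="bisquare")
        assert res.r2["positive"] > 0.1
        assert res.r2["negative"] > 0.1

    def test_subject_order_invariance_given_folds(self, small_cohort, rng):
        Y = small_cohort.connectivity.session(0)
        x = small_cohort.true_factor_scores[:, 0]
        folds = fold_assignment(len(x), 3, seed=0)
        res1 = crossval_predict(Y, x, folds=folds, method="ols")
        perm = rng.permutation(len(x))
        res2 = crossval_predict(Y[perm], x[perm], folds=folds[perm], method="ols")
        assert res1.r2["positive"] == pytest.approx(res2.r2["positive"], rel=1e-10)
        assert np.allclose(res1.predicted["positive"][perm],
                           res2.predicted["positive"], equal_nan=True)

    def test_shuffled_traits_kill_prediction(self, small_cohort, rng):
        Y = small_cohort.connectivity.session(0)
        x = rng.permutation(small_cohort.true_factor_scores[:, 0])
        res = crossval_predict(Y, x, k=3, seed=0, method="ols")
        assert res.r2["positive"] < 0.15

    def test_fold_selections_disjoint_signs(self, small_cohort):
        Y = small_cohort.connectivity.session(0)
        x = small_cohort.true_factor_scores[:, 0]
        res = crossval_predict(Y, x, k=3, seed=0, method="ols")
        for sel in res.fold_selections:
            assert np.intersect1d(sel.positive, sel.negative).size == 0

    def test_k_bounds(self, rng):
        with pytest.raises(ValueError):
            fold_assignment(8, 3, 0)  # n < 3k
        with pytest.raises(ValueError):
            fold_assignment(10, 1, 0)


class TestPermutation:
    def test_minimum_p_formula(self, small_cohort):
        """With n_perm = 999 and an observed statistic beating every
        permutation, p = 1/1000 by the add-one rule."""
        exceed = 0
        p = (1 + exceed) / (999 + 1)
        assert p == 1 / 1000
        # and the machinery reproduces the rule on a strong planted signal
        Y = small_cohort.connectivity.session(0)
        x = small_cohort.true_factor_scores[:, 0]
        res = crossval_predict(Y, x, k=3, seed=0, method="ols")
        pvals = permutation_test(Y, x, observed=res, n_perm=199, seed=0,
                                 method="ols", mode="full")
        assert pvals["positive"] == pytest.approx(1 / 200)

    def test_nperm_lower_bound_enforced(self, small_cohort):
        Y = small_cohort.connectivity.session(0)
        x = small_cohort.true_factor_scores[:, 0]
        with pytest.raises(ValueError):
            permutation_test(Y, x, n_perm=50)

    def test_score_mode_null_signal_large_p(self, small_cohort, rng):
        Y = small_cohort.connectivity.session(0)
        x = rng.permutation(small_cohort.true_factor_scores[:, 0])
        res = crossval_predict(Y, x, k=3, seed=0, method="ols")
        pvals = permutation_test(Y, x, observed=res, n_perm=199, seed=1,
                                 method="ols", mode="score")
        assert pvals["positive"] > 0.05


# ---------------------------------------------------------------------------
# Model application and motion


class TestApplyModel:
    def test_same_session_scores_reproduce(self, small_cohort):
        Y = small_cohort.connectivity.session(0)
        x = small_cohort.true_factor_scores[:, 0]
        res = crossval_predict(Y, x, k=3, seed=0, method="ols")
        model = consensus_weights(res.fold_selections, "positive",
                                  n_nodes=small_cohort.config.n_nodes)
        s1 = apply_model(model, Y)
        s2 = apply_model(model, Y)
        assert np.array_equal(s1, s2)
        assert np.corrcoef(s1, x)[0, 1] > 0.5

    def test_empty_model_zero_scores(self, small_cohort):
        from neurotraits.connectome import NeurotraitModel

        model = NeurotraitModel("t", "positive", {}, small_cohort.config.n_nodes)
        s = apply_model(model, small_cohort.connectivity.session(0))
        assert np.all(s == 0)

    def test_repeat_session_reliability_matches_generator_icc(self):
        """Scores from repeat sessions of an icc=0.87 generator are
        correspondingly reliable."""
        from neurotraits.reliability import icc_two_way_random

        cfg = CohortConfig(n_subjects=56, n_nodes=40, session_icc=0.87,
                           planted_edges_per_trait=8, edge_effect=0.5, seed=31)
        _, F = generate_questionnaires(cfg)
        conn, planted = generate_connectivity(cfg, F)
        from neurotraits.connectome import NeurotraitModel

        model = NeurotraitModel(
            "t", "positive", {int(e): 1.0 for e in planted.positive[0]},
            cfg.n_nodes)
        scores = np.column_stack(
            [apply_model(model, conn.session(s)) for s in range(4)]
        )
        icc = icc_two_way_random(scores, form="single_absolute")
        # planted trait signal adds between-subject variance on top of the
        # noise random intercept, so the score ICC is at least session_icc
        assert icc.icc > 0.8


class TestMotionControls:
    def test_motion_correlated_edge_removed(self, rng):
        n = 60
        fd = rng.normal(0.11, 0.05, size=n)
        Y = rng.normal(size=(n, 10))
        Y[:, 4] = 3 * fd + 0.1 * rng.normal(size=n)  # r ~ 0.9 with motion
        keep = motion_edge_filter(Y, fd, alpha=0.05)
        assert not keep[4]
        assert keep.sum() >= 7

    def test_missing_motion_error(self, rng):
        fd = np.array([0.1, np.nan, 0.2, 0.15])
        with pytest.raises(ValueError):
            motion_edge_filter(rng.normal(size=(4, 3)), fd)

    def test_orthogonal_covariate_leaves_correlation(self, rng):
        from neurotraits.connectome import motion_partial_scores
        from neurotraits.associations import correlate

        n = 200
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        fd = rng.normal(size=n)  # independent of both
        r_partial, _ = motion_partial_scores(y, x, fd)
        r_plain = correlate(y, x).r
        assert r_partial == pytest.approx(r_plain, abs=0.02)
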