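"""The l1-l2 solver, the ridge refit, and the nested LOO selection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hyposig.io import log2_transform, normalize_chain
from hyposig.l1l2 import (
    ConvergenceError,
    L1L2Config,
    LabeledDataset,
    SelectionFrequencyTable,
    debias_rls,
    frequency_signature,
    ista_path,
    l1l2_objective,
    l1l2_solve,
    outer_loo_selection,
    select_tau_loocv,
    soft_threshold,
    tau_grid_for,
)
from hyposig.simulate import CellLineSimConfig, simulate_cell_line_pairs


class TestSoftThreshold:
    @pytest.mark.parametrize("z,lam,expected", [(3, 1, 2), (-0.5, 1, 0), (-3, 1, -2), (0, 0, 0)])
    def test_known_values(self, z, lam, expected):
        assert soft_threshold(z, lam) == expected

    @given(st.floats(-100, 100, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_zero_threshold_is_identity(self, z):
        assert soft_threshold(z, 0.0) == z

    @given(st.floats(-10, 10), st.floats(0, 10))
    @settings(derandomize=True, max_examples=100)
    def test_shrinks_toward_zero_and_preserves_sign(self, z, lam):
        out = soft_threshold(z, lam)
        assert abs(out) <= abs(z)
        assert out == 0 or np.sign(out) == np.sign(z)


class TestSolver:
    def test_full_shrinkage_bound_gives_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (8, 5))
        y = rng.choice([-1.0, 1.0], 8)
        tau = 2 * np.max(np.abs(X.T @ y)) / 8
        beta = l1l2_solve(X, y, tau * 1.0001, mu=0.0)
        assert np.all(beta == 0)

    def test_orthonormal_design_closed_form(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(0, 1, (4, 4)))
        y = rng.normal(0, 1, 4)
        tau = 0.2
        beta = l1l2_solve(Q, y, tau, mu=0.0, tol=1e-12, max_iter=50000)
        # orthonormal X, mu=0: beta_j = soft(OLS_j, tau*n/2)
        expected = soft_threshold(Q.T @ y, tau * 4 / 2)
        np.testing.assert_allclose(beta, expected, atol=1e-9)

    def test_objective_decreases_every_iteration(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (10, 20))
        y = rng.choice([-1.0, 1.0], 10)
        _, objs = l1l2_solve(X, y, tau=0.05, mu=0.01, return_objectives=True)
        diffs = np.diff(objs)
        assert (diffs <= 1e-12).all()

    def test_convergence_error_carries_last_iterate(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (10, 20))
        y = rng.normal(0, 1, 10)
        with pytest.raises(ConvergenceError) as err:
            l1l2_solve(X, y, tau=1e-6, mu=0.0, tol=1e-14, max_iter=3)
        assert err.value.last_iterate.shape == (20,)

    def test_path_matches_single_solves(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (10, 30))
        y = rng.choice([-1.0, 1.0], 10)
        taus = tau_grid_for(X, y, L1L2Config(n_tau=6))
        betas, _ = ista_path(X, y, taus, mu=0.05, tol=1e-9, max_iter=50000)
        for ti, tau in enumerate(taus):
            ref = l1l2_solve(X, y, tau, mu=0.05, tol=1e-9, max_iter=50000)
            np.testing.assert_allclose(betas[ti], ref, atol=1e-6)


class TestDebias:
    def test_zero_ridge_equals_ols(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (10, 6))
        y = rng.normal(0, 1, 10)
        support = np.array([0, 2, 4])
        beta = debias_rls(X, y, support, ridge_lambda=0.0)
        expected = np.linalg.lstsq(X[:, support], y, rcond=None)[0]
        np.testing.assert_allclose(beta, expected, atol=1e-10)

    def test_large_ridge_shrinks_to_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (10, 4))
        y = rng.normal(0, 1, 10)
        beta = debias_rls(X, y, np.arange(4), ridge_lambda=1e9)
        assert np.max(np.abs(beta)) < 1e-6

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (8, 5))
        y = rng.normal(0, 1, 8)
        support = np.array([1, 2, 4])
        lam = 0.3
        beta = debias_rls(X, y, support, ridge_lambda=lam)
        Xs = X[:, support]
        expected = np.linalg.solve(Xs.T @ Xs / 8 + lam * np.eye(3), Xs.T @ y / 8)
        np.testing.assert_allclose(beta, expected, atol=1e-10)

    def test_wide_support_uses_consistent_dual_form(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (6, 20))
        y = rng.normal(0, 1, 6)
        lam = 0.2
        beta = debias_rls(X, y, np.arange(20), ridge_lambda=lam)
        # primal normal equations still hold: (X'X/n + lam I) b = X'y/n
        lhs = X.T @ X @ beta / 6 + lam * beta
        np.testing.assert_allclose(lhs, X.T @ y / 6, atol=1e-10)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            debias_rls(np.ones((4, 2)), np.ones(4), np.array([], dtype=int))


class TestTauSelection:
    def test_grid_of_length_one_returned_directly(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (8, 5))
        y = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        cfg = L1L2Config(tau_grid=np.array([0.42]))
        tau, _ = select_tau_loocv(X, y, cfg)
        assert tau == 0.42

    def test_separable_planted_data_reaches_zero_inner_error(self):
        E, d, _ = simulate_cell_line_pairs(
            CellLineSimConfig(n_lines=8, n_probesets=300, n_responsive=30, seed=4)
        )
        D = LabeledDataset.from_expression(log2_transform(normalize_chain(E)), d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, curve = select_tau_loocv(D.X, D.y, L1L2Config(n_tau=15))
        assert curve.min() == 0.0

    def test_permuted_labels_give_chance_level_error(self):
        """Null data: the minimized inner-LOO error sits below 0.5 by the
        selection over the grid but well above the planted-signal regime
        (band frozen from a 20-permutation oracle run: mean 0.36, sd 0.16)."""
        E, d, _ = simulate_cell_line_pairs(
            CellLineSimConfig(n_lines=8, n_probesets=200, n_responsive=20, seed=3)
        )
        D = LabeledDataset.from_expression(log2_transform(normalize_chain(E)), d)
        rng = np.random.default_rng(7)
        cfg = L1L2Config(n_tau=15)
        errs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(20):
                y = rng.permutation(D.y)
                _, curve = select_tau_loocv(D.X, y, cfg)
                errs.append(curve.min())
        assert 0.25 <= np.mean(errs) <= 0.55


class TestOuterLoop:
    def test_tiny_instance_perfect_feature_always_selected(self):
        # n=4, 2 features; feature 0 separates the classes exactly
        X = np.array([[1.0, 0.3], [0.9, -0.1], [-1.0, 0.2], [-1.1, 0.05]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        D = LabeledDataset(X, y, ["good", "noise"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            T = outer_loo_selection(D, L1L2Config(n_tau=10))
        counts = dict(zip(T.feature_ids, T.counts))
        assert counts["good"] == 4

    def test_duplicated_samples_give_identical_loop_lists(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (5, 40))
        X[:, 0] += np.array([2.0, 2, -2, -2, 2])
        y = np.array([1.0, 1, -1, -1, 1])
        Xd = np.repeat(X, 2, axis=0)
        yd = np.repeat(y, 2)
        D = LabeledDataset(Xd, yd, [f"f{i}" for i in range(40)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            T = outer_loo_selection(D, L1L2Config(n_tau=8))
        for i in range(0, 10, 2):
            assert T.per_loop[i] == T.per_loop[i + 1]

    def test_held_out_sample_never_leaks_into_selection(self):
        """Poisoning check: perturbing sample i cannot change loop i's list."""
        E, d, _ = simulate_cell_line_pairs(
            CellLineSimConfig(n_lines=6, n_probesets=100, n_responsive=10, seed=12)
        )
        D = LabeledDataset.from_expression(log2_transform(normalize_chain(E)), d)
        cfg = L1L2Config(n_tau=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            T1 = outer_loo_selection(D, cfg)
            for i in (0, 5):
                X2 = D.X.copy()
                X2[i] = X2[i] + np.random.default_rng(i).normal(0, 5, D.p)
                T2 = outer_loo_selection(LabeledDataset(X2, D.y, D.feature_ids), cfg)
                assert T1.per_loop[i] == T2.per_loop[i]

    def test_planted_recovery_and_loo_error(self, derivation_bundle, planted_cellline):
        _, _, truth = planted_cellline
        T = derivation_bundle.frequency_table
        assert T.L == 22
        half = {f for f, c in zip(T.feature_ids, T.counts) if c >= T.L / 2}
        recall = len(half & truth) / len(truth)
        assert recall >= 0.8
        assert T.loo_error <= 0.15

    def test_union_of_loops_equals_positive_counts(self, derivation_bundle):
        T = derivation_bundle.frequency_table
        union = {f for lst in T.per_loop for f in lst}
        assert union == {f for f, c in zip(T.feature_ids, T.counts) if c >= 1}


class TestFrequencySignature:
    def _table(self):
        return SelectionFrequencyTable(
            feature_ids=["a", "b", "c", "d"],
            counts=np.array([22, 11, 1, 0]),
            L=22,
            loo_error=0.1,
            per_loop=[["a", "b"]] * 11 + [["a"]] * 10 + [["a", "c"]],
        )

    def test_threshold_half_keeps_majority_features(self):
        sig = frequency_signature(self._table(), 0.5)
        assert sig.probesets == ["a", "b"]

    def test_tiny_threshold_gives_union(self):
        sig = frequency_signature(self._table(), 1e-9)
        assert set(sig.probesets) == {"a", "b", "c"}

    def test_threshold_one_keeps_only_always_selected(self):
        sig = frequency_signature(self._table(), 1.0)
        assert sig.probesets == ["a"]

    def test_empty_result_warns(self):
        T = SelectionFrequencyTable(["a"], np.array([1]), 22, 0.0, [["a"]])
        with pytest.warns(UserWarning, match="no features"):
            sig = frequency_signature(T, 0.5)
        assert len(sig) == 0


def test_signature_size_grows_with_epsilon():
    """Larger epsilon (heavier l2) admits more correlated features: the mean
    signature size over simulated datasets is non-decreasing in epsilon."""
    sizes = {1.0: [], 100.0: []}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(6):
            E, d, _ = simulate_cell_line_pairs(
                CellLineSimConfig(
                    n_lines=6, n_probesets=120, n_responsive=12,
                    effect_log2=0.8, noise_sd=0.8, seed=40_000 + s,
                )
            )
            D = LabeledDataset.from_expression(log2_transform(normalize_chain(E)), d)
            for eps in sizes:
                T = outer_loo_selection(D, L1L2Config(epsilon=eps, n_tau=12))
                sizes[eps].append(len(frequency_signature(T, 0.5)))
    assert np.mean(sizes[100.0]) >= np.mean(sizes[1.0])
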