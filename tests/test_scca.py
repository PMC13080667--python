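import numpy as np
import pytest
from scipy import linalg

from kinconn._solver import _tune_grid
from kinconn.scca import (
    DEFAULT_GRID,
    SCCAPenalties,
    extract_modes,
    fit_scca,
    permutation_test,
    repeated_cv,
    tune_penalties,
)


def classical_cca_r(X, Y):
    """Generalized-eigenvalue oracle for the top canonical correlation."""
    X = X - X.mean(0)
    Y = Y - Y.mean(0)
    n = len(X)
    Sxx, Syy = X.T @ X / (n - 1), Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    M = Sxy @ np.linalg.solve(Syy, Sxy.T)
    return float(np.sqrt(max(linalg.eigh(M, Sxx, eigvals_only=True))))


def _random_instance(seed, n=40, k=3, q=2):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k)) @ rng.standard_normal((k, k))
    Y = rng.standard_normal((n, q)) @ rng.standard_normal((q, q))
    Y[:, 0] += 0.5 * X[:, 0]
    return X, Y


class TestFitSCCA:
    def test_one_dimensional_views_reduce_to_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((30, 1))
        y = -0.4 * x + rng.standard_normal((30, 1))
        mode = fit_scca(x, y, SCCAPenalties(1.0, 1.0))
        expected = abs(np.corrcoef(x.ravel(), y.ravel())[0, 1])
        assert abs(mode.canonical_r) == pytest.approx(expected, abs=1e-10)

    def test_maximal_sparsity_gives_one_hot_weights(self):
        rng = np.random.default_rng(1)
        X, Y = rng.standard_normal((50, 6)), rng.standard_normal((50, 4))
        mode = fit_scca(X, Y, SCCAPenalties(0.0, 0.0))
        assert np.count_nonzero(mode.w_brain) == 1
        assert np.count_nonzero(mode.w_behavior) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_unpenalized_limit_matches_classical_cca(self, seed):
        X, Y = _random_instance(seed)
        mode = fit_scca(X, Y, SCCAPenalties(1.0, 1.0, ridge=1e-8),
                        tol=1e-10, max_iter=5000)
        assert abs(mode.canonical_r) == pytest.approx(
            classical_cca_r(X, Y), abs=1e-6)

    def test_canonical_r_is_pearson_of_variates(self):
        X, Y = _random_instance(7)
        mode = fit_scca(X, Y, SCCAPenalties(0.5, 0.5))
        r = np.corrcoef(mode.variate_brain, mode.variate_behavior)[0, 1]
        assert mode.canonical_r == pytest.approx(r, abs=1e-10)

    def test_sign_convention_and_unit_norm(self):
        X, Y = _random_instance(3)
        mode = fit_scca(X, Y, SCCAPenalties(0.8, 0.8))
        j = np.argmax(np.abs(mode.w_behavior))
        assert mode.w_behavior[j] > 0
        assert np.linalg.norm(mode.w_brain) == pytest.approx(1.0)
        assert np.linalg.norm(mode.w_behavior) == pytest.approx(1.0)

    def test_invariant_to_affine_column_rescaling(self):
        X, Y = _random_instance(4)
        mode1 = fit_scca(X, Y, SCCAPenalties(0.6, 0.6))
        X2 = X * np.array([3.0, 0.2, 11.0]) + np.array([5.0, -2.0, 0.7])
        mode2 = fit_scca(X2, Y, SCCAPenalties(0.6, 0.6))
        assert mode1.canonical_r == pytest.approx(mode2.canonical_r, abs=1e-8)

    def test_non_finite_input_rejected(self):
        X, Y = _random_instance(5)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_scca(X, Y, SCCAPenalties(1.0, 1.0))

    def test_penalties_validated(self):
        with pytest.raises(ValueError):
            SCCAPenalties(1.5, 0.5)
        with pytest.raises(ValueError):
            SCCAPenalties(0.5, 0.5, ridge=0.0)


class TestTuning:
    def test_grid_enumerates_121_pairs(self):
        X, Y = _random_instance(0, n=30)
        ids = np.arange(30) % 3
        _, _, _, mean_r = _tune_grid(X, Y, ids, 3, DEFAULT_GRID, 1e-3, 1e-5, 60)
        assert mean_r.shape == (11, 11)
        assert DEFAULT_GRID.size == 11
        assert np.all(np.isfinite(mean_r))

    def test_planted_pair_support_recovered(self):
        rng = np.random.default_rng(0)
        n = 150
        s = rng.standard_normal(n)
        X = rng.standard_normal((n, 4))
        Y = rng.standard_normal((n, 5))
        X[:, 2] = s + 0.35 * rng.standard_normal(n)
        Y[:, 3] = s + 0.35 * rng.standard_normal(n)
        pen = tune_penalties(X, Y, seed=1)
        mode = fit_scca(X, Y, pen)
        assert mode.w_brain[2] != 0
        assert mode.w_behavior[3] != 0
        assert np.argmax(np.abs(mode.w_brain)) == 2
        assert np.argmax(np.abs(mode.w_behavior)) == 3

    def test_deterministic_selection_for_fixed_seed(self):
        X, Y = _random_instance(6, n=45)
        assert tune_penalties(X, Y, seed=3) == tune_penalties(X, Y, seed=3)

    def test_small_folds_rejected(self):
        X, Y = _random_instance(0, n=8)
        with pytest.raises(ValueError, match="folds"):
            tune_penalties(X, Y, folds=3, seed=0)


class TestPermutation:
    def test_strong_signal_reaches_minimum_p(self):
        rng = np.random.default_rng(0)
        n = 60
        s = rng.standard_normal(n)
        X = np.column_stack([s + 0.05 * rng.standard_normal(n),
                             rng.standard_normal((n, 2))])
        Y = np.column_stack([s + 0.05 * rng.standard_normal(n),
                             rng.standard_normal((n, 2))])
        res = permutation_test(X, Y, permutations=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.exceeds_percentile

    def test_add_one_estimator_bookkeeping(self):
        X, Y = _random_instance(2, n=30)
        res = permutation_test(X, Y, permutations=49, seed=0)
        recomputed = (1 + np.sum(res.null_rs >= res.observed_r)) / 50
        assert res.p_value == pytest.approx(recomputed)
        assert res.threshold_95 == pytest.approx(np.percentile(res.null_rs, 95))

    def test_too_few_permutations_rejected(self):
        X, Y = _random_instance(0, n=30)
        with pytest.raises(ValueError, match="19"):
            permutation_test(X, Y, permutations=10, seed=0)

    def test_too_few_subjects_rejected(self):
        X, Y = _random_instance(0, n=5)
        with pytest.raises(ValueError, match="6 subjects"):
            permutation_test(X, Y, permutations=99, seed=0)


class TestExtractModes:
    def _two_factor_views(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
        X = np.column_stack([
            s1 + 0.4 * rng.standard_normal(n),
            s1 + 0.4 * rng.standard_normal(n),
            rng.standard_normal(n),
            s2 + 0.5 * rng.standard_normal(n),
            s2 + 0.5 * rng.standard_normal(n),
            rng.standard_normal(n)])
        Y = np.column_stack([
            s1 + 0.4 * rng.standard_normal(n),
            s1 + 0.5 * rng.standard_normal(n),
            rng.standard_normal(n),
            s2 + 0.6 * rng.standard_normal(n),
            s2 + 0.7 * rng.standard_normal(n)])
        return X, Y

    def test_two_planted_factors_found_with_matching_supports(self):
        X, Y = self._two_factor_views()
        modes = extract_modes(X, Y, max_modes=3, seed=1, permutations=99)
        sig = [m for m in modes if m.significant]
        assert len(sig) == 2
        # mode 1 ~ factor on Y cols (0,1); mode 2 ~ factor on Y cols (3,4)
        d1 = np.zeros(5); d1[:2] = 1 / np.sqrt(2)
        d2 = np.zeros(5); d2[3:] = 1 / np.sqrt(2)
        cos1 = abs(sig[0].w_behavior @ d1)
        cos2 = abs(sig[1].w_behavior @ d2)
        assert cos1 >= 0.9
        assert cos2 >= 0.9

    def test_max_modes_one_returns_single_mode(self):
        X, Y = self._two_factor_views(seed=2)
        modes = extract_modes(X, Y, max_modes=1, seed=0, permutations=49)
        assert len(modes) == 1
        assert modes[0].mode_index == 1

    def test_stops_after_first_nonsignificant(self):
        X, Y = _random_instance(9, n=60, k=4, q=4)  # no real structure
        modes = extract_modes(X, Y, max_modes=4, seed=0, permutations=99)
        flags = [m.significant for m in modes]
        assert not flags[-1]                      # stopped on a failure
        assert all(flags[:-1])                    # everything before it passed

    def test_invalid_max_modes_rejected(self):
        X, Y = _random_instance(0, n=30)
        with pytest.raises(ValueError, match="max_modes"):
            extract_modes(X, Y, max_modes=5, seed=0, permutations=49)


class TestRepeatedCV:
    def test_fold_count_bookkeeping(self):
        X, Y = _random_instance(0, n=45)
        rep = repeated_cv(X, Y, repeats=7, seed=0)
        assert rep.test_fold_rs.size == 3 * 7

    def test_noiseless_coupling_generalizes(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 3))
        Y = np.column_stack([X @ np.array([0.5, -0.2, 0.1]),
                             rng.standard_normal(60)])
        rep = repeated_cv(X, Y, repeats=10, seed=2)
        assert rep.median >= 0.95

    def test_null_views_do_not_generalize(self):
        rng = np.random.default_rng(3)
        X, Y = rng.standard_normal((100, 4)), rng.standard_normal((100, 5))
        rep = repeated_cv(X, Y, repeats=10, seed=4)
        assert rep.median <= 0.2

    def test_held_out_below_training(self, planted_views):
        X, Y = planted_views
        pen = tune_penalties(X, Y, seed=0)
        train_r = fit_scca(X, Y, pen).canonical_r
        rep = repeated_cv(X, Y, repeats=10, seed=0)
        assert rep.median <= train_r + 1e-9
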