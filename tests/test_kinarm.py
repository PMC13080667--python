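import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from kinconn.kinarm import (
    TASKS,
    compare_groups,
    mann_whitney_u,
    rank_biserial_from_u,
    spearman_screen,
    task_score_one_sided,
    yates_chi_square,
    z_task_score,
)

# Published case-control worked example: per-task U statistics and the
# printed rank-biserial effect sizes, for 24 controls vs 33 patients.
TABLE_U_R = {
    "VGR": (309, 0.22), "RVGR": (156, 0.61), "OH": (237, 0.40),
    "OHA": (232, 0.41), "TMA": (199, 0.50), "TMB": (228, 0.42),
    "PAL": (172, 0.57), "BOB": (376, 0.05), "APM": (326, 0.18),
}


class TestZTaskScore:
    @pytest.mark.parametrize("z, expected", [
        ([0, 0, 0], 0.0),
        ([3, 4], np.sqrt(12.5)),
        ([-1.7], 1.7),
    ])
    def test_rms_definition(self, z, expected):
        assert z_task_score(z) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            z_task_score([])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8),
           st.floats(0, 10))
    def test_scale_consistency(self, z, c):
        assert z_task_score([c * v for v in z]) == pytest.approx(
            c * z_task_score(z), abs=1e-9)


class TestTaskScore:
    def test_best_performance_is_zero(self):
        assert task_score_one_sided(0.0) == 0.0

    def test_monotone_in_impairment(self):
        scores = [task_score_one_sided(z) for z in (0.0, 0.5, 1.0, 2.5)]
        assert scores == sorted(scores)
        assert all(s >= 0 for s in scores)

    def test_two_sided_convention_reduces_to_abs(self):
        # quantile map of the two-sided tail onto the half-normal is |z|
        assert task_score_one_sided(1.5) == pytest.approx(1.5)
        assert task_score_one_sided(-1.5) == pytest.approx(1.5)


class TestMannWhitney:
    def test_exact_small_sample(self):
        # all 20 rank assignments enumerable; complete separation
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0
        assert p == pytest.approx(0.1)

    def test_u_symmetry_under_label_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(10), rng.standard_normal(14)
        u1, _ = mann_whitney_u(x, y)
        u2, _ = mann_whitney_u(y, x)
        assert u1 + u2 == pytest.approx(10 * 14)

    def test_complete_ties_give_half_u(self):
        x = np.arange(8.0)
        U, _ = mann_whitney_u(x, x)
        assert U == pytest.approx(8 * 8 / 2)


class TestRankBiserial:
    def test_reproduces_published_effect_sizes(self):
        # all nine tasks of the worked example at 2-dp rounding
        for task, (U, r_printed) in TABLE_U_R.items():
            r = rank_biserial_from_u(U, 24, 33)
            assert round(r, 2) == pytest.approx(r_printed), task

    def test_half_u_is_zero_effect(self):
        assert rank_biserial_from_u(6 * 7 / 2, 6, 7) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rank_biserial_from_u(43, 6, 7)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(1, 30), st.integers(1, 30), st.floats(0, 1))
    def test_bounded(self, n1, n2, frac):
        r = rank_biserial_from_u(frac * n1 * n2, n1, n2)
        assert -1.0 <= r <= 1.0


class TestYatesChiSquare:
    def _oracle(self, t):
        # independent hand formula: sum max(|O-E|-0.5, 0)^2 / E
        t = np.asarray(t, float)
        E = np.outer(t.sum(1), t.sum(0)) / t.sum()
        return float((np.maximum(np.abs(t - E) - 0.5, 0) ** 2 / E).sum())

    def test_sex_table(self):
        chi2, p = yates_chi_square([[18, 6], [16, 17]])
        assert round(chi2, 2) == pytest.approx(3.03)

    def test_handedness_table_clips_to_zero(self):
        chi2, _ = yates_chi_square([[2, 22], [3, 30]])
        assert chi2 == 0.0

    def test_observed_equals_expected(self):
        chi2, p = yates_chi_square([[10, 10], [10, 10]])
        assert chi2 == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_formula(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 40, (2, 2))
        chi2, _ = yates_chi_square(t)
        assert chi2 == pytest.approx(self._oracle(t), abs=1e-10)

    def test_transpose_invariance(self):
        t = [[18, 6], [16, 17]]
        assert yates_chi_square(t)[0] == pytest.approx(
            yates_chi_square(np.transpose(t))[0])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            yates_chi_square([[0, 0], [5, 7]])


class TestCompareGroups:
    def _behavior(self, x, y):
        df = pd.DataFrame(
            np.concatenate([np.tile(x[:, None], len(TASKS)),
                            np.tile(y[:, None], len(TASKS))]),
            columns=list(TASKS))
        df["group"] = ["control"] * len(x) + ["TLE"] * len(y)
        return df

    def test_skewed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(1.0, 20) ** 2  # heavily skewed
        y = rng.exponential(1.0, 25) ** 2
        assert stats.shapiro(x).pvalue < 0.05  # oracle confirms the gate input
        res = compare_groups(self._behavior(x, y))
        assert set(res["test_used"]) == {"mann_whitney"}

    def test_normal_data_routes_to_t_test(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(20), rng.standard_normal(25)
        assert stats.shapiro(x).pvalue >= 0.05
        assert stats.shapiro(y).pvalue >= 0.05
        res = compare_groups(self._behavior(x, y))
        assert set(res["test_used"]) == {"t_test"}

    def test_identical_groups_null_result(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(15)
        res = compare_groups(self._behavior(x, x.copy()))
        assert (res["p_value"] > 0.99).all()
        assert np.abs(res["effect_size_r"]).max() < 1e-12

    def test_small_group_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match=">= 3"):
            compare_groups(self._behavior(rng.standard_normal(2),
                                          rng.standard_normal(10)))


class TestSpearman:
    def _behavior_one_task(self, values):
        df = pd.DataFrame({t: values for t in TASKS})
        return df

    def test_monotone_pairs(self):
        b = self._behavior_one_task(np.array([1.0, 2, 3, 5, 9]))
        res = spearman_screen(b, np.array([2.0, 4, 5, 6, 20]))
        np.testing.assert_allclose(res["rho"], 1.0)
        res = spearman_screen(b, -np.array([2.0, 4, 5, 6, 20]))
        np.testing.assert_allclose(res["rho"], -1.0)

    def test_hand_computed_example(self):
        # ranks (1,2,3,4) vs (2,1,4,3): sum d^2 = 4, rho = 1 - 24/60 = 0.6
        b = self._behavior_one_task(np.array([1.0, 2, 3, 4]))
        res = spearman_screen(b, np.array([2.0, 1, 4, 3]))
        assert res["rho"].iloc[0] == pytest.approx(0.6)

    def test_constant_covariate_rejected(self):
        b = self._behavior_one_task(np.array([1.0, 2, 3, 4]))
        with pytest.raises(ValueError, match="constant"):
            spearman_screen(b, np.ones(4))
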