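import numpy as np
import pandas as pd
import pytest

from kinconn.features import residualize_features, vectorize_upper_triangle
from kinconn.interpret import (
    annotate_networks,
    compute_loadings,
    covariate_moderation,
    threshold_consistency,
    top_k_edges,
)
from kinconn.kinarm import TASKS
from kinconn.scca import SCCAPenalties, fit_scca
from kinconn.synthetic import CohortSpec, generate_cohort, make_parcellation


class _FakeMode:
    def __init__(self, brain, behavior):
        self.variate_brain = np.asarray(brain, dtype=float)
        self.variate_behavior = np.asarray(behavior, dtype=float)


def _tasks_frame(n, rng):
    return pd.DataFrame(rng.standard_normal((n, 9)), columns=list(TASKS))


class TestLoadings:
    def test_variate_equal_to_task_loads_one(self):
        rng = np.random.default_rng(0)
        tasks = _tasks_frame(30, rng)
        edges = rng.standard_normal((30, 6))
        mode = _FakeMode(edges[:, 0], tasks["PAL"])
        rep = compute_loadings(mode, tasks, edges)
        assert rep.task_loadings["PAL"] == pytest.approx(1.0)
        assert rep.edge_loadings[0] == pytest.approx(1.0)
        mode_neg = _FakeMode(edges[:, 0], -tasks["PAL"])
        rep_neg = compute_loadings(mode_neg, tasks, edges)
        assert rep_neg.task_loadings["PAL"] == pytest.approx(-1.0)

    def test_orthogonal_variate_loads_zero(self):
        rng = np.random.default_rng(1)
        tasks = _tasks_frame(20, rng)
        t = tasks["VGR"].to_numpy()
        v = rng.standard_normal(20)
        tc = t - t.mean()
        v -= v.mean()
        v -= (v @ tc) / (tc @ tc) * tc
        rep = compute_loadings(_FakeMode(v, v), tasks, rng.standard_normal((20, 3)))
        assert abs(rep.task_loadings["VGR"]) < 1e-10

    def test_zero_variance_edge_excluded_from_top_lists(self):
        rng = np.random.default_rng(2)
        tasks = _tasks_frame(15, rng)
        edges = rng.standard_normal((15, 6))
        edges[:, 4] = 2.5
        rep = compute_loadings(_FakeMode(edges[:, 0], tasks["OH"]), tasks, edges)
        assert np.isnan(rep.edge_loadings[4])
        listed = set(rep.top_positive["edge"]).union(rep.top_negative["edge"])
        assert 4 not in listed

    def test_residualized_converges_to_raw_when_no_covariate_effect(self):
        # with zero true confounding the OLS step still removes the three
        # chance-correlated covariate directions, perturbing loadings by
        # O(sqrt(3/n)); at large n the two computations agree
        spec = CohortSpec(n_subjects=1500, n_nodes=8, active_edges=6,
                          covariate_effect=0.0, seed=3)
        c = generate_cohort(spec)
        X = np.vstack([vectorize_upper_triangle(m) for m in c.connectivity])
        resid = residualize_features(X, c.covariates)
        v = c.truth.latent
        tasks = c.behavior[list(TASKS)]
        raw = compute_loadings(_FakeMode(v, v), tasks, X).edge_loadings
        res = compute_loadings(_FakeMode(v, v), tasks, resid).edge_loadings
        assert np.nanmax(np.abs(raw - res)) < 0.02


class TestTopK:
    def test_top_15_each_sign(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(-1, 1, 45)  # 10-node edge count
        pos, neg = top_k_edges(r, k=15)
        assert len(pos) == 15 and len(neg) == 15
        assert (pos["loading"] > 0).all() and (neg["loading"] < 0).all()
        assert list(pos["loading"]) == sorted(pos["loading"], reverse=True)
        assert list(neg["loading"]) == sorted(neg["loading"])

    def test_all_positive_leaves_negative_empty(self):
        r = np.abs(np.random.default_rng(1).uniform(0.1, 1, 15))
        pos, neg = top_k_edges(r, k=5)
        assert len(neg) == 0 and len(pos) == 5

    def test_k_larger_than_edge_count_returns_all(self):
        r = np.array([0.5, -0.4, 0.3])
        pos, neg = top_k_edges(r, k=100)
        assert len(pos) == 2 and len(neg) == 1

    def test_ties_break_toward_smaller_edge_index(self):
        r = np.array([0.5, 0.9, 0.9, -0.2, 0.9, 0.1])
        pos, _ = top_k_edges(r, k=2)
        assert list(pos["edge"]) == [1, 2]


class TestThresholdConsistency:
    def test_identical_k_full_overlap(self):
        r = np.random.default_rng(0).uniform(-1, 1, 28)
        out = threshold_consistency(r, [10, 10])
        assert (out["edge_containment"] == 1.0).all()
        assert (out["category_jaccard"] == 1.0).all()

    def test_nested_k_containment(self):
        r = np.random.default_rng(1).uniform(-1, 1, 45)
        out = threshold_consistency(r, [10, 15, 20])
        assert (out["edge_containment"] == 1.0).all()  # top-k nesting

    def test_empty_k_values_rejected(self):
        with pytest.raises(ValueError):
            threshold_consistency(np.array([0.1, -0.2, 0.3]), [])


class TestAnnotate:
    def test_hemisphere_classification_and_subcortical_label(self):
        parc = make_parcellation(6, 4)  # 10 nodes: 0-2 L, 3-5 R ctx; 6-7 L, 8-9 R sub
        edges = pd.DataFrame({"node_i": [0, 0, 6], "node_j": [1, 3, 8],
                              "loading": [0.5, -0.3, 0.2]})
        out = annotate_networks(edges, parc)
        assert list(out["hemispheric"]) == ["intra", "inter", "inter"]
        assert out.loc[2, "network_i"] == "Subcortical"
        assert out.loc[2, "network_j"] == "Subcortical"

    def test_unknown_node_rejected(self):
        parc = make_parcellation(6, 4)
        edges = pd.DataFrame({"node_i": [0], "node_j": [99], "loading": [0.1]})
        with pytest.raises(ValueError, match="unknown node"):
            annotate_networks(edges, parc)


class TestModeration:
    def _covs(self, n, rng):
        return pd.DataFrame({"education": rng.integers(12, 19, n).astype(float),
                             "duration": rng.uniform(1, 20, n)})

    def test_identical_variates_give_unit_slope(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(50)
        res = covariate_moderation(_FakeMode(v, v), self._covs(50, rng))
        assert res.coef_behavior == pytest.approx(1.0)
        assert res.p_behavior < 1e-10
        assert res.behavior_significant

    def test_orthogonal_covariates_leave_simple_slope(self):
        rng = np.random.default_rng(1)
        n = 80
        behav = rng.standard_normal(n)
        brain = 0.7 * behav + 0.2 * rng.standard_normal(n)
        covs = self._covs(n, rng)
        # orthogonalize both covariates against both variates
        D = np.column_stack([np.ones(n), behav, brain])
        for col in covs.columns:
            v = covs[col].to_numpy()
            covs[col] = v - D @ np.linalg.lstsq(D, v, rcond=None)[0]
        simple = np.polyfit(behav, brain, 1)[0]
        res = covariate_moderation(_FakeMode(brain, behav), covs)
        assert res.coef_behavior == pytest.approx(simple, abs=1e-8)

    def test_null_brain_variate_is_calibrated(self):
        # brain variate independent of everything: p should be ~ uniform
        rng = np.random.default_rng(2)
        n, sims = 200, 200
        rejections = 0
        for _ in range(sims):
            brain = rng.standard_normal(n)
            behav = rng.standard_normal(n)
            covs = pd.DataFrame({"education": rng.uniform(12, 18, n),
                                 "duration": rng.uniform(1, 20, n)})
            res = covariate_moderation(_FakeMode(brain, behav), covs)
            rejections += res.p_behavior < 0.05
        assert 0.02 <= rejections / sims <= 0.09

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(40)
        covs = pd.DataFrame({"education": v * 1e-9 + 1.0,
                             "duration": v * 1e-9 + 1.0})
        with pytest.raises(ValueError, match="collinear"):
            covariate_moderation(_FakeMode(rng.standard_normal(40), v), covs)

    def test_incomplete_cases_dropped(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(30)
        covs = self._covs(30, rng)
        covs.loc[:9, "duration"] = np.nan
        res = covariate_moderation(_FakeMode(v, v), covs)
        assert res.n == 20
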