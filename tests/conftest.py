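"""Shared fixtures: small synthetic cohorts preprocessed through the feature stack."""

from __future__ import annotations

import numpy as np
import pytest

from kinconn.features import (
    residualize_features, vectorize_upper_triangle, zscore_columns,
)
from kinconn.pca import fit_pca, project
from kinconn.synthetic import CohortSpec, generate_cohort


def preprocess(cohort):
    """Edges -> residualize -> z-score -> PC scores, plus the behavior block."""
    X = np.vstack([vectorize_upper_triangle(m) for m in cohort.connectivity])
    std = zscore_columns(residualize_features(X, cohort.covariates))
    model = fit_pca(std)
    scores = project(std, model)
    tasks = [c for c in cohort.behavior.columns if c != "group"]
    Y = cohort.behavior[tasks].to_numpy(dtype=float)
    return scores, Y, std, model


@pytest.fixture(scope="session")
def planted_cohort():
    """Single-mode cohort with a strong planted brain-behavior association."""
    spec = CohortSpec(n_subjects=60, n_nodes=10, active_edges=10,
                      canonical_rho=0.8, seed=4)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_views(planted_cohort):
    scores, Y, std, model = preprocess(planted_cohort)
    return scores, Y


@pytest.fixture(scope="session")
def null_cohort():
    spec = CohortSpec(n_subjects=60, n_nodes=10, active_edges=10,
                      canonical_rho=0.0, seed=11)
    return generate_cohort(spec)
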