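#!/usr/bin/env python
"""Back-projection of significant modes: loadings, top edges, moderation.

For each significant mode of the reduced-parcellation SC demo cohort: Pearson loadings of
the behavior variate on the nine task scores and of the brain variate on
the residualized edges; the top-15 positive/negative edges annotated with
Yeo-7 network and hemisphere; selection consistency across reporting
thresholds; and the education/duration moderation regression.
"""

from pathlib import Path

import numpy as np

from kinconn.features import (
    residualize_features, vectorize_upper_triangle, zscore_columns,
)
from kinconn.interpret import (
    compute_loadings, covariate_moderation, threshold_consistency,
)
from kinconn.io import load_parcellation, read_connectivity_dir, read_table, write_table
from kinconn.kinarm import TASKS
from kinconn.pca import fit_pca, project, stability_select
from kinconn.scca import extract_modes

RESULTS = Path("results")
COHORT = Path("scratch/cohorts/SC_demo")
SEED = 23  # same fits as 04_scca_modes.py


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    matrices = read_connectivity_dir(COHORT / "connectivity", "SC")
    behavior = read_table(COHORT / "behavior.tsv")
    covariates = read_table(COHORT / "covariates.tsv")
    parcellation = load_parcellation(COHORT / "parcellation.tsv")
    X = np.vstack([vectorize_upper_triangle(m) for m in matrices])
    resid = residualize_features(X, covariates)
    std = zscore_columns(resid)
    rep = stability_select(std, n_resamples=200, seed=SEED)
    scores = project(std, fit_pca(std), n_components=rep.stable_count)
    Y = behavior[list(TASKS)].to_numpy(dtype=float)
    modes = extract_modes(scores, Y, max_modes=2, seed=SEED, permutations=199)

    for mode in modes:
        if not mode.significant:
            continue
        report = compute_loadings(mode, behavior[list(TASKS)], resid,
                                  parcellation=parcellation, k=15)
        tag = f"SC_mode{mode.mode_index}"
        write_table(report.task_loadings.to_frame(),
                    RESULTS / f"{tag}_task_loadings.tsv")
        write_table(report.top_positive, RESULTS / f"{tag}_top_positive_edges.tsv",
                    index=False)
        write_table(report.top_negative, RESULTS / f"{tag}_top_negative_edges.tsv",
                    index=False)
        cons = threshold_consistency(report.edge_loadings, [10, 15, 20],
                                     parcellation)
        write_table(cons, RESULTS / f"{tag}_threshold_consistency.tsv", index=False)

        top_task = report.task_loadings.abs().idxmax()
        print(f"mode {mode.mode_index}: strongest task loading {top_task} "
              f"(r={report.task_loadings[top_task]:.2f}); "
              f"top edge |loading|={report.top_positive['loading'].abs().max():.2f}")
        intra = (report.top_positive["hemispheric"] == "intra").sum() + \
                (report.top_negative["hemispheric"] == "intra").sum()
        total = len(report.top_positive) + len(report.top_negative)
        print(f"  {intra}/{total} of the top edges are intra-hemispheric")

        mod = covariate_moderation(mode, covariates)
        print(f"  moderation (n={mod.n} complete cases): behavior-variate "
              f"coefficient {mod.coef_behavior:.3f} (p={mod.p_behavior:.2e}) "
              f"remains significant: {mod.behavior_significant}")


if __name__ == "__main__":
    main()
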