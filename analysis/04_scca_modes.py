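#!/usr/bin/env python
"""Sparse CCA between PC scores and behavior, with permutation inference.

Runs the full multivariate stage on the reduced-parcellation demo cohorts
(see 01_simulate_cohorts.py for why the 6670-edge cohorts are not usable
here):
penalty tuning by 3-fold cross-validated grid search, sequential mode
extraction with 199-permutation inference per mode (each permutation
re-tunes), and 50x3-fold repeated cross-validation as an out-of-sample
check.  Writes per-mode weights/variates and a summary.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from kinconn.features import (
    residualize_features, vectorize_upper_triangle, zscore_columns,
)
from kinconn.io import read_connectivity_dir, read_table, write_table
from kinconn.kinarm import TASKS
from kinconn.pca import fit_pca, project, stability_select
from kinconn.scca import extract_modes, repeated_cv

RESULTS = Path("results")
SCRATCH = Path("scratch/cohorts")
PERMUTATIONS = 199
CV_REPEATS = 50
SEED = 23


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    summary = {}
    for modality in ("SC", "FC"):
        cohort_dir = SCRATCH / f"{modality}_demo"
        matrices = read_connectivity_dir(cohort_dir / "connectivity", modality)
        behavior = read_table(cohort_dir / "behavior.tsv")
        covariates = read_table(cohort_dir / "covariates.tsv")
        X = np.vstack([vectorize_upper_triangle(m) for m in matrices])
        std = zscore_columns(residualize_features(X, covariates))
        rep = stability_select(std, n_resamples=200, seed=SEED)
        scores = project(std, fit_pca(std), n_components=rep.stable_count)
        Y = behavior[list(TASKS)].to_numpy(dtype=float)

        modes = extract_modes(scores, Y, max_modes=2, seed=SEED,
                              permutations=PERMUTATIONS)
        cv = repeated_cv(scores, Y, repeats=CV_REPEATS, seed=SEED)

        mode_info = []
        for m in modes:
            write_table(pd.DataFrame({"task": list(TASKS),
                                      "w_behavior": m.w_behavior}),
                        RESULTS / f"{modality}_mode{m.mode_index}_w_behavior.tsv",
                        index=False)
            mode_info.append({"mode": m.mode_index,
                              "canonical_r": round(m.canonical_r, 3),
                              "p_perm": m.p_perm,
                              "significant": bool(m.significant),
                              "c_brain": m.penalties.c_brain,
                              "c_behavior": m.penalties.c_behavior})
            print(f"{modality} mode {m.mode_index}: r={m.canonical_r:.3f} "
                  f"p={m.p_perm:.4f} significant={m.significant}")
        print(f"{modality} repeated CV: median held-out r={cv.median:.3f} "
              f"IQR=({cv.iqr[0]:.3f}, {cv.iqr[1]:.3f}) over "
              f"{cv.test_fold_rs.size} fold evaluations")
        summary[modality] = {
            "n_components": int(rep.stable_count),
            "modes": mode_info,
            "cv_median_r": cv.median,
            "cv_iqr": list(cv.iqr),
            "cv_n_correlations": int(cv.test_fold_rs.size),
        }
        write_table(pd.DataFrame({"test_fold_r": cv.test_fold_rs}),
                    RESULTS / f"{modality}_cv_correlations.tsv")
    with open(RESULTS / "scca_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
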