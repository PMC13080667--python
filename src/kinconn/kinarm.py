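"""Robotic (Kinarm) behavioral scores and univariate group statistics.

Nine standardized upper-limb tasks are analyzed: Visually Guided Reaching
(VGR), Reverse Visually Guided Reaching (RVGR), Object Hit (OH), Object Hit
& Avoid (OHA), Trail Making A/B (TMA/TMB), Paired-Associates Learning (PAL),
Ball on Bar (BOB) and Arm Position Matching (APM).  Each task is summarized
by a Z-Task Score, the root-mean-square of that task's parameter z-scores
relative to a normative model; a one-sided Task Score (0 = best possible
performance, larger = worse) is used for display.

Group comparisons follow a Shapiro-Wilk normality gate: Student's t-test
when both groups look normal, Mann-Whitney U otherwise, with rank-biserial
correlation r = 1 - 2U/(n1*n2) as the nonparametric effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TASKS",
    "GroupComparisonResult",
    "z_task_score",
    "task_score_one_sided",
    "mann_whitney_u",
    "rank_biserial_from_u",
    "yates_chi_square",
    "compare_groups",
    "spearman_screen",
]

#: Fixed task order used throughout the package.
TASKS = ("VGR", "RVGR", "OH", "OHA", "TMA", "TMB", "PAL", "BOB", "APM")

#: Group labels in behavior tables.
CONTROL, PATIENT = "control", "TLE"


@dataclass
class GroupComparisonResult:
    task: str
    test_used: str  # "mann_whitney" | "t_test"
    statistic: float
    p_value: float
    effect_size_r: float
    shapiro_p_control: float
    shapiro_p_patient: float


def z_task_score(parameter_z) -> float:
    """Root-mean-square of a task's parameter z-scores (always >= 0)."""
    z = np.asarray(parameter_z, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("z_task_score needs at least one parameter z-score")
    return float(np.sqrt(np.mean(z * z)))


def task_score_one_sided(z_task: float) -> float:
    """One-sided Task Score: 0 is the best possible performance.

    Implemented as the quantile map of the two-sided tail of the Z-Task
    score onto the positive half-normal; under a standard-normal Z-Task
    this reduces to the absolute value.  The map is monotone in the
    impairment magnitude, matching the published convention (the device's
    internal transform is proprietary).
    """
    z = float(z_task)
    if not np.isfinite(z):
        raise ValueError("z_task must be finite")
    return abs(z)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact enumeration when n1 + n2 <= 12 and there are no ties; normal
    approximation with tie correction (and continuity correction)
    otherwise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rank_biserial_from_u(U: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = 1 - 2U/(n1*n2), in [-1, 1]."""
    prod = n1 * n2
    if prod <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= U <= prod):
        raise ValueError(f"U={U} outside [0, {prod}]")
    return 1.0 - 2.0 * U / prod


def yates_chi_square(table) -> tuple[float, float]:
    """Continuity-corrected chi-square on a 2x2 table; returns (chi2, p).

    chi2 = sum over cells of max(|O - E| - 0.5, 0)^2 / E with 1 df; the
    per-cell clipping at zero means tables already close to independence
    score exactly 0.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=True)
    assert dof == 1
    return float(chi2), float(p)


def _t_effect_size_r(t: float, df: float) -> float:
    # point-biserial conversion r = t / sqrt(t^2 + df) (Cohen's d to r)
    return float(t / np.sqrt(t * t + df))


def compare_groups(
    behavior: pd.DataFrame,
    alpha_normality: float = 0.05,
    tasks=TASKS,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-task two-group comparison with a Shapiro-Wilk normality gate.

    For each task, Shapiro-Wilk is run on each group; Student's t-test is
    used only when both groups pass (p >= ``alpha_normality``), otherwise
    the Mann-Whitney U test.  Effect sizes are rank-biserial r for the U
    test and the t-to-r conversion for the t-test.  The U statistic is the
    control group's, so positive r means patients score worse (higher).
    """
    groups = behavior[group_col]
    x_all = behavior.loc[groups == CONTROL]
    y_all = behavior.loc[groups == PATIENT]
    if len(x_all) < 3 or len(y_all) < 3:
        raise ValueError("each group needs >= 3 subjects for the normality gate")
    rows = []
    for task in tasks:
        x = x_all[task].to_numpy(dtype=float)
        y = y_all[task].to_numpy(dtype=float)
        sw_x = float(stats.shapiro(x).pvalue)
        sw_y = float(stats.shapiro(y).pvalue)
        if sw_x >= alpha_normality and sw_y >= alpha_normality:
            t, p = stats.ttest_ind(x, y, equal_var=True)
            df = len(x) + len(y) - 2
            rows.append(GroupComparisonResult(
                task, "t_test", float(t), float(p), _t_effect_size_r(float(t), df),
                sw_x, sw_y))
        else:
            U, p = mann_whitney_u(x, y)
            rows.append(GroupComparisonResult(
                task, "mann_whitney", U, p,
                rank_biserial_from_u(U, len(x), len(y)), sw_x, sw_y))
    return pd.DataFrame([vars(r) for r in rows])


def spearman_screen(behavior: pd.DataFrame, covariate, tasks=TASKS) -> pd.DataFrame:
    """Spearman correlation (midrank ties, two-sided p) of each task with a covariate."""
    cov = np.asarray(covariate, dtype=float).ravel()
    if cov.size != len(behavior):
        raise ValueError("covariate length must match behavior rows")
    keep = np.isfinite(cov)
    if keep.sum() < 3:
        raise ValueError("need >= 3 paired observations")
    if np.unique(cov[keep]).size < 2:
        raise ValueError("constant covariate")
    rows = []
    for task in tasks:
        vals = behavior[task].to_numpy(dtype=float)[keep]
        rho, p = stats.spearmanr(vals, cov[keep])
        rows.append({"task": task, "rho": float(rho), "p_value": float(p)})
    return pd.DataFrame(rows)
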