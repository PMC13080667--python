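"""Synthetic cohorts with known latent brain-behavior structure.

The study data this pipeline targets (per-subject connectomes plus robotic
behavioral scores for a case-control epilepsy cohort) are confidential, so
every downstream stage is exercised on generated cohorts with a planted,
fully known ground truth:

* a latent factor ``s`` per subject drives a sparse set of "active"
  connectome edges and all nine behavioral task scores,
* nuisance covariates (age, sex, education) leak into the edges,
* patients receive additive per-task shifts patterned on the published
  case-control effect sizes,
* edge values are squashed into modality-appropriate ranges (nonnegative
  streamline-like weights for SC, [-1, 1] correlations for FC).

Noise algebra
-------------
Each view observes a noisy unit-variance latent: ``u_x = sqrt(r)*s +
sqrt(1-r)*g_x`` and likewise ``u_y``, so corr(u_x, u_y) = r.  Every active
edge j is ``w_j*u_x + sigma*eps`` and every task k is ``b_k*u_y +
sigma*eps`` with unit-norm loading vectors w, b.  The best linear combination
of one view correlates with its latent at ``1/sqrt(1+sigma^2)`` (information
sum(w_j^2)/sigma^2 = 1/sigma^2), so the population canonical correlation of
the two observed blocks is ``r/(1+sigma^2)``.  The generator therefore sets
``r = min(1, canonical_rho*(1+sigma^2))`` so that the blocks' population
canonical correlation equals ``canonical_rho`` (exactly, up to the mild
near-linear modality squashing and the cap at r=1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .features import ConnectivityMatrix, edge_index
from .kinarm import TASKS, CONTROL, PATIENT

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "SyntheticCohort",
    "generate_cohort",
    "degrade_to_null",
    "make_parcellation",
    "make_factor_features",
    "DEFAULT_GROUP_SHIFT",
]

#: Published case-control rank-biserial effect sizes per task (worked-example
#: inputs), mapped to normal-shift units via delta = sqrt(2)*Phi^-1((1+r)/2).
_EFFECT_SIZES = {
    "VGR": 0.22, "RVGR": 0.61, "OH": 0.40, "OHA": 0.41, "TMA": 0.50,
    "TMB": 0.42, "PAL": 0.57, "BOB": 0.05, "APM": 0.18,
}

DEFAULT_GROUP_SHIFT = np.array(
    [np.sqrt(2.0) * _stats.norm.ppf((1.0 + _EFFECT_SIZES[t]) / 2.0) for t in TASKS]
)

_SUBCORTICAL = ("Thalamus", "Caudate", "Putamen", "Pallidum",
                "Hippocampus", "Amygdala", "Accumbens", "VentralDC")
_YEO7 = ("Visual", "Somatomotor", "DorsalAttention", "VentralAttention",
         "Limbic", "Frontoparietal", "Default")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study conditions: 24 controls / 33 patients,
    116 nodes (100 cortical + 16 subcortical), nine tasks, and patient
    task shifts derived from the published effect sizes.
    """

    n_subjects: int = 57
    n_controls: int | None = None  # default: round(24/57 * n_subjects)
    n_nodes: int = 116
    n_tasks: int = 9
    active_edges: int = 40
    canonical_rho: float = 0.5
    covariate_effect: float = 0.3
    group_shift: np.ndarray | None = None  # per-task shift in task-SD units
    modality: str = "SC"
    noise_sd: float = 0.3
    background_factors: int = 5
    background_strength: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not (0.0 <= self.canonical_rho <= 1.0):
            raise ValueError(f"canonical_rho must be in [0, 1], got {self.canonical_rho}")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if not (1 <= self.active_edges <= max_edges):
            raise ValueError(f"active_edges must be in [1, {max_edges}]")
        if self.modality not in ("SC", "FC"):
            raise ValueError("modality must be 'SC' or 'FC'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_controls is None:
            self.n_controls = int(round(self.n_subjects * 24 / 57))
        if not (0 <= self.n_controls <= self.n_subjects):
            raise ValueError("n_controls out of range")
        if self.group_shift is None:
            if self.n_tasks == len(TASKS):
                self.group_shift = DEFAULT_GROUP_SHIFT.copy()
            else:
                self.group_shift = np.zeros(self.n_tasks)
        self.group_shift = np.asarray(self.group_shift, dtype=float)
        if self.group_shift.shape != (self.n_tasks,):
            raise ValueError("group_shift length must equal n_tasks")


@dataclass
class CohortTruth:
    """Planted ground truth of a synthetic cohort."""

    active_edges: np.ndarray          # sorted edge indices carrying signal
    latent: np.ndarray                # shared factor s per subject
    edge_loadings_raw: np.ndarray     # w over all edges (unit norm, zeros off-support)
    behavior_loadings_raw: np.ndarray  # b over tasks (unit norm)
    brain_weights: np.ndarray         # population-optimal unit weights, standardized edges
    behavior_weights: np.ndarray      # population-optimal unit weights, standardized tasks
    canonical_rho: float
    rho_latent: float
    is_null: bool = False


@dataclass
class SyntheticCohort:
    connectivity: list[ConnectivityMatrix]
    behavior: pd.DataFrame            # TASKS columns + "group", indexed by subject id
    covariates: pd.DataFrame          # age, sex, education, duration
    truth: CohortTruth
    edge_latent: np.ndarray = field(repr=False, default=None)  # pre-squash edge values

    @property
    def subject_ids(self) -> list[str]:
        return list(self.behavior.index)


def _draw_covariates(rng: np.random.Generator, n_controls: int, n_patients: int) -> pd.DataFrame:
    """Covariates bracketing the study demographics.

    Controls: younger, more educated, mostly female; patients: education
    centered lower, roughly balanced sex, epilepsy duration log-normal
    with mean ~9.6 and SD ~11 years (controls have no duration).
    """
    age_c = np.clip(rng.normal(31, 9, n_controls), 19, 56)
    age_p = np.clip(rng.normal(36, 10, n_patients), 20, 61)
    sex_c = (rng.random(n_controls) > 0.75).astype(float)   # 1 = male
    sex_p = (rng.random(n_patients) > 0.48).astype(float)
    edu_c = rng.integers(14, 19, n_controls).astype(float)
    edu_p = rng.integers(12, 15, n_patients).astype(float)
    # lognormal matched to mean 9.58, sd 11.04
    s2 = np.log(1 + (11.04 / 9.58) ** 2)
    dur_p = rng.lognormal(np.log(9.58) - s2 / 2, np.sqrt(s2), n_patients)
    return pd.DataFrame({
        "age": np.concatenate([age_c, age_p]),
        "sex": np.concatenate([sex_c, sex_p]),
        "education": np.concatenate([edu_c, edu_p]),
        "duration": np.concatenate([np.full(n_controls, np.nan), dur_p]),
    })


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort with the planted structure described in the module docstring.

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, n_nodes = spec.n_subjects, spec.n_nodes
    n_edges = n_nodes * (n_nodes - 1) // 2
    n_pat = n - spec.n_controls
    sigma = spec.noise_sd

    # latent structure: see module docstring for the attenuation algebra
    rho_latent = min(1.0, spec.canonical_rho * (1.0 + sigma**2))
    s = rng.standard_normal(n)
    g_x = rng.standard_normal(n)
    g_y = rng.standard_normal(n)
    u_x = np.sqrt(rho_latent) * s + np.sqrt(1.0 - rho_latent) * g_x
    u_y = np.sqrt(rho_latent) * s + np.sqrt(1.0 - rho_latent) * g_y

    active = np.sort(rng.choice(n_edges, size=spec.active_edges, replace=False))
    w = rng.standard_normal(spec.active_edges)
    w /= np.linalg.norm(w)
    b = rng.standard_normal(spec.n_tasks)
    b /= np.linalg.norm(b)

    # pre-squash edge values on the latent scale
    inactive_sd = np.sqrt(1.0 / spec.active_edges + sigma**2)
    Z = rng.normal(0.0, inactive_sd, size=(n, n_edges))
    Z[:, active] = np.outer(u_x, w) + sigma * rng.standard_normal((n, spec.active_edges))

    # shared background factors: real connectome edges are strongly
    # inter-correlated (community/hub structure), which is what concentrates
    # the PCA spectrum into a handful of retainable components; without this
    # the edge correlation matrix is near-identity and the Kaiser rule keeps
    # an uninterpretable Marchenko-Pastur bulk.  Background loadings are
    # shared across all edges and carry no brain-behavior signal.
    if spec.background_factors > 0 and spec.background_strength > 0:
        F = rng.standard_normal((n, spec.background_factors))
        L = rng.standard_normal((spec.background_factors, n_edges))
        L *= spec.background_strength / np.linalg.norm(L, axis=0, keepdims=True)
        Z = Z + F @ L

    covariates = _draw_covariates(rng, spec.n_controls, n_pat)
    if spec.covariate_effect != 0.0:
        C = covariates[["age", "sex", "education"]].to_numpy()
        C = (C - C.mean(0)) / C.std(0, ddof=1)
        gamma = rng.standard_normal((3, n_edges)) / np.sqrt(3)
        Z = Z + spec.covariate_effect * (C @ gamma)

    # behavior: latent loading + noise + patient shift (in task-SD units)
    Y = np.outer(u_y, b) + sigma * rng.standard_normal((n, spec.n_tasks)) + 1.0
    task_sd = np.sqrt(b**2 + sigma**2)
    is_patient = np.arange(n) >= spec.n_controls
    Y[is_patient] += spec.group_shift * task_sd

    # modality squashing, kept near-linear over the latent range so the
    # population canonical structure survives the transform
    iu = np.triu_indices(n_nodes, k=1)
    if spec.modality == "SC":
        base = rng.normal(3.0, 0.5, n_edges)
        edge_vals = _softplus(base + Z) * 25.0
    else:
        base = rng.normal(0.31, 0.2, n_edges)
        edge_vals = np.tanh(base + 0.35 * Z)

    subject_ids = [f"sub-{i:03d}" for i in range(n)]
    matrices = []
    for i in range(n):
        M = np.zeros((n_nodes, n_nodes))
        M[iu] = edge_vals[i]
        M += M.T
        if spec.modality == "FC":
            np.fill_diagonal(M, 1.0)
        matrices.append(ConnectivityMatrix(M, spec.modality, subject_ids[i]))

    task_cols = list(TASKS[: spec.n_tasks]) if spec.n_tasks <= len(TASKS) else [
        f"task{k}" for k in range(spec.n_tasks)]
    behavior = pd.DataFrame(Y, columns=task_cols, index=subject_ids)
    behavior["group"] = np.where(is_patient, PATIENT, CONTROL)
    covariates.index = pd.Index(subject_ids)

    # population-optimal weights on the standardized observables: the raw
    # optimal combination is sum_j w_j * x_j, which on z-scored columns
    # becomes weights proportional to w_j * sd_j (sd_j = sqrt(w_j^2+sigma^2))
    w_full = np.zeros(n_edges)
    w_full[active] = w
    bg_var = (spec.background_strength**2
              if spec.background_factors > 0 else 0.0)
    brain_w = np.zeros(n_edges)
    # approximation: treats the shared background as independent per-edge
    # noise (the exact optimum can partially cancel it across edges)
    brain_w[active] = w * np.sqrt(w**2 + sigma**2 + bg_var)
    brain_w /= np.linalg.norm(brain_w)
    behav_w = b * task_sd
    behav_w /= np.linalg.norm(behav_w)

    truth = CohortTruth(
        active_edges=active, latent=s, edge_loadings_raw=w_full,
        behavior_loadings_raw=b, brain_weights=brain_w, behavior_weights=behav_w,
        canonical_rho=spec.canonical_rho, rho_latent=rho_latent)
    return SyntheticCohort(matrices, behavior, covariates, truth, edge_latent=Z)


def degrade_to_null(cohort: SyntheticCohort, seed: int) -> SyntheticCohort:
    """Permute behavior rows against the rest of the cohort.

    Breaks every brain-behavior association while preserving the behavior
    table's marginal distributions (rows move as whole units, keeping the
    group label attached to its scores).
    """
    rng = np.random.default_rng(seed)
    n = len(cohort.behavior)
    perm = rng.permutation(n)
    behavior = cohort.behavior.iloc[perm].copy()
    behavior.index = cohort.behavior.index
    truth = CohortTruth(
        active_edges=cohort.truth.active_edges, latent=cohort.truth.latent,
        edge_loadings_raw=cohort.truth.edge_loadings_raw,
        behavior_loadings_raw=cohort.truth.behavior_loadings_raw,
        brain_weights=cohort.truth.brain_weights,
        behavior_weights=cohort.truth.behavior_weights,
        canonical_rho=0.0, rho_latent=cohort.truth.rho_latent, is_null=True)
    return SyntheticCohort(cohort.connectivity, behavior, cohort.covariates,
                           truth, edge_latent=cohort.edge_latent)


def make_parcellation(n_cortical: int = 100, n_subcortical: int = 16) -> pd.DataFrame:
    """Synthetic parcellation table: Yeo-7-labelled cortical nodes split
    across hemispheres plus subcortical structures (stand-in for the real
    atlas; columns node_id, label, network, hemisphere)."""
    if n_cortical % 2 or n_subcortical % 2:
        raise ValueError("cortical and subcortical counts must be even (L/R split)")
    rows = []
    node = 0
    for hemi in ("L", "R"):
        for i in range(n_cortical // 2):
            net = _YEO7[i % len(_YEO7)]
            rows.append((node, f"{hemi}_{net}_{i}", net, hemi))
            node += 1
    for hemi in ("L", "R"):
        for i in range(n_subcortical // 2):
            name = _SUBCORTICAL[i % len(_SUBCORTICAL)]
            rows.append((node, f"{hemi}_{name}", "Subcortical", hemi))
            node += 1
    return pd.DataFrame(rows, columns=["node_id", "label", "network", "hemisphere"])


def make_factor_features(
    n_subjects: int = 300, n_features: int = 60, n_factors: int = 7,
    loading: float = 0.9, seed: int = 0,
) -> np.ndarray:
    """Features driven by disjoint blocks of strong factors.

    Each factor loads sqrt(loading) on its block, so within-block
    correlations equal ``loading`` and the correlation matrix has one
    eigenvalue ~ 1 + (block_size - 1)*loading per factor, with the rest
    near 1 - loading: a clean planted component count for stability tests.
    """
    if not (0 < loading < 1):
        raise ValueError("loading must be in (0, 1)")
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n_subjects, n_factors))
    X = np.empty((n_subjects, n_features))
    blocks = np.array_split(np.arange(n_features), n_factors)
    for k, idx in enumerate(blocks):
        X[:, idx] = (np.sqrt(loading) * F[:, [k]]
                     + np.sqrt(1 - loading) * rng.standard_normal((n_subjects, len(idx))))
    return X
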