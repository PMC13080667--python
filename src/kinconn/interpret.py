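"""Interpretation of significant canonical modes.

A mode is interpreted by back-projection: the Pearson correlation
("loading") of each canonical variate with every original variable — each
task score for the behavior variate, each residualized (pre-PCA) edge value
for the brain variate.  The top-K most positively and most negatively
loaded edges (K = 15 by default, mirroring the reporting convention) are
annotated with the network and hemisphere of both endpoints.  A moderation
regression checks that the brain-behavior coupling survives adjustment for
education and epilepsy duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import edge_index as _edge_index

__all__ = [
    "LoadingReport",
    "ModerationResult",
    "compute_loadings",
    "top_k_edges",
    "threshold_consistency",
    "annotate_networks",
    "covariate_moderation",
]


@dataclass
class LoadingReport:
    task_loadings: pd.Series       # per-task r of behavior variate vs Z-Task score
    edge_loadings: np.ndarray      # per-edge r of brain variate vs residualized edge
    top_positive: pd.DataFrame
    top_negative: pd.DataFrame


@dataclass
class ModerationResult:
    coef_behavior: float
    p_behavior: float
    coef_education: float
    p_education: float
    coef_duration: float
    p_duration: float
    n: int
    behavior_significant: bool


def _pearson_columns(variate: np.ndarray, columns: np.ndarray) -> np.ndarray:
    """Pearson r of a variate with each column; zero-variance columns -> NaN."""
    v = np.asarray(variate, dtype=float).ravel()
    M = np.asarray(columns, dtype=float)
    if M.shape[0] != v.size:
        raise ValueError("subject counts do not align")
    vc = v - v.mean()
    sv = np.sqrt(vc @ vc)
    Mc = M - M.mean(axis=0)
    sm_ = np.sqrt(np.einsum("ij,ij->j", Mc, Mc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ Mc) / (sv * sm_)
    r[sm_ <= 1e-12] = np.nan
    if sv <= 1e-12:
        r[:] = np.nan
    return r


def compute_loadings(
    mode, original_tasks: pd.DataFrame, original_edges: np.ndarray,
    parcellation: pd.DataFrame | None = None, k: int = 15,
) -> LoadingReport:
    """Loadings of a fitted mode on the original variables.

    ``original_edges`` should be the residualized (pre-PCA) edge matrix —
    the state of the connectivity data immediately before dimensionality
    reduction.  Undefined (zero-variance) loadings are excluded from the
    top lists.
    """
    task_vals = original_tasks.to_numpy(dtype=float)
    task_r = _pearson_columns(mode.variate_behavior, task_vals)
    task_loadings = pd.Series(task_r, index=list(original_tasks.columns), name="loading")
    edge_r = _pearson_columns(mode.variate_brain, original_edges)
    top_pos, top_neg = top_k_edges(edge_r, k=k)
    if parcellation is not None:
        top_pos = annotate_networks(top_pos, parcellation)
        top_neg = annotate_networks(top_neg, parcellation)
    return LoadingReport(task_loadings, edge_r, top_pos, top_neg)


def _edges_frame(edge_loadings: np.ndarray, n_nodes: int) -> pd.DataFrame:
    pairs = _edge_index(n_nodes)
    return pd.DataFrame({
        "edge": np.arange(len(pairs)),
        "node_i": [p[0] for p in pairs],
        "node_j": [p[1] for p in pairs],
        "loading": edge_loadings,
    })


def _n_nodes_from_edges(n_edges: int) -> int:
    n = int((1 + np.sqrt(1 + 8 * n_edges)) / 2)
    if n * (n - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} is not a valid strict-upper-triangle length")
    return n


def top_k_edges(edge_loadings: np.ndarray, k: int = 15) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k positive and top-k negative edge loadings.

    Lists are sorted by |loading| descending within each sign; ties break
    toward the smaller edge index, so the selection is invariant to any
    permutation of the input order.  NaN loadings are skipped; if fewer
    than k edges of a sign exist, all available are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    r = np.asarray(edge_loadings, dtype=float).ravel()
    df = _edges_frame(r, _n_nodes_from_edges(r.size)).dropna(subset=["loading"])
    pos = df[df["loading"] > 0].sort_values(
        ["loading", "edge"], ascending=[False, True], kind="mergesort").head(k)
    neg = df[df["loading"] < 0].sort_values(
        ["loading", "edge"], ascending=[True, True], kind="mergesort").head(k)
    pos = pos.reset_index(drop=True)
    neg = neg.reset_index(drop=True)
    pos.insert(0, "rank", np.arange(1, len(pos) + 1))
    neg.insert(0, "rank", np.arange(1, len(neg) + 1))
    return pos, neg


def threshold_consistency(
    edge_loadings: np.ndarray, k_values, parcellation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Overlap of top-edge selections across reporting thresholds.

    For each pair of k values, reports the Jaccard overlap of the selected
    network-pair categories (when a parcellation is given) and the
    containment of the smaller edge set in the larger (1.0 by construction
    for nested top-k of the same ranking).
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be nonempty")

    def _sets(k):
        pos, neg = top_k_edges(edge_loadings, k=k)
        edges = set(pos["edge"]).union(set(neg["edge"]))
        if parcellation is not None:
            net = parcellation.set_index("node_id")["network"]
            cats = {tuple(sorted((net[i], net[j])))
                    for i, j in zip(pos["node_i"], pos["node_j"])}
            cats |= {tuple(sorted((net[i], net[j])))
                     for i, j in zip(neg["node_i"], neg["node_j"])}
        else:
            cats = edges
        return edges, cats

    rows = []
    for a in k_values:
        ea, ca = _sets(a)
        for b in k_values:
            eb, cb = _sets(b)
            small, large = (ea, eb) if len(ea) <= len(eb) else (eb, ea)
            containment = len(small & large) / len(small) if small else 1.0
            jac = len(ca & cb) / len(ca | cb) if (ca | cb) else 1.0
            rows.append({"k_a": a, "k_b": b,
                         "edge_containment": containment,
                         "category_jaccard": jac})
    return pd.DataFrame(rows)


def annotate_networks(edges: pd.DataFrame, parcellation: pd.DataFrame) -> pd.DataFrame:
    """Attach network/hemisphere labels per endpoint and classify each edge
    as intra- or inter-hemispheric."""
    parc = parcellation.set_index("node_id")
    out = edges.copy()
    for suffix in ("i", "j"):
        nodes = out[f"node_{suffix}"]
        unknown = set(nodes) - set(parc.index)
        if unknown:
            raise ValueError(f"unknown node ids: {sorted(unknown)}")
        out[f"label_{suffix}"] = nodes.map(parc["label"]).to_numpy()
        out[f"network_{suffix}"] = nodes.map(parc["network"]).to_numpy()
        out[f"hemisphere_{suffix}"] = nodes.map(parc["hemisphere"]).to_numpy()
    out["hemispheric"] = np.where(
        out["hemisphere_i"] == out["hemisphere_j"], "intra", "inter")
    return out


def covariate_moderation(
    mode, covariates: pd.DataFrame, alpha: float = 0.05,
) -> ModerationResult:
    """OLS of the brain variate on [1, behavior variate, education, duration].

    Complete cases only (controls without a recorded epilepsy duration drop
    out).  Reports whether the behavior-variate coefficient stays
    significant once the covariates enter as simultaneous predictors.
    """
    brain = np.asarray(mode.variate_brain, dtype=float).ravel()
    behav = np.asarray(mode.variate_behavior, dtype=float).ravel()
    edu = covariates["education"].to_numpy(dtype=float)
    dur = covariates["duration"].to_numpy(dtype=float)
    keep = np.isfinite(brain) & np.isfinite(behav) & np.isfinite(edu) & np.isfinite(dur)
    n = int(keep.sum())
    if n < 5:
        raise ValueError(f"need >= 5 complete cases, got {n}")
    design = sm.add_constant(np.column_stack([behav[keep], edu[keep], dur[keep]]))
    if np.linalg.cond(design) > 1e10:
        raise ValueError("collinear predictors in moderation design")
    fit = sm.OLS(brain[keep], design).fit()
    coef, pvals = fit.params, fit.pvalues
    return ModerationResult(
        coef_behavior=float(coef[1]), p_behavior=float(pvals[1]),
        coef_education=float(coef[2]), p_education=float(pvals[2]),
        coef_duration=float(coef[3]), p_duration=float(pvals[3]),
        n=n, behavior_significant=bool(pvals[1] < alpha))
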