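"""End-to-end orchestration: ingest -> features -> stats -> PCA -> sCCA -> interpretation.

A run is fully described by a :class:`PipelineConfig` (loadable from YAML);
identical configs and seeds produce byte-identical output tables.  Outputs
land in the configured directory as delimited tables plus a machine-readable
``manifest.json`` recording versions, seeds, parameters and headline results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import (
    EdgeTable, edge_index, residualize_features, vectorize_upper_triangle,
    zscore_columns,
)
from .interpret import compute_loadings, covariate_moderation, threshold_consistency
from .io import (
    load_parcellation, read_connectivity_dir, read_table, write_table,
)
from .kinarm import TASKS, compare_groups, spearman_screen
from .pca import fit_pca, project, stability_select
from .scca import extract_modes, repeated_cv

__all__ = ["PipelineConfig", "ValidationReport", "validate_inputs", "run_pipeline"]

log = logging.getLogger("kinconn")


@dataclass
class PipelineConfig:
    connectivity_dir: str
    behavior_path: str
    covariates_path: str
    output_dir: str
    parcellation_path: str | None = None
    modality: str = "SC"
    # PCA settings
    pca_resamples: int = 5000
    pca_subsample_fraction: float = 0.9
    pca_seed: int = 0
    # sCCA settings
    grid_step: float = 0.1
    folds: int = 3
    permutations: int = 5000
    cv_repeats: int = 1000
    ridge: float = 1e-3
    scca_seed: int = 0
    max_modes: int = 2
    alpha: float = 0.05
    # interpretation / stats
    top_k: int = 15
    consistency_ks: tuple = (10, 15, 20)
    alpha_normality: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def grid(self) -> np.ndarray:
        return np.round(np.arange(0.0, 1.0 + 1e-9, self.grid_step), 10)


@dataclass
class ValidationReport:
    fatal: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def _load_inputs(config: PipelineConfig):
    matrices = read_connectivity_dir(config.connectivity_dir, config.modality)
    behavior = read_table(config.behavior_path)
    covariates = read_table(config.covariates_path)
    parcellation = (load_parcellation(config.parcellation_path)
                    if config.parcellation_path else None)
    return matrices, behavior, covariates, parcellation


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Structural checks: matrix symmetry/modality, subject alignment, missingness.

    Fatal findings (asymmetric matrices, misaligned subject ids, missing
    behavior scores) block a run; expected gaps such as a control without an
    epilepsy duration are warnings only.
    """
    report = ValidationReport()
    try:
        matrices, behavior, covariates, parcellation = _load_inputs(config)
    except Exception as exc:  # unreadable inputs are fatal by definition
        report.fatal.append(f"failed to load inputs: {exc}")
        return report

    for m in matrices:
        try:
            m.validate()
        except ValueError as exc:
            report.fatal.append(str(exc))
    conn_ids = [m.subject_id for m in matrices]
    aligned = True
    for name, ids in (("behavior", list(behavior.index)),
                      ("covariates", list(covariates.index))):
        if ids != conn_ids:
            aligned = False
            extra = sorted(set(map(str, ids)) ^ set(conn_ids))
            report.fatal.append(
                f"subject ids in {name} table do not align with connectivity: "
                f"mismatches {extra[:10] or 'ordering differs'}")
    task_cols = [t for t in TASKS if t in behavior.columns]
    if len(task_cols) < 2:
        report.fatal.append("behavior table lacks recognizable task columns")
    elif behavior[task_cols].isna().any().any():
        report.fatal.append("missing behavior scores for analyzed subjects")
    if "group" not in behavior.columns:
        report.fatal.append("behavior table lacks a 'group' column")
    if aligned and "duration" in covariates.columns and "group" in behavior.columns:
        ctrl_missing = covariates.loc[behavior["group"] == "control", "duration"].isna()
        if ctrl_missing.any():
            report.warnings.append(
                f"{int(ctrl_missing.sum())} controls without epilepsy duration "
                "(expected; duration enters patient-side moderation only)")
        pat_missing = covariates.loc[behavior["group"] != "control", "duration"].isna()
        if pat_missing.any():
            report.warnings.append(
                f"{int(pat_missing.sum())} patients without epilepsy duration")
    if parcellation is not None and len(parcellation) != matrices[0].n_nodes:
        report.fatal.append(
            f"parcellation has {len(parcellation)} nodes but matrices have "
            f"{matrices[0].n_nodes}")
    return report


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


#: Stage order; ``through`` in run_pipeline truncates the run after a stage.
STAGES = ("stats", "pca", "scca", "interpret")


def run_pipeline(config: PipelineConfig, through: str = "interpret") -> dict:
    """Run the stages up to ``through`` and write reports; returns the manifest.

    Raises on fatal validation findings; any stage error propagates with
    its stage name prefixed.
    """
    if through not in STAGES:
        raise ValueError(f"through must be one of {STAGES}")
    last = STAGES.index(through)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(config)
    if not report.ok:
        raise ValueError("fatal input problems: " + "; ".join(report.fatal))
    for w in report.warnings:
        log.warning(w)

    manifest: dict = {
        "kinconn_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }
    matrices, behavior, covariates, parcellation = _load_inputs(config)
    task_cols = [t for t in TASKS if t in behavior.columns]

    try:
        t0 = _stage("features")
        rows = np.vstack([vectorize_upper_triangle(m) for m in matrices])
        n_nodes = matrices[0].n_nodes
        edges = EdgeTable(rows, edge_index(n_nodes), [m.subject_id for m in matrices])
        resid = residualize_features(edges.values, covariates)
        std = zscore_columns(resid)
        manifest["stages"]["features"] = {
            "n_subjects": rows.shape[0], "n_edges": rows.shape[1],
            "elapsed_s": round(time.perf_counter() - t0, 3)}

        t0 = _stage("group_stats")
        stats_table = compare_groups(behavior, config.alpha_normality, tasks=task_cols)
        write_table(stats_table, out / "group_comparisons.tsv", index=False)
        screens = []
        for cov_name in ("education", "duration"):
            if cov_name in covariates.columns:
                cov = covariates[cov_name]
                scr = spearman_screen(behavior, cov, tasks=task_cols)
                scr.insert(0, "covariate", cov_name)
                screens.append(scr)
        if screens:
            write_table(pd.concat(screens), out / "covariate_screens.tsv", index=False)
        manifest["stages"]["group_stats"] = {
            "n_tasks": len(task_cols), "elapsed_s": round(time.perf_counter() - t0, 3)}
        if last < 1:
            return _finish(manifest, report, out)

        t0 = _stage("pca")
        model = fit_pca(std)
        stability = stability_select(std, config.pca_resamples,
                                     config.pca_subsample_fraction, config.pca_seed)
        k = stability.stable_count
        scores = project(std, model, n_components=k)
        write_table(pd.DataFrame({"eigenvalue": model.eigenvalues}),
                    out / "pca_eigenvalues.tsv")
        write_table(pd.DataFrame(model.loadings[:, :k],
                                 columns=[f"PC{i+1}" for i in range(k)]),
                    out / "pca_loadings.tsv")
        manifest["stages"]["pca"] = {
            "kaiser_count_full": model.n_components,
            "stable_count": k,
            "agreement_fraction": stability.agreement_fraction,
            "subspace_similarity": stability.subspace_similarity,
            "explained_variance_fraction": float(model.eigenvalues[:k].sum()
                                                / model.n_features),
            "elapsed_s": round(time.perf_counter() - t0, 3)}
        if last < 2:
            return _finish(manifest, report, out)

        t0 = _stage("scca")
        Y = behavior[task_cols].to_numpy(dtype=float)
        max_modes = min(config.max_modes, k, len(task_cols))
        modes = extract_modes(scores, Y, max_modes=max_modes, seed=config.scca_seed,
                              permutations=config.permutations, folds=config.folds,
                              ridge=config.ridge, grid=config.grid(),
                              alpha=config.alpha)
        cv = repeated_cv(scores, Y, repeats=config.cv_repeats, seed=config.scca_seed,
                         folds=config.folds, ridge=config.ridge, grid=config.grid())
        for mode in modes:
            write_table(pd.DataFrame({"w_brain": mode.w_brain}),
                        out / f"mode{mode.mode_index}_w_brain.tsv")
            write_table(pd.DataFrame({"task": task_cols, "w_behavior": mode.w_behavior}),
                        out / f"mode{mode.mode_index}_w_behavior.tsv", index=False)
            write_table(pd.DataFrame({
                "subject": behavior.index,
                "variate_brain": mode.variate_brain,
                "variate_behavior": mode.variate_behavior}),
                out / f"mode{mode.mode_index}_variates.tsv", index=False)
        write_table(pd.DataFrame({"test_fold_r": cv.test_fold_rs}),
                    out / "cv_test_fold_correlations.tsv")
        manifest["stages"]["scca"] = {
            "n_modes_fit": len(modes),
            "n_significant_modes": sum(bool(m.significant) for m in modes),
            "modes": [{"mode": m.mode_index, "r": m.canonical_r, "p_perm": m.p_perm,
                       "significant": bool(m.significant),
                       "c_brain": m.penalties.c_brain,
                       "c_behavior": m.penalties.c_behavior} for m in modes],
            "cv_median_r": cv.median, "cv_iqr": list(cv.iqr),
            "cv_n_correlations": int(cv.test_fold_rs.size),
            "elapsed_s": round(time.perf_counter() - t0, 3)}
        if last < 3:
            return _finish(manifest, report, out)

        t0 = _stage("interpretation")
        interp_summary = []
        for mode in modes:
            if not mode.significant:
                continue
            rep = compute_loadings(mode, behavior[task_cols], resid,
                                   parcellation=parcellation, k=config.top_k)
            write_table(rep.task_loadings.to_frame(),
                        out / f"mode{mode.mode_index}_task_loadings.tsv")
            write_table(rep.top_positive,
                        out / f"mode{mode.mode_index}_top_positive_edges.tsv", index=False)
            write_table(rep.top_negative,
                        out / f"mode{mode.mode_index}_top_negative_edges.tsv", index=False)
            cons = threshold_consistency(rep.edge_loadings, config.consistency_ks,
                                         parcellation)
            write_table(cons, out / f"mode{mode.mode_index}_threshold_consistency.tsv",
                        index=False)
            entry = {"mode": mode.mode_index,
                     "strongest_task": rep.task_loadings.abs().idxmax()}
            if {"education", "duration"}.issubset(covariates.columns):
                try:
                    mod = covariate_moderation(mode, covariates)
                    entry["moderation_p_behavior"] = mod.p_behavior
                    entry["moderation_behavior_significant"] = mod.behavior_significant
                except ValueError as exc:
                    log.warning("moderation skipped for mode %d: %s",
                                mode.mode_index, exc)
            interp_summary.append(entry)
        manifest["stages"]["interpretation"] = {
            "modes": interp_summary,
            "elapsed_s": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        stage = next(reversed(manifest["stages"]), "load")
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    return _finish(manifest, report, out)


def _finish(manifest: dict, report: ValidationReport, out: Path) -> dict:
    manifest["validation_warnings"] = report.warnings
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
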