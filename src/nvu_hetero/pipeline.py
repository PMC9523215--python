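"""End-to-end orchestration: simulate -> QC -> markers -> NMF ->
heterogeneity -> pathway activity -> potency, with a run manifest.

One global seed is supplied; each stage derives its own seed as
``seed + stage_index`` so toggling one stage does not shift another
stage's random stream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InputError
from .heterogeneity import NMIParams, discretize_equal_width, heterogeneity_test
from .markers import (NormalizedMatrix, find_markers, lognormalize,
                      select_hvg, top_k_markers)
from .nmf_consensus import consensus_filter, nmf_restarts
from .pathway_activity import (GeneSetCollection, differential_activity,
                               read_gmt, score_pathways)
from .potency import potency_score
from .qc_io import QCThresholds, qc_filter, write_matrix
from .synthetic_data import SimConfig, simulate_counts, write_dataset

STAGES = ("simulate", "qc", "markers", "nmf", "heterogeneity", "pathway", "potency")


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    sim: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)      # n_top (profile size)
    nmf: dict = field(default_factory=dict)          # k, restarts, threshold, knn, n_hvg
    heterogeneity: dict = field(default_factory=dict)  # NMIParams fields
    pathway: dict = field(default_factory=dict)      # gmt path or use_truth_sets
    potency: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    return int(seed) + STAGES.index(stage)


def run_pipeline(config: PipelineConfig):
    """Execute the enabled stages in order; returns (run dir, manifest dict)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": int(config.seed),
                "stages": list(config.stages), "stage_seeds": {}, "counts": {}}
    state: dict = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        seed = _stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        try:
            _STAGE_FNS[stage](config, seed, state, out, manifest)
        except Exception as e:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out, manifest


def _run_simulate(config, seed, state, out, manifest):
    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", seed)
    sim_cfg = SimConfig(**sim_kwargs)
    matrix, meta, truth = simulate_counts(sim_cfg)
    state.update(matrix=matrix, meta=meta, truth=truth, sim_cfg=sim_cfg)
    write_dataset(matrix, meta, truth, sim_cfg, out / "simulated")
    manifest["counts"]["simulate"] = {"genes": matrix.n_genes, "cells": matrix.n_cells}


def _run_qc(config, seed, state, out, manifest):
    thresholds = QCThresholds(**config.qc)
    matrix, meta, report = qc_filter(state["matrix"], state["meta"], thresholds)
    state.update(matrix=matrix, meta=meta, qc_report=report)
    write_matrix(matrix, meta, out / "filtered")
    (out / "qc_report.json").write_text(json.dumps(
        {"steps": report.steps, "retained_genes": report.retained_genes,
         "retained_cells": report.retained_cells}, indent=1))
    manifest["counts"]["qc"] = {"genes": report.retained_genes,
                                "cells": report.retained_cells,
                                "removed_per_rule": report.removals()}


def _run_markers(config, seed, state, out, manifest):
    norm = lognormalize(state["matrix"])
    state["norm"] = norm
    meta = state["meta"]
    groups = pd.Series(meta["group"].to_numpy(), index=meta["cell_id"])
    types = pd.Series(meta["cell_type"].to_numpy(), index=meta["cell_id"])
    n_top = config.markers.get("n_top", 100)
    young, old = config.sim.get("groups", ("young", "old"))
    tables, profiles = [], {}
    for t in sorted(types.unique()):
        cells = types.index[types == t]
        mask = np.isin(norm.cell_ids, cells)
        sub = NormalizedMatrix(norm.values[:, mask], norm.gene_ids,
                               norm.cell_ids[mask], norm.scale)
        try:
            tab = find_markers(sub, groups, old, young, cluster_name=t)
        except InputError as e:
            warnings.warn(f"skipping markers for {t}: {e}")
            continue
        tables.append(tab)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profiles[t] = top_k_markers(tab, t, n_top)
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "markers.tsv", sep="\t", index=False)
    state.update(marker_table=table, profiles=profiles)
    manifest["counts"]["markers"] = {
        "cell_types": len(profiles),
        "significant": int(table["significant"].sum())}


def _run_nmf(config, seed, state, out, manifest):
    p = config.nmf
    norm = state.get("norm") or lognormalize(state["matrix"])
    hvgs = select_hvg(state["matrix"], min(p.get("n_hvg", 2000),
                                           state["matrix"].n_genes))
    X = norm.restrict_genes(hvgs).to_dense().T  # cells x HVGs, non-negative
    decomps = nmf_restarts(X, k=p.get("k", 16), n_restarts=p.get("restarts", 10),
                           seed=seed)
    res = consensus_filter(decomps, knn=p.get("knn"),
                           threshold=p.get("threshold", 0.2))
    np.savetxt(out / "consensus_spectra.tsv", res.consensus_spectra, delimiter="\t")
    (out / "nmf_consensus.json").write_text(json.dumps({
        "pool": int(len(res.restart_of)), "removed": res.removed.tolist(),
        "threshold": res.threshold,
        "mean_knn_distance": res.mean_knn_distance.tolist()}, indent=1))
    state["nmf"] = res
    manifest["counts"]["nmf"] = {"pool": int(len(res.restart_of)),
                                 "removed": int(len(res.removed)),
                                 "consensus": int(res.consensus_spectra.shape[0])}


def _run_heterogeneity(config, seed, state, out, manifest):
    params_kwargs = dict(config.heterogeneity)
    params_kwargs.setdefault("seed", seed)
    norm = state.get("norm") or lognormalize(state["matrix"])
    meta = state["meta"]
    types = pd.Series(meta["cell_type"].to_numpy(), index=meta["cell_id"])
    groups = pd.Series(meta["group"].to_numpy(), index=meta["cell_id"])
    young, old = config.sim.get("groups", ("young", "old"))
    rows, full = [], {}
    for t, profile_genes in sorted(state["profiles"].items()):
        params = NMIParams(**params_kwargs)
        cells_mask = np.isin(norm.cell_ids, types.index[types == t])
        sub = norm.restrict_genes(profile_genes)
        vals = np.asarray(sub.values[:, cells_mask].todense()).T  # cells x genes
        prof = discretize_equal_width(vals, params.n_bins,
                                      cell_ids=norm.cell_ids[cells_mask],
                                      gene_ids=profile_genes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = heterogeneity_test(prof, groups, params, group_a=young, group_b=old)
        rows.append({"cell_type": t, "median_A": float(np.median(res.medians_a)),
                     "median_B": float(np.median(res.medians_b)),
                     "D": res.observed_diff, "p_value": res.p_value,
                     "direction": res.direction})
        full[t] = {"medians_" + res.group_a: res.medians_a.tolist(),
                   "medians_" + res.group_b: res.medians_b.tolist()}
    report = pd.DataFrame(rows)
    if rows:  # raw p per type, BH across types offered alongside
        from statsmodels.stats.multitest import multipletests
        report["adj_p"] = multipletests(report["p_value"], method="fdr_bh")[1]
    report.to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
    (out / "heterogeneity_replicates.json").write_text(json.dumps(full, indent=1))
    state["heterogeneity"] = report
    manifest["counts"]["heterogeneity"] = {
        "cell_types": len(rows),
        "significant": int((report["p_value"] < 0.05).sum()) if rows else 0}


def _run_pathway(config, seed, state, out, manifest):
    p = config.pathway
    norm = state.get("norm") or lognormalize(state["matrix"])
    if p.get("gmt"):
        sets = read_gmt(p["gmt"])
    elif state.get("truth") is not None and state["truth"].pathway_genes:
        sets = GeneSetCollection(dict(state["truth"].pathway_genes), "simulated")
    else:
        manifest["counts"]["pathway"] = {"pathways": 0}
        warnings.warn("no gene sets available; pathway stage skipped")
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = score_pathways(norm, sets, min_genes=p.get("min_genes", 3))
    meta = state["meta"]
    groups = pd.Series(meta["group"].to_numpy(), index=meta["cell_id"])
    young, old = config.sim.get("groups", ("young", "old"))
    diff = differential_activity(scores, groups, group_a=old, group_b=young)
    scores.to_csv(out / "pathway_scores.tsv", sep="\t")
    diff.to_csv(out / "pathway_differential.tsv", sep="\t", index=False)
    state["pathway"] = diff
    manifest["counts"]["pathway"] = {
        "pathways": int(scores.shape[1]),
        "significant": int((diff["adj_p"] < 0.05).sum())}


def _run_potency(config, seed, state, out, manifest):
    p = config.potency
    res = potency_score(state["matrix"], n_top=p.get("n_top", 200),
                        knn=min(p.get("knn", 30), state["matrix"].n_cells - 1),
                        n_smooth=p.get("n_smooth", 2))
    pd.DataFrame({"cell_id": res.cell_ids, "gcs": res.gcs,
                  "raw_score": res.raw_score, "smoothed": res.smoothed,
                  "rank_norm": res.score}).to_csv(
        out / "potency.tsv", sep="\t", index=False)
    state["potency"] = res
    manifest["counts"]["potency"] = {"cells": int(len(res.cell_ids))}


_STAGE_FNS = {
    "simulate": _run_simulate,
    "qc": _run_qc,
    "markers": _run_markers,
    "nmf": _run_nmf,
    "heterogeneity": _run_heterogeneity,
    "pathway": _run_pathway,
    "potency": _run_potency,
}
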