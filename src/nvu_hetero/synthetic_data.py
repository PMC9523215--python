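"""Seeded synthetic single-cell datasets with planted structure.

The generator emulates a two-group (young/old) brain single-cell count
matrix: each cell type carries a small number of expression *programs*
(gene sets with log-scale loadings) whose per-cell weights are lognormal;
the ``heterogeneity_factor`` multiplies the log-sd of those weights for a
chosen (cell type, group), which is the single knob that lowers within-type
pairwise NMI. Per-type differential genes between the groups are planted
inside the program genes so that the 100-gene DE profiles used by the
heterogeneity statistic actually carry the program-weight noise. Counts
are negative binomial around library-size-scaled means; mitochondrial and
hemoglobin genes carry reserved name prefixes for the QC rules; an
optional cell type carries a nested-repertoire differentiation gradient.

Energy-table fixtures for the MM/GBSA module are generated here as well.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .qc_io import ExpressionMatrix, write_matrix

_DEFAULT_TYPE_NAMES = ["AC", "CPC", "EC", "MG", "OLG", "OPC", "PC", "SMC",
                       "EPC", "MAC", "MNC", "mNeur", "NRP", "hbEC"]


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    heterogeneity_factor maps cell type -> {group: multiplier >= 1} applied
    to the log-sd of the per-cell program weights. pathway_shift maps
    (pathway name, group) -> additive log-mean shift applied to that
    pathway's member genes in that group. pathways maps name -> gene-set
    size; the member genes are drawn by the generator and recorded in
    SimTruth.
    """

    n_genes: int = 1000
    n_cell_types: int = 5
    cells_per_type_per_group: int = 200
    groups: tuple = ("young", "old")
    nb_mean_range: tuple = (1.0, 5.0)
    nb_dispersion: float = 10.0
    heterogeneity_factor: dict = field(default_factory=dict)
    n_mito_genes: int = 13
    n_hb_genes: int = 6
    pathways: dict = field(default_factory=dict)
    pathway_shift: dict = field(default_factory=dict)
    gradient_type: str | None = None
    seed: int = 0
    # program / noise architecture
    n_programs_per_type: int = 3
    program_size: int = 50
    program_loading_range: tuple = (0.5, 2.0)
    n_de_genes: int = 100
    de_log_fc: float = 0.8
    program_noise_sd: float = 0.35   # per-gene program-weight noise (the knob base)
    program_weight_sd: float = 0.35  # per-program scalar weight noise
    library_log_sd: float = 0.3
    hb_base_mean: float = 0.05  # sporadic hemoglobin detection (contamination-like)
    count_noise: str = "nb"  # "nb" or "none" (deterministic rounded means)
    cell_type_names: list | None = None

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_types", "cells_per_type_per_group"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if len(self.groups) != 2:
            raise ConfigurationError("exactly two groups are required")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not (0 < self.nb_mean_range[0] <= self.nb_mean_range[1]):
            raise ConfigurationError("nb_mean_range must be a positive interval")
        for t, per_group in self.heterogeneity_factor.items():
            for g, mult in per_group.items():
                if mult < 1:
                    raise ConfigurationError(
                        f"heterogeneity multiplier for ({t},{g}) must be >= 1")
        if min(self.n_mito_genes, self.n_hb_genes) < 0:
            raise ConfigurationError("planted QC gene counts must be >= 0")
        if self.count_noise not in ("nb", "none"):
            raise ConfigurationError("count_noise must be 'nb' or 'none'")

    def type_names(self) -> list:
        if self.cell_type_names is not None:
            return list(self.cell_type_names)
        names = list(_DEFAULT_TYPE_NAMES)
        while len(names) < self.n_cell_types:
            names.append(f"type{len(names)}")
        return names[: self.n_cell_types]


@dataclass
class SimTruth:
    """Ground truth recorded by the generator."""

    cell_types: pd.Series            # cell_id -> cell type
    groups: pd.Series                # cell_id -> group
    programs: dict                   # type -> list of (gene_id array, loading array)
    de_genes: dict                   # type -> DataFrame(gene, sign)
    pathway_genes: dict              # pathway name -> list of gene ids
    shifted_pathways: dict           # (pathway, group) -> shift
    potency: pd.Series | None        # cell_id -> true potency in [0,1]
    means: np.ndarray                # genes x cells expected NB means

    def program_gene_ids(self, cell_type: str) -> np.ndarray:
        return np.concatenate([g for g, _ in self.programs[cell_type]])


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, size: float) -> np.ndarray:
    # gamma-Poisson mixture == NB(mean=mu, size); robust to extreme means
    out = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    lam = rng.gamma(size, np.minimum(mu[pos], 1e9) / size)
    out[pos] = rng.poisson(lam)
    return out


def simulate_counts(config: SimConfig):
    """Generate (ExpressionMatrix, CellMeta DataFrame, SimTruth); seeded."""
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    types = config.type_names()

    gene_ids = np.array([f"gene{i:05d}" for i in range(G)], dtype=object)
    for i in range(config.n_mito_genes):
        gene_ids[i] = f"mt-sim{i + 1}"
    for i in range(config.n_hb_genes):
        prefix = "Hba" if i % 2 == 0 else "Hbb"
        gene_ids[config.n_mito_genes + i] = f"{prefix}-sim{i + 1}"
    if config.n_mito_genes + config.n_hb_genes > G:
        raise ConfigurationError("more planted QC genes than genes")

    base_mean = rng.uniform(*config.nb_mean_range, size=G)
    if config.n_hb_genes:
        base_mean[config.n_mito_genes:
                  config.n_mito_genes + config.n_hb_genes] = config.hb_base_mean
    log_base = np.log(base_mean)

    # Assign program and pathway genes from the non-QC gene pool.
    pool = np.arange(config.n_mito_genes + config.n_hb_genes, G)
    rng.shuffle(pool)
    need = config.n_cell_types * config.n_programs_per_type * config.program_size
    if need > len(pool):
        raise ConfigurationError(
            f"program layout needs {need} genes but only {len(pool)} available")
    cursor = 0
    programs: dict = {}
    prog_idx: dict = {}
    for t in types:
        programs[t], prog_idx[t] = [], []
        for _ in range(config.n_programs_per_type):
            idx = np.sort(pool[cursor: cursor + config.program_size])
            cursor += config.program_size
            loadings = rng.uniform(*config.program_loading_range, size=len(idx))
            programs[t].append((gene_ids[idx], loadings))
            prog_idx[t].append((idx, loadings))

    pathway_genes: dict = {}
    pathway_idx: dict = {}
    for name, size in config.pathways.items():
        if cursor + size > len(pool):
            raise ConfigurationError("not enough genes left for pathway sets")
        idx = np.sort(pool[cursor: cursor + size])
        cursor += size
        pathway_genes[name] = list(gene_ids[idx])
        pathway_idx[name] = idx

    de_genes: dict = {}
    de_idx: dict = {}
    for t in types:
        all_prog = (np.concatenate([i for i, _ in prog_idx[t]])
                    if prog_idx[t] else np.array([], dtype=np.int64))
        n_de = min(config.n_de_genes, len(all_prog))
        if 0 < n_de < config.n_de_genes or (config.n_de_genes and not len(all_prog)):
            warnings.warn(f"only {n_de} program genes available for DE planting in {t}")
        chosen = (rng.choice(all_prog, size=n_de, replace=False)
                  if n_de else np.array([], dtype=np.int64))
        signs = rng.choice([-1.0, 1.0], size=n_de)
        de_idx[t] = (chosen, signs)
        de_genes[t] = pd.DataFrame({"gene": gene_ids[chosen], "sign": signs})

    n_per = config.cells_per_type_per_group
    n_cells = config.n_cell_types * 2 * n_per
    cell_ids, cell_type_col, group_col = [], [], []
    means = np.zeros((G, n_cells))
    potency_vals: dict = {}
    counts = np.zeros((G, n_cells), dtype=np.int64)

    c = 0
    for t in types:
        grad_rank = 0
        n_type = 2 * n_per
        for g in config.groups:
            h = config.heterogeneity_factor.get(t, {}).get(g, 1.0)
            sigma = config.program_noise_sd * h
            w_sigma = config.program_weight_sd
            for _ in range(n_per):
                cid = f"{t}_{g}_{c:05d}"
                cell_ids.append(cid)
                cell_type_col.append(t)
                group_col.append(g)
                log_mu = log_base.copy()
                for idx, loadings in prog_idx[t]:
                    # scalar program weight (usage variation across cells)
                    w = (rng.lognormal(mean=-0.5 * w_sigma**2, sigma=w_sigma)
                         if w_sigma > 0 else 1.0)
                    log_mu[idx] += w * loadings
                    # per-gene program-weight perturbation: lognormal on the
                    # linear-mean scale; its log-sd carries the heterogeneity knob
                    if sigma > 0:
                        log_mu[idx] += rng.normal(-0.5 * sigma**2, sigma, len(idx))
                # DE shift split symmetrically across the groups so that the
                # cross-gene structure of the profile is group-balanced
                idx, signs = de_idx[t]
                half = 0.5 * config.de_log_fc
                log_mu[idx] += signs * (half if g == config.groups[1] else -half)
                for (name, grp), shift in config.pathway_shift.items():
                    if grp == g:
                        log_mu[pathway_idx[name]] += shift
                mu = np.exp(log_mu)
                if t == config.gradient_type:
                    grad_rank += 1
                    f = grad_rank / n_type
                    rep = np.concatenate([i for i, _ in prog_idx[t]])
                    n_on = int(np.ceil(f * len(rep)))
                    mu[rep[n_on:]] = 0.0
                    potency_vals[cid] = f
                lib = (np.exp(rng.normal(0.0, config.library_log_sd))
                       if config.library_log_sd > 0 else 1.0)
                mu *= lib
                means[:, c] = mu
                if config.count_noise == "nb":
                    counts[:, c] = _nb_sample(rng, mu, config.nb_dispersion)
                else:
                    counts[:, c] = np.rint(mu).astype(np.int64)
                c += 1

    matrix = ExpressionMatrix(counts, gene_ids, np.array(cell_ids, dtype=object))
    meta = pd.DataFrame(
        {"cell_id": cell_ids, "group": group_col, "cell_type": cell_type_col})
    truth = SimTruth(
        cell_types=pd.Series(cell_type_col, index=cell_ids),
        groups=pd.Series(group_col, index=cell_ids),
        programs=programs,
        de_genes=de_genes,
        pathway_genes=pathway_genes,
        shifted_pathways=dict(config.pathway_shift),
        potency=pd.Series(potency_vals) if potency_vals else None,
        means=means,
    )
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# Energy-table fixtures for the MM/GBSA module.

_ENERGY_COMPONENTS = ("Ebond", "Eangle", "Etorsion", "EVDW", "Eelec", "EGB", "SASA")

_DEFAULT_ENERGY_PARAMS = {
    # role -> component -> (mean kcal/mol or A^2 for SASA, sd)
    "complex": {"Ebond": (310.0, 4.0), "Eangle": (820.0, 6.0), "Etorsion": (1050.0, 5.0),
                "EVDW": (-320.0, 5.0), "Eelec": (-2750.0, 12.0), "EGB": (-480.0, 8.0),
                "SASA": (13800.0, 90.0)},
    "receptor": {"Ebond": (300.0, 4.0), "Eangle": (800.0, 6.0), "Etorsion": (1020.0, 5.0),
                 "EVDW": (-280.0, 5.0), "Eelec": (-2650.0, 12.0), "EGB": (-450.0, 8.0),
                 "SASA": (13500.0, 90.0)},
    "ligand": {"Ebond": (10.0, 0.5), "Eangle": (20.0, 0.8), "Etorsion": (30.0, 0.9),
               "EVDW": (-5.0, 0.6), "Eelec": (-80.0, 2.0), "EGB": (-55.0, 1.5),
               "SASA": (700.0, 15.0)},
}


def simulate_energy_tables(n_frames: int, seed: int, params: dict | None = None,
                           t0_ns: float = 20.0, dt_ns: float = 0.1) -> dict:
    """Per-frame MM/GBSA component tables for complex/receptor/ligand.

    Components are independent normals with role/component-specific means
    and sds (overridable via ``params``); frame times start at ``t0_ns``.
    Returns {"complex": DataFrame, "receptor": ..., "ligand": ...} with a
    time_ns column plus the seven component columns.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    params = params or _DEFAULT_ENERGY_PARAMS
    rng = np.random.default_rng(seed)
    times = t0_ns + dt_ns * np.arange(n_frames)
    out = {}
    for role in ("complex", "receptor", "ligand"):
        cols = {"time_ns": times}
        for comp in _ENERGY_COMPONENTS:
            mean, sd = params[role][comp]
            cols[comp] = rng.normal(mean, sd, size=n_frames) if sd > 0 \
                else np.full(n_frames, float(mean))
        out[role] = pd.DataFrame(cols)
    return out


# ---------------------------------------------------------------------------
# Dataset serialization.

def write_dataset(matrix: ExpressionMatrix, meta: pd.DataFrame, truth: SimTruth,
                  config: SimConfig, outdir) -> Path:
    """Write MTX triplet + cell_meta.tsv + truth.json + config.yaml."""
    d = Path(outdir)
    write_matrix(matrix, meta, d)
    truth_summary = {
        "programs": {t: [list(map(str, g)) for g, _ in progs]
                     for t, progs in truth.programs.items()},
        "de_genes": {t: df["gene"].tolist() for t, df in truth.de_genes.items()},
        "pathway_genes": truth.pathway_genes,
        "shifted_pathways": {f"{k[0]}|{k[1]}": v
                             for k, v in truth.shifted_pathways.items()},
        "potency": truth.potency.to_dict() if truth.potency is not None else None,
        "seed": config.seed,
    }
    (d / "truth.json").write_text(json.dumps(truth_summary, indent=1))
    cfg = asdict(config)
    cfg["groups"] = list(cfg["groups"])
    cfg["pathway_shift"] = {f"{k[0]}|{k[1]}": v for k, v in cfg["pathway_shift"].items()}
    (d / "config.yaml").write_text(yaml.safe_dump(cfg))
    return d
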