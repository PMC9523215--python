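"""Pairwise-NMI transcriptional heterogeneity with subsampled resampling.

For one cell type, expression of its ~100 differential genes is
discretized per gene into equal-width bins; normalized mutual information
(NMI) between the bin vectors of two cells measures how similar their
transcriptional states are, so a *lower* median pairwise NMI within a
population means *higher* heterogeneity. Class imbalance between the two
condition groups is handled by repeatedly subsampling an equal number of
cells from each group and recording the median pairwise NMI per draw; the
observed statistic is the difference of the two groups' median-of-medians,
and its p-value comes from a symmetric sign comparison of the replicate
medians with tie-splitting and a 1/R floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class DiscretizedProfile:
    """Cells x genes matrix of integer bin indices in [0, n_bins)."""

    bins: np.ndarray
    n_bins: int
    edges: np.ndarray  # genes x (n_bins+1) bin edges
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.int64)
        if self.bins.size and (self.bins.min() < 0 or self.bins.max() >= self.n_bins):
            raise InputError("bin index out of range")


@dataclass
class NMIParams:
    """Subsampling and NMI parameters (defaults follow the study design)."""

    n_genes_profile: int = 100
    n_cells_per_class: int = 100
    n_replicates: int = 100
    n_bins: int = 10
    normalization: str = "arithmetic"  # arithmetic | geometric | min | max
    seed: int = 0
    share_replicate_rng: bool = False  # common random numbers across groups

    def __post_init__(self) -> None:
        if min(self.n_genes_profile, self.n_cells_per_class, self.n_replicates) <= 0:
            raise InputError("all NMI parameters must be positive")
        if self.n_bins < 2:
            raise InputError("need at least 2 bins")
        if self.normalization not in ("arithmetic", "geometric", "min", "max"):
            raise InputError(f"unknown normalization {self.normalization!r}")


@dataclass
class HeterogeneityResult:
    """Replicate medians, observed difference and resampling p-value."""

    group_a: str
    group_b: str
    medians_a: np.ndarray
    medians_b: np.ndarray
    observed_diff: float  # median_r m_A(r) - median_r m_B(r)
    p_value: float
    direction: str  # which group has the lower median NMI (more heterogeneous)
    draws: list | None = None


def discretize_equal_width(values: np.ndarray, n_bins: int,
                           cell_ids=None, gene_ids=None) -> DiscretizedProfile:
    """Per-gene equal-width binning over the range observed across cells.

    ``values`` is cells x genes. Bins are right-closed ((lo, hi], with the
    first bin closed on both sides), so the per-gene maximum falls in bin
    n_bins-1 and a constant gene puts every cell in bin 0.
    """
    if n_bins < 2:
        raise InputError("need at least 2 bins")
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] == 0:
        raise InputError("empty gene selection")
    n_cells, n_genes = values.shape
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    width = (hi - lo) / n_bins
    edges = lo[:, None] + width[:, None] * np.arange(n_bins + 1)[None, :]
    bins = np.zeros_like(values, dtype=np.int64)
    for g in range(n_genes):
        if width[g] == 0:
            continue  # constant gene -> bin 0
        bins[:, g] = np.digitize(values[:, g], edges[g, 1:-1], right=True)
    return DiscretizedProfile(
        bins, n_bins, edges,
        np.asarray(cell_ids if cell_ids is not None else np.arange(n_cells), dtype=object),
        np.asarray(gene_ids if gene_ids is not None else np.arange(n_genes), dtype=object),
    )


_H_TOL = 1e-12  # entropies below this are float noise around zero


def _normalize_mi(mi, hx, hy, normalization):
    hx = np.where(np.asarray(hx) > _H_TOL, hx, 0.0)
    hy = np.where(np.asarray(hy) > _H_TOL, hy, 0.0)
    if normalization == "arithmetic":
        denom = 0.5 * (hx + hy)
    elif normalization == "geometric":
        denom = np.sqrt(hx * hy)
    elif normalization == "min":
        denom = np.minimum(hx, hy)
    else:
        denom = np.maximum(hx, hy)
    zero = (hx == 0.0) | (hy == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(zero, 0.0, mi / np.maximum(denom, 1e-300))
    return np.clip(out, 0.0, 1.0)


def nmi_pair(x, y, normalization: str = "arithmetic") -> float:
    """Plug-in NMI between two equal-length bin vectors; symmetric, in [0,1].

    Mutual information is computed from the joint histogram of (x_g, y_g)
    over genes g; a zero-entropy (constant) vector yields 0 by convention.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("bin vectors must be 1-D and of equal length")
    if len(x) < 2:
        raise InputError("need at least 2 genes")
    n = len(x)
    if x.min() < 0 or y.min() < 0:
        raise InputError("bin indices must be non-negative")
    bx, by = int(x.max()) + 1, int(y.max()) + 1
    joint = np.bincount(x * by + y, minlength=bx * by).reshape(bx, by) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())
    hx = float(-(px[px > 0] * np.log(px[px > 0])).sum())  # empty bins drop out
    hy = float(-(py[py > 0] * np.log(py[py > 0])).sum())
    return float(_normalize_mi(np.array(mi), np.array(hx), np.array(hy), normalization))


def pairwise_nmi(bins: np.ndarray, n_bins: int,
                 normalization: str = "arithmetic") -> np.ndarray:
    """All-pairs NMI for a cells x genes bin matrix (vectorized).

    Returns the symmetric n_cells x n_cells matrix; equals nmi_pair applied
    to every pair (the diagonal holds each cell's self-NMI).
    """
    bins = np.asarray(bins, dtype=np.int64)
    n, G = bins.shape
    onehot = np.stack([(bins == b) for b in range(n_bins)]).astype(np.float64)  # B,n,G
    joint = np.einsum("ang,bmg->abnm", onehot, onehot) / G                      # B,B,n,n
    marg = onehot.sum(axis=2) / G                                               # B,n
    with np.errstate(invalid="ignore", divide="ignore"):
        h = -(marg * np.where(marg > 0, np.log(np.maximum(marg, 1e-300)), 0.0)).sum(axis=0)
        denom = marg[:, None, :, None] * marg[None, :, None, :]
        term = joint * (np.log(np.maximum(joint, 1e-300))
                        - np.log(np.maximum(denom, 1e-300)))
    term[joint <= 0] = 0.0
    mi = term.sum(axis=(0, 1))
    return _normalize_mi(mi, h[:, None], h[None, :], normalization)


def median_pairwise_nmi(bins: np.ndarray, n_bins: int,
                        normalization: str = "arithmetic") -> float:
    """Median NMI over all unordered distinct cell pairs."""
    mat = pairwise_nmi(bins, n_bins, normalization)
    iu = np.triu_indices(mat.shape[0], k=1)
    return float(np.median(mat[iu]))


def resampling_p_value(medians_a: np.ndarray, medians_b: np.ndarray) -> float:
    """Two-sided sign-comparison p with tie-splitting and a 1/R floor.

    p = 2 * min(#(A>B) + ties/2, #(A<B) + ties/2) / R, clamped to [1/R, 1].
    """
    medians_a = np.asarray(medians_a, dtype=float)
    medians_b = np.asarray(medians_b, dtype=float)
    r = len(medians_a)
    gt = int((medians_a > medians_b).sum())
    lt = int((medians_a < medians_b).sum())
    ties = r - gt - lt
    p = 2.0 * min(gt + ties / 2.0, lt + ties / 2.0) / r
    return float(min(max(p, 1.0 / r), 1.0))


def heterogeneity_test(profile: DiscretizedProfile, groups: pd.Series,
                       params: NMIParams, group_a=None, group_b=None,
                       keep_draws: bool = False) -> HeterogeneityResult:
    """Class-balanced subsampled median-NMI comparison of two groups.

    ``groups`` maps cell id -> group label. Per replicate and group,
    ``n_cells_per_class`` cells are drawn (without replacement when the
    group is large enough, otherwise with replacement and a warning) and
    the median pairwise NMI among them recorded. With
    ``share_replicate_rng`` each replicate reuses one RNG substream for
    both groups (common random numbers; only meaningful when the groups
    hold identical cell multisets in identical order).
    """
    lab = groups.reindex(profile.cell_ids)
    if lab.isna().any():
        raise InputError("group labels missing for some cells")
    levels = list(pd.unique(lab)) if group_a is None else [group_a, group_b]
    if len(levels) != 2 or any(l is None for l in levels):
        raise InputError("exactly two groups are required")
    ga, gb = levels
    idx = {g: np.flatnonzero((lab == g).to_numpy()) for g in (ga, gb)}
    for g, ix in idx.items():
        if len(ix) < 2:
            raise InputError(f"group {g!r} has fewer than 2 cells")
        if len(ix) < params.n_cells_per_class:
            warnings.warn(f"group {g!r} has {len(ix)} < {params.n_cells_per_class} "
                          "cells; sampling with replacement")

    root = np.random.SeedSequence(params.seed)
    medians = {ga: np.empty(params.n_replicates), gb: np.empty(params.n_replicates)}
    draws: list = []
    for r_i in range(params.n_replicates):
        rep_children = root.spawn(1)[0] if params.share_replicate_rng else None
        rec = {}
        for g in (ga, gb):
            if params.share_replicate_rng:
                rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=rep_children.entropy, spawn_key=rep_children.spawn_key))
            else:
                rng = np.random.default_rng(root.spawn(1)[0])
            ix = idx[g]
            replace = len(ix) < params.n_cells_per_class
            chosen = rng.choice(len(ix), size=params.n_cells_per_class, replace=replace)
            cells = ix[chosen]
            medians[g][r_i] = median_pairwise_nmi(
                profile.bins[cells], profile.n_bins, params.normalization)
            rec[g] = cells
        if keep_draws:
            draws.append(rec)

    d = float(np.median(medians[ga]) - np.median(medians[gb]))
    p = resampling_p_value(medians[ga], medians[gb])
    direction = str(ga) if d < 0 else (str(gb) if d > 0 else "none")
    return HeterogeneityResult(str(ga), str(gb), medians[ga], medians[gb], d, p,
                               direction, draws if keep_draws else None)
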