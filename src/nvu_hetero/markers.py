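"""Log-normalization, highly-variable-gene selection and marker tests.

Differential expression follows the common single-cell convention: a
two-sided Wilcoxon rank-sum test on log-normalized values, a natural-log
fold change computed on de-logged group means with a pseudocount of 1, and
Benjamini-Hochberg adjustment; a gene is flagged significant when
|log FC| > 0.25 and p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .qc_io import ExpressionMatrix

LOGFC_THRESHOLD = 0.25
P_THRESHOLD = 0.05


@dataclass
class NormalizedMatrix:
    """ln(1 + scale * count / cell_total) values, genes x cells."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale: float = 1e4
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def restrict_genes(self, genes) -> "NormalizedMatrix":
        order = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in order]
        if missing:
            raise InputError(f"unknown genes requested, e.g. {missing[:3]}")
        idx = np.array([order[g] for g in genes])
        return NormalizedMatrix(self.values[idx], self.gene_ids[idx],
                                self.cell_ids, self.scale, self.pseudocount)


def lognormalize(m: ExpressionMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalize to ``scale`` counts per cell, then ln(1+x)."""
    if scale <= 0:
        raise InputError("scale must be positive")
    X = m.values.tocsc().astype(float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} cells have zero total counts")
    factors = np.where(totals > 0, scale / np.maximum(totals, 1), 0.0)
    X = X.multiply(factors[None, :]).tocsr()  # broadcasts across rows
    np.log1p(X.data, out=X.data)
    return NormalizedMatrix(X, m.gene_ids.copy(), m.cell_ids.copy(), scale=scale)


def _row_mean_var(X: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[1]
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def standardized_variance(m: ExpressionMatrix) -> np.ndarray:
    """vst-style standardized variance per gene on raw counts.

    Fits log10(variance) on log10(mean) with a second-degree polynomial,
    standardizes counts by the fitted sd, clips at sqrt(n_cells), and
    returns the variance of the clipped standardized values.
    """
    X = m.values.tocsr().astype(float)
    n = m.n_cells
    mean, var = _row_mean_var(X)
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() >= 3:
        lx, ly = np.log10(mean[fit_mask]), np.log10(var[fit_mask])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            coef = np.polyfit(lx, ly, 2)
            # second, robust pass: drop high positive residuals (the HVGs
            # themselves) so they cannot inflate the fitted trend
            resid = ly - np.polyval(coef, lx)
            keep = resid <= np.quantile(resid, 0.9)
            if keep.sum() >= 3:
                coef = np.polyfit(lx[keep], ly[keep], 2)
        exp_var = 10 ** np.polyval(coef, np.log10(np.maximum(mean, 1e-12)))
    else:  # too few genes to fit a trend; fall back to the raw variance
        exp_var = np.maximum(var, 1e-12)
    exp_sd = np.sqrt(exp_var)
    clip = np.sqrt(n)

    out = np.zeros(m.n_genes)
    indptr, data = X.indptr, X.data
    for g in range(m.n_genes):
        if not fit_mask[g]:
            continue
        vals = data[indptr[g]: indptr[g + 1]]
        z_nz = np.minimum((vals - mean[g]) / exp_sd[g], clip)
        z0 = min(-mean[g] / exp_sd[g], clip)
        n0 = n - len(vals)
        mu_z = (z0 * n0 + z_nz.sum()) / n
        ss = n0 * (z0 - mu_z) ** 2 + ((z_nz - mu_z) ** 2).sum()
        out[g] = ss / max(n - 1, 1)
    return out


def select_hvg(m: ExpressionMatrix, n: int = 2000) -> list:
    """Top-n genes by standardized variance; ties broken by gene id."""
    if n > m.n_genes:
        raise InputError(f"requested {n} HVGs from {m.n_genes} genes")
    sv = standardized_variance(m)
    order = np.lexsort((np.asarray(m.gene_ids, dtype=str), -sv))
    return list(m.gene_ids[order[:n]])


def find_markers(m: NormalizedMatrix, labels: pd.Series, group_a, group_b=None,
                 cluster_name=None) -> pd.DataFrame:
    """Wilcoxon rank-sum markers for ``group_a`` vs ``group_b`` (or vs rest).

    ``labels`` maps cell id -> cluster/group label. Returns a MarkerTable
    DataFrame (gene, cluster, log_fc, p_value, adj_p, pct_in, pct_out,
    significant).
    """
    lab = labels.reindex(m.cell_ids)
    if lab.isna().any():
        raise InputError("labels missing for some cells")
    mask_a = (lab == group_a).to_numpy()
    mask_b = (lab == group_b).to_numpy() if group_b is not None else ~mask_a
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise InputError("each side of the contrast needs >= 3 cells")

    A = np.asarray(m.values[:, mask_a].todense())
    B = np.asarray(m.values[:, mask_b].todense())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes give degenerate U
        res = mannwhitneyu(A, B, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    constant = (A.std(axis=1) == 0) & (B.std(axis=1) == 0) & \
               (A.mean(axis=1) == B.mean(axis=1))
    p[np.isnan(p) | constant] = 1.0

    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    log_fc = np.log((mean_a + 1.0) / (mean_b + 1.0))
    adj_p = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "gene": m.gene_ids,
        "cluster": cluster_name if cluster_name is not None else str(group_a),
        "log_fc": log_fc,
        "p_value": p,
        "adj_p": adj_p,
        "pct_in": (A > 0).mean(axis=1),
        "pct_out": (B > 0).mean(axis=1),
    })
    table["significant"] = (table["log_fc"].abs() > LOGFC_THRESHOLD) & \
                           (table["p_value"] < P_THRESHOLD)
    return table


def top_k_markers(table: pd.DataFrame, cluster, k: int = 100) -> list:
    """Top-k genes for a cluster: by p, then |log_fc|, then gene id.

    If fewer than k genes are significant, the list is padded with the
    best-ranked non-significant genes (with a warning).
    """
    sub = table[table["cluster"] == cluster]
    if sub.empty:
        raise InputError(f"no rows for cluster {cluster!r}")
    ranked = sub.assign(_abs_fc=sub["log_fc"].abs()).sort_values(
        ["p_value", "_abs_fc", "gene"], ascending=[True, False, True])
    sig = ranked[ranked["significant"]]
    if len(sig) >= k:
        return sig["gene"].head(k).tolist()
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} genes available for cluster {cluster!r}")
        return ranked["gene"].tolist()
    warnings.warn(
        f"only {len(sig)} significant genes for cluster {cluster!r}; padding by rank")
    return ranked["gene"].head(k).tolist()
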