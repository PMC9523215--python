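"""Gene-count differentiation-potency score with kNN smoothing.

The raw feature is the per-cell gene count (number of genes detected),
which tends to be higher in less differentiated cells. The score refines
it by (1) correlating every gene's log-normalized expression with the
gene-count vector, (2) averaging the log-normalized expression of the top
correlated genes, (3) smoothing over a cosine kNN graph built on a PCA
embedding of highly variable genes (two averaging passes by default), and
(4) rank-normalizing to [0, 1]. Higher score = less differentiated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import InputError
from .markers import lognormalize, select_hvg
from .qc_io import ExpressionMatrix


@dataclass
class PotencyScore:
    cell_ids: np.ndarray
    gcs: np.ndarray          # genes detected per cell
    raw_score: np.ndarray    # mean log-norm expression of top-correlated genes
    smoothed: np.ndarray
    score: np.ndarray        # rank-normalized to [0, 1]
    top_genes: list


def gene_counts(m: ExpressionMatrix) -> np.ndarray:
    """Genes detected (count > 0) per cell."""
    if m.n_genes == 0 or m.n_cells == 0:
        raise InputError("empty matrix")
    return np.asarray((m.values > 0).sum(axis=0)).ravel().astype(np.int64)


def _pearson_with_vector(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of X (genes x cells) with v; 0 where degenerate."""
    v = v - v.mean()
    sv = np.sqrt((v**2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ v) / np.maximum(sx * sv, 1e-300)
    r[(sx == 0) | (sv == 0)] = 0.0
    return r


def potency_score(m: ExpressionMatrix, n_top: int = 200, knn: int = 30,
                  n_smooth: int = 2, n_hvg: int = 2000,
                  n_pcs: int = 30) -> PotencyScore:
    """Differentiation-potency score per cell (higher = less differentiated)."""
    if knn >= m.n_cells:
        raise InputError(f"knn={knn} must be < number of cells {m.n_cells}")
    norm = lognormalize(m)
    X = norm.to_dense()  # genes x cells
    gcs = gene_counts(m)

    corr = _pearson_with_vector(X, gcs.astype(float))
    n_top = min(n_top, m.n_genes)
    order = np.lexsort((np.asarray(m.gene_ids, dtype=str), -corr))
    top = order[:n_top]
    raw = X[top].mean(axis=0)

    smoothed = raw.copy()
    if n_smooth > 0:
        hvgs = select_hvg(m, min(n_hvg, m.n_genes))
        emb_in = norm.restrict_genes(hvgs).to_dense().T  # cells x hvgs
        n_pcs = min(n_pcs, min(emb_in.shape) - 1)
        if n_pcs >= 1 and np.ptp(emb_in) > 0:
            emb = PCA(n_components=n_pcs, random_state=0).fit_transform(emb_in)
        else:
            emb = np.zeros((m.n_cells, 1))
        k_eff = min(knn, m.n_cells)
        if np.allclose(emb, emb[0]):  # identical cells: every cell neighbors every cell
            nbr = np.tile(np.arange(k_eff), (m.n_cells, 1))
        else:
            nn = NearestNeighbors(n_neighbors=k_eff, metric="cosine")
            nn.fit(emb)
            _, nbr = nn.kneighbors(emb)  # includes the cell itself
        for _ in range(n_smooth):
            smoothed = smoothed[nbr].mean(axis=1)

    if m.n_cells == 1:
        score = np.array([0.5])
    else:
        score = (rankdata(smoothed, method="average") - 1.0) / (m.n_cells - 1.0)
    return PotencyScore(m.cell_ids.copy(), gcs, raw, smoothed, score,
                        [str(g) for g in m.gene_ids[top]])
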