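"""Restarted NMF with cosine-kNN consensus and outlier-spectra filtering.

Each restart factorizes the (cells x genes) matrix into usage (cells x k)
and spectra (k x genes) by multiplicative updates on the Frobenius loss.
Spectra from all restarts are pooled; a spectrum whose mean cosine
distance to its k nearest neighbors from *other* restarts exceeds the
filtering threshold (default 0.2) is discarded as unstable. Survivors are
clustered by average-linkage on cosine distance and each cluster's
element-wise median (re-normalized) is reported as a consensus spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import NMF
from sklearn.metrics.pairwise import cosine_distances

from .errors import InputError


@dataclass
class NMFDecomposition:
    """One restart: L2-row-normalized spectra, matching usage, final error."""

    spectra: np.ndarray   # k x genes, rows L2-normalized
    usage: np.ndarray     # cells x k
    k: int
    restart: int
    error: float          # final Frobenius reconstruction error


@dataclass
class ConsensusResult:
    kept: np.ndarray          # indices into the pooled spectra
    removed: np.ndarray
    mean_knn_distance: np.ndarray
    threshold: float
    cluster_labels: np.ndarray    # label per kept spectrum
    consensus_spectra: np.ndarray  # n_clusters x genes
    restart_of: np.ndarray         # pooled spectrum -> restart id


def _normalize_rows(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(H, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    return H / norms[:, None], norms


def nmf_fit(m, k: int, seed: int = 0, max_iter: int = 500,
            tol: float = 1e-5) -> NMFDecomposition:
    """One NMF restart (multiplicative updates, Frobenius loss, random init)."""
    X = m.toarray() if sp.issparse(m) else np.asarray(m, dtype=float)
    if X.min() < 0:
        raise InputError("NMF input must be non-negative")
    if not (0 < k < min(X.shape)):
        raise InputError(f"k={k} must be in (0, min{X.shape})")
    model = NMF(n_components=k, init="random", solver="mu",
                beta_loss="frobenius", max_iter=max_iter, tol=tol,
                random_state=seed)
    import warnings as _w
    with _w.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        _w.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(X)
    H = model.components_
    Hn, norms = _normalize_rows(H)
    err = float(np.linalg.norm(X - W @ H))
    return NMFDecomposition(Hn, W * norms[None, :], k, seed, err)


def nmf_restarts(m, k: int, n_restarts: int = 10, seed: int = 0,
                 **kwargs) -> list:
    """Independent restarts with seeds derived from ``seed``."""
    return [nmf_fit(m, k, seed=seed + i, **kwargs) for i in range(n_restarts)]


def consensus_filter(decomps: list, knn: int | None = None,
                     threshold: float = 0.2,
                     n_clusters: int | None = None) -> ConsensusResult:
    """Filter pooled spectra by mean-kNN cosine distance, then cluster.

    ``knn`` defaults to 30% of the number of restarts (at least 1).
    Neighbors from the spectrum's own restart are excluded from the kNN
    pool so that a restart cannot vouch for itself.
    """
    if len(decomps) < 2:
        raise InputError("consensus needs at least 2 restarts")
    spectra = np.vstack([d.spectra for d in decomps])
    restart_of = np.concatenate(
        [np.full(d.k, i) for i, d in enumerate(decomps)])
    n_pool = spectra.shape[0]
    if knn is None:
        knn = max(1, round(0.3 * len(decomps)))
    if knn >= n_pool:
        raise InputError(f"knn={knn} must be < pooled spectra count {n_pool}")

    D = cosine_distances(spectra)
    mean_knn = np.empty(n_pool)
    for i in range(n_pool):
        cand = np.flatnonzero(restart_of != restart_of[i])
        if len(cand) < knn:
            raise InputError("not enough cross-restart neighbors for knn")
        d_i = np.sort(D[i, cand])[:knn]
        mean_knn[i] = d_i.mean()

    keep = mean_knn <= threshold
    kept = np.flatnonzero(keep)
    removed = np.flatnonzero(~keep)
    if len(kept) == 0:
        raise InputError("all spectra removed by the consensus filter")

    k_out = n_clusters if n_clusters is not None else decomps[0].k
    k_out = min(k_out, len(kept))
    if len(kept) == 1:
        labels = np.array([1])
    else:
        Z = linkage(spectra[kept], method="average", metric="cosine")
        labels = fcluster(Z, t=k_out, criterion="maxclust")
    consensus = np.vstack([
        np.median(spectra[kept][labels == c], axis=0)
        for c in np.unique(labels)])
    consensus, _ = _normalize_rows(consensus)
    return ConsensusResult(kept, removed, mean_knn, threshold, labels,
                           consensus, restart_of)
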