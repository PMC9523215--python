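"""Expression-matrix I/O and quality-control filtering.

The QC procedure applies five rules in a fixed order:

1. drop genes detected in fewer than ``min_cells_per_gene`` cells,
2. drop cells detecting fewer than ``min_genes_per_cell`` or more than
   ``max_genes_per_cell`` genes (counted after rule 1),
3. drop cells whose mitochondrial load exceeds ``mito_limit`` (either a
   percentage of UMIs or an absolute UMI count, per ``mito_mode``),
4. drop cells detecting more than ``max_hb_genes`` hemoglobin genes,
5. drop genes detected in no more than ``min_cells_per_feature`` cells
   (re-counted after the cell rules).

Boundary semantics are strict: a cell with exactly ``min_genes_per_cell``
detected genes is retained; a gene detected in exactly
``min_cells_per_gene`` cells is retained; a gene detected in exactly
``min_cells_per_feature`` cells is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import FormatError, InputError

MITO_PREFIX = "mt-"
HB_PREFIXES = ("hba-", "hbb-")


@dataclass
class ExpressionMatrix:
    """Non-negative integer counts, genes x cells, with stable identifiers."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.cell_ids)} cells"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} identifiers")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative entries in count matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset(self, gene_mask=None, cell_mask=None) -> "ExpressionMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return ExpressionMatrix(
            self.values[gm][:, cm], self.gene_ids[gm], self.cell_ids[cm]
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            list(self.gene_ids) == list(other.gene_ids)
            and list(self.cell_ids) == list(other.cell_ids)
            and (self.values != other.values).nnz == 0
        )


@dataclass
class QCThresholds:
    """Cutoffs for the five QC rules (defaults follow the study design)."""

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 400
    max_genes_per_cell: int = 12000
    mito_mode: str = "percent"  # "percent" (of UMIs) or "absolute" (UMI count)
    mito_limit: float = 10.0
    max_hb_genes: int = 5
    min_cells_per_feature: int = 10

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise InputError("min_genes_per_cell must be < max_genes_per_cell")
        if self.mito_mode not in ("percent", "absolute"):
            raise InputError(f"unknown mito_mode {self.mito_mode!r}")
        if min(self.mito_limit, self.max_hb_genes, self.min_cells_per_gene,
               self.min_cells_per_feature) < 0:
            raise InputError("QC limits must be non-negative")


@dataclass
class QCReport:
    """Ordered audit log of the filter: one entry per rule."""

    steps: list = field(default_factory=list)  # (rule, axis, removed, genes, cells)
    retained_genes: int = 0
    retained_cells: int = 0

    def add(self, rule: str, axis: str, removed: int, genes: int, cells: int) -> None:
        self.steps.append(
            {"rule": rule, "axis": axis, "removed": int(removed),
             "retained_genes": int(genes), "retained_cells": int(cells)}
        )
        self.retained_genes, self.retained_cells = int(genes), int(cells)

    def removals(self) -> list:
        return [s["removed"] for s in self.steps]


def _dedupe_ids(ids: np.ndarray, what: str) -> np.ndarray:
    seen: dict = {}
    out = []
    dup = False
    for i in ids:
        if i in seen:
            seen[i] += 1
            out.append(f"{i}.{seen[i]}")
            dup = True
        else:
            seen[i] = 0
            out.append(i)
    if dup:
        warnings.warn(f"duplicate {what} identifiers were suffix-deduplicated")
    return np.asarray(out, dtype=object)


def read_counts(path) -> ExpressionMatrix:
    """Read counts from an MTX triplet directory or a dense TSV file.

    A directory is expected to contain ``matrix.mtx``, ``genes.tsv`` and
    ``barcodes.tsv``; a file is parsed as a dense TSV with genes as rows,
    the first column holding gene ids and the header row cell ids.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    if path.suffix == ".mtx":
        return _read_mtx_dir(path.parent)
    return _read_dense_tsv(path)


def _read_mtx_dir(d: Path) -> ExpressionMatrix:
    mtx, genes_f, cells_f = d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv"
    for f in (mtx, genes_f, cells_f):
        if not f.exists():
            raise FormatError(f"missing file {f}")
    try:
        values = sp.csr_matrix(mmread(str(mtx)))
    except Exception as e:  # out-of-bound 1-based indices, bad header, ...
        raise FormatError(f"malformed MTX file {mtx}: {e}") from e
    genes = pd.read_csv(genes_f, sep="\t", header=None).iloc[:, 0].to_numpy(object)
    cells = pd.read_csv(cells_f, sep="\t", header=None).iloc[:, 0].to_numpy(object)
    if values.shape != (len(genes), len(cells)):
        raise FormatError(
            f"MTX shape {values.shape} does not match {len(genes)} genes x "
            f"{len(cells)} barcodes"
        )
    return ExpressionMatrix(values, _dedupe_ids(genes, "gene"), cells)


def _read_dense_tsv(f: Path) -> ExpressionMatrix:
    try:
        df = pd.read_csv(f, sep="\t", index_col=0)
    except Exception as e:
        raise FormatError(f"malformed dense TSV {f}: {e}") from e
    values = sp.csr_matrix(df.to_numpy())
    return ExpressionMatrix(
        values, _dedupe_ids(df.index.to_numpy(object), "gene"),
        df.columns.to_numpy(object),
    )


def write_matrix(m: ExpressionMatrix, meta: pd.DataFrame | None, path) -> Path:
    """Write an MTX triplet (plus optional cell_meta.tsv); inverse of read_counts."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(m.values), field="integer")
    pd.Series(m.gene_ids).to_csv(d / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
    if meta is not None:
        meta.to_csv(d / "cell_meta.tsv", sep="\t", index=False)
    return d


def mito_gene_mask(gene_ids, mito_genes=None) -> np.ndarray:
    """Mitochondrial membership from the reserved ``mt-`` prefix or a supplied list."""
    if mito_genes is not None:
        s = set(mito_genes)
        return np.array([g in s for g in gene_ids])
    return np.array([str(g).lower().startswith(MITO_PREFIX) for g in gene_ids])


def hb_gene_mask(gene_ids, hb_genes=None) -> np.ndarray:
    """Hemoglobin membership from ``Hba-``/``Hbb-`` prefixes or a supplied list."""
    if hb_genes is not None:
        s = set(hb_genes)
        return np.array([g in s for g in gene_ids])
    return np.array([str(g).lower().startswith(HB_PREFIXES) for g in gene_ids])


def cell_qc_stats(m: ExpressionMatrix, mito_mode: str = "percent",
                  mito_genes=None, hb_genes=None) -> pd.DataFrame:
    """Per-cell detected-gene, mitochondrial and hemoglobin statistics."""
    X = m.values.tocsc()
    detected = (X > 0).astype(np.int64)
    n_genes = np.asarray(detected.sum(axis=0)).ravel()
    totals = np.asarray(X.sum(axis=0)).ravel()
    mito = mito_gene_mask(m.gene_ids, mito_genes)
    hb = hb_gene_mask(m.gene_ids, hb_genes)
    mito_umi = np.asarray(X[mito].sum(axis=0)).ravel() if mito.any() else np.zeros(m.n_cells)
    n_hb = np.asarray(detected[hb].sum(axis=0)).ravel() if hb.any() else np.zeros(m.n_cells, int)
    if mito_mode == "percent":
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_value = np.where(totals > 0, 100.0 * mito_umi / np.maximum(totals, 1), 0.0)
    else:
        mito_value = mito_umi.astype(float)
    return pd.DataFrame(
        {"cell_id": m.cell_ids, "n_genes_detected": n_genes,
         "mito_value": mito_value, "n_hb_genes_detected": n_hb}
    )


def qc_filter(m: ExpressionMatrix, meta: pd.DataFrame, t: QCThresholds | None = None,
              mito_genes=None, hb_genes=None):
    """Apply the five QC rules in order; returns (matrix, meta, QCReport).

    ``meta`` must have a ``cell_id`` column covering every cell of ``m``;
    its other columns (group, cell_type, ...) are carried through and the
    per-cell QC statistics are (re)attached.
    """
    t = t or QCThresholds()
    meta = meta.copy()
    if "cell_id" not in meta.columns:
        raise InputError("meta must contain a cell_id column")
    missing = set(m.cell_ids) - set(meta["cell_id"])
    if missing:
        raise InputError(f"meta is missing {len(missing)} cells, e.g. {sorted(missing)[:3]}")
    unknown = set(meta["cell_id"]) - set(m.cell_ids)
    if unknown:
        raise InputError(f"meta contains {len(unknown)} unknown cells, e.g. {sorted(unknown)[:3]}")

    report = QCReport()
    # Rule 1: genes detected in fewer than min_cells_per_gene cells.
    det_cells = np.asarray((m.values > 0).sum(axis=1)).ravel()
    keep_g = det_cells >= t.min_cells_per_gene
    m = m.subset(gene_mask=keep_g)
    report.add("gene_min_cells", "genes", (~keep_g).sum(), m.n_genes, m.n_cells)

    # Per-cell statistics are computed on the rule-1-filtered matrix.
    stats = cell_qc_stats(m, t.mito_mode, mito_genes, hb_genes)
    meta = meta[[c for c in meta.columns
                 if c not in ("n_genes_detected", "mito_value", "n_hb_genes_detected")]]
    meta = meta.merge(stats, on="cell_id", how="right")
    meta = meta.set_index("cell_id").loc[list(m.cell_ids)].reset_index()

    # Rule 2: detected-gene bounds (strict: exactly min/max retained);
    # logged as two sub-steps for the audit trail.
    keep_c = (meta["n_genes_detected"] >= t.min_genes_per_cell).to_numpy()
    m, meta = m.subset(cell_mask=keep_c), meta[keep_c].reset_index(drop=True)
    report.add("cell_min_genes", "cells", (~keep_c).sum(), m.n_genes, m.n_cells)
    keep_c = (meta["n_genes_detected"] <= t.max_genes_per_cell).to_numpy()
    m, meta = m.subset(cell_mask=keep_c), meta[keep_c].reset_index(drop=True)
    report.add("cell_max_genes", "cells", (~keep_c).sum(), m.n_genes, m.n_cells)

    # Rule 3: mitochondrial load (strictly greater than the limit removed).
    keep_c = (meta["mito_value"] <= t.mito_limit).to_numpy()
    m, meta = m.subset(cell_mask=keep_c), meta[keep_c].reset_index(drop=True)
    report.add("cell_mito", "cells", (~keep_c).sum(), m.n_genes, m.n_cells)

    # Rule 4: hemoglobin-gene count (strictly greater removed).
    keep_c = (meta["n_hb_genes_detected"] <= t.max_hb_genes).to_numpy()
    m, meta = m.subset(cell_mask=keep_c), meta[keep_c].reset_index(drop=True)
    report.add("cell_hb", "cells", (~keep_c).sum(), m.n_genes, m.n_cells)

    # Rule 5: features in no more than min_cells_per_feature cells removed.
    det_cells = np.asarray((m.values > 0).sum(axis=1)).ravel()
    keep_g = det_cells > t.min_cells_per_feature
    m = m.subset(gene_mask=keep_g)
    report.add("gene_min_feature_cells", "genes", (~keep_g).sum(), m.n_genes, m.n_cells)

    if m.n_genes == 0 or m.n_cells == 0:
        warnings.warn("QC filtering left an empty matrix")
    return m, meta, report
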