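"""Per-cell pathway-activity scoring and cross-list pathway intersection.

The activity score is deliberately simple: each gene is z-scored across
cells on the log-normalized matrix and a cell's pathway score is the mean
z over the pathway's member genes present in the matrix. Group-wise
differential activity uses a two-sided Wilcoxon rank-sum test per pathway
with Benjamini-Hochberg adjustment. Pathway name lists from different
sources are intersected after a lenient normalization (casefold, strip
punctuation, collapse whitespace).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, InputError
from .markers import NormalizedMatrix


@dataclass
class GeneSetCollection:
    """Named, nonempty gene sets."""

    sets: dict = field(default_factory=dict)  # name -> list of gene symbols
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Parse a GMT file (name, description, gene...)."""
    sets: dict = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: GMT line needs name, description "
                              "and at least one gene")
        name, genes = fields[0], [g for g in fields[2:] if g]
        if not genes:
            raise FormatError(f"{path}:{ln}: gene set {name!r} has no genes")
        if name in sets:
            raise FormatError(f"{path}:{ln}: duplicate gene set name {name!r}")
        sets[name] = genes
    return GeneSetCollection(sets, source or str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = ["\t".join([name, collection.source or "na", *genes])
             for name, genes in collection.sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def score_pathways(m: NormalizedMatrix, sets: GeneSetCollection,
                   min_genes: int = 3) -> pd.DataFrame:
    """Cells x pathways score matrix: mean per-gene z over member genes.

    Sets with fewer than ``min_genes`` genes present in the matrix are
    dropped with a warning; constant genes contribute z = 0.
    """
    if min_genes < 1:
        raise InputError("min_genes must be >= 1")
    X = m.to_dense()  # genes x cells
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mu) / np.maximum(sd, 1e-300), 0.0)
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}

    scores, names = [], []
    for name, genes in sets.sets.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if len(idx) < min_genes:
            warnings.warn(f"pathway {name!r} has {len(idx)} genes present "
                          f"(< {min_genes}); dropped")
            continue
        scores.append(Z[idx].mean(axis=0))
        names.append(name)
    if not names:
        raise InputError("no pathway survives the min_genes filter")
    return pd.DataFrame(np.column_stack(scores), index=m.cell_ids, columns=names)


def differential_activity(scores: pd.DataFrame, groups: pd.Series,
                          group_a: str = "old", group_b: str = "young") -> pd.DataFrame:
    """Per-pathway Wilcoxon test of group_a vs group_b scores, BH-adjusted.

    Effect = mean(group_a) - mean(group_b); direction is its sign.
    """
    lab = groups.reindex(scores.index)
    if lab.isna().any():
        raise InputError("group labels missing for some cells")
    mask_a = (lab == group_a).to_numpy()
    mask_b = (lab == group_b).to_numpy()
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise InputError("each group needs >= 3 cells")
    A = scores.to_numpy()[mask_a].T  # pathways x cells
    B = scores.to_numpy()[mask_b].T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = np.asarray(mannwhitneyu(A, B, axis=1, alternative="two-sided").pvalue,
                       dtype=float)
    p[np.isnan(p)] = 1.0
    effect = A.mean(axis=1) - B.mean(axis=1)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "pathway": scores.columns,
        "effect": effect,
        "p_value": p,
        "adj_p": adj,
        "direction": np.where(effect > 0, "up", np.where(effect < 0, "down", "none")),
    })


_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize_pathway_name(name: str) -> str:
    """Casefold, strip punctuation (parenthesized text is kept), collapse whitespace."""
    s = _PUNCT.sub(" ", str(name).casefold())
    return _WS.sub(" ", s).strip()


def intersect_pathways(list_a, list_b) -> list:
    """Name-normalized intersection; returns (a_spelling, b_spelling) pairs.

    Pairs are ordered as in ``list_a``; the first spelling wins when a list
    contains normalization-duplicates.
    """
    norm_b: dict = {}
    for b in list_b:
        norm_b.setdefault(normalize_pathway_name(b), b)
    out, seen = [], set()
    for a in list_a:
        key = normalize_pathway_name(a)
        if key in norm_b and key not in seen:
            seen.add(key)
            out.append((a, norm_b[key]))
    return out
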