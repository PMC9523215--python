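# nvu-hetero

Transcriptional-heterogeneity analysis for two-group (young vs. old)
single-cell RNA-seq of the brain's neurovascular unit, built around a
normalized-mutual-information (NMI) statistic: within a cell type, lower
median pairwise NMI between cells means a more heterogeneous
transcriptional state, and aging-associated dispersion shows up as a
drop in the old group's median NMI. The package provides the full
supporting pipeline — quality control, marker selection, consensus NMF
program extraction, per-cell pathway-activity scoring, a gene-count
differentiation-potency score, and MM/GBSA binding-energy aggregation —
plus a seeded synthetic-data generator that plants every effect the
pipeline is supposed to detect, so all claims are testable offline.

## The central statistic

For cells of one type, take its 100 top differential genes between the
groups, discretize each gene's log-normalized expression into B = 10
equal-width bins, and for a pair of cells (x, y) compute the plug-in
mutual information of the joint bin histogram over genes, normalized by
the mean entropy:

    NMI(x, y) = 2·I(x; y) / (H(x) + H(y))  ∈ [0, 1]

To balance unequal group sizes, each of R replicates subsamples n cells
per group and records the median pairwise NMI, m_g(r). The observed
difference is D = median_r m_A(r) − median_r m_B(r) and the resampling
p-value is the two-sided sign proportion 2·min(#(m_A>m_B)+t/2,
#(m_A<m_B)+t/2)/R, floored at 1/R. Direction (which group has lower
median NMI) and the stability of D across seeds carry the result; see
`docs/methods.md` for calibration properties.

## Worked example

```python
import warnings
import numpy as np
import pandas as pd

from nvu_hetero.synthetic_data import SimConfig, simulate_counts
from nvu_hetero.markers import (NormalizedMatrix, lognormalize,
                                find_markers, top_k_markers)
from nvu_hetero.heterogeneity import (NMIParams, discretize_equal_width,
                                      heterogeneity_test)

# 5 cell types, 200 cells per type per group; the old CPC population gets
# twice the within-type program noise (the planted heterogeneity effect).
cfg = SimConfig(n_cell_types=5, cells_per_type_per_group=200,
                heterogeneity_factor={"CPC": {"old": 2.0}}, seed=7)
matrix, meta, truth = simulate_counts(cfg)

norm = lognormalize(matrix)
groups = pd.Series(meta["group"].to_numpy(), index=meta["cell_id"])
types = pd.Series(meta["cell_type"].to_numpy(), index=meta["cell_id"])
params = NMIParams(n_cells_per_class=50, n_replicates=50, seed=7)

for cell_type in sorted(types.unique()):
    mask = np.isin(norm.cell_ids, types.index[types == cell_type])
    sub = NormalizedMatrix(norm.values[:, mask], norm.gene_ids,
                           norm.cell_ids[mask], norm.scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = find_markers(sub, groups, "old", "young", cluster_name=cell_type)
        profile = top_k_markers(table, cell_type, 100)
        values = np.asarray(sub.restrict_genes(profile).values.todense()).T
        prof = discretize_equal_width(values, params.n_bins,
                                      cell_ids=sub.cell_ids, gene_ids=profile)
        res = heterogeneity_test(prof, groups, params,
                                 group_a="young", group_b="old")
    print(f"{cell_type:4s} median NMI young={np.median(res.medians_a):.3f} "
          f"old={np.median(res.medians_b):.3f} D={res.observed_diff:+.3f} "
          f"p={res.p_value:.2f} lower-NMI group: {res.direction}")
```

Output:

```
AC   median NMI young=0.181 old=0.167 D=+0.014 p=0.02 lower-NMI group: old
CPC  median NMI young=0.188 old=0.172 D=+0.016 p=0.02 lower-NMI group: old
EC   median NMI young=0.191 old=0.169 D=+0.022 p=0.02 lower-NMI group: old
MG   median NMI young=0.171 old=0.179 D=-0.008 p=0.04 lower-NMI group: young
OLG  median NMI young=0.165 old=0.176 D=-0.010 p=0.02 lower-NMI group: young
```

The planted type (CPC) shows the old group as more heterogeneous
(positive D: old median NMI is lower). Because the replicate medians are
precise, p-values hit the 1/R floor for any consistent difference —
other types reach it too at a single seed, but only the planted type's
direction is stable across reseeding (20/20 seeds in the acceptance
suite, versus coin-flip directions elsewhere). Read D and its stability,
not the stars.

The full pipeline (simulate → QC → markers → NMF → heterogeneity →
pathway → potency) runs from one YAML config:

```sh
nvu-hetero run config.yaml      # writes a run directory with manifest.json
nvu-hetero simulate --out data --seed 7
nvu-hetero qc data --min-genes 400 --max-genes 12000 --mito-limit 10
nvu-hetero hetero data --bins 10 --cells 100 --reps 100 --seed 7
nvu-hetero gbsa --complex c.tsv --receptor r.tsv --ligand l.tsv --window 20 30
```

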