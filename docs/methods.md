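# Methods

`nvu_hetero` re-implements, as a tested pipeline, the bespoke computations
of a single-cell study design for brain aging: five-rule quality control,
marker selection, consensus non-negative matrix factorization, an
NMI-based transcriptional-heterogeneity statistic with a resampling
p-value, per-cell pathway-activity scoring with cross-list intersection,
a gene-count differentiation-potency score, and MM/GBSA binding-energy
aggregation. Everything runs on a synthetic data generator that plants
the structure each stage is supposed to detect, so the whole pipeline is
verifiable without any download.

## Synthetic data model

Counts are negative binomial (drawn as a gamma–Poisson mixture for
numerical robustness), genes × cells, with per-cell mean

    mu_cg = L_c * exp( b_g + sum_p w_cp * a_pg + eps_cg + s_g(group) + pathway shifts )

* `b_g` — base log-mean; base means are uniform on `nb_mean_range`
  (default U(1, 5)); NB size (`nb_dispersion`) defaults to 10, i.e.
  moderate overdispersion (var = mu + mu²/10).
* Each cell type carries `n_programs_per_type` (default 3) disjoint
  expression programs of `program_size` (default 50) genes with loadings
  `a_pg ~ U(0.5, 2)`. Two noise sources act on program genes:
  * a scalar per-program weight `w_cp`, lognormal with log-sd
    `program_weight_sd` (default 0.35) — this is what gives restarted NMF
    a non-trivial usage matrix to recover;
  * a per-gene perturbation `eps_cg`, lognormal on the linear-mean scale
    with log-sd `program_noise_sd` (default 0.35). The
    `heterogeneity_factor` multiplies this log-sd for a chosen
    (cell type, group) and is the single knob that lowers within-type
    pairwise NMI. A scalar-only weight would not work: it preserves
    monotone relations between cells' profiles, to which mutual
    information is nearly invariant (measured effect ≈ 0.004 NMI).
* Differential genes: per type, `n_de_genes` (default 100, matching the
  100-gene profiles the heterogeneity statistic consumes) are drawn from
  the type's program genes, with a log-fold-change of `de_log_fc`
  (default 0.8) split symmetrically across the two groups (±0.4 each).
  Drawing them from the program genes is essential — profiles made of
  non-program genes would not carry the heterogeneity knob — and the
  symmetric split keeps the profile's cross-gene structure
  group-balanced; an asymmetric shift inflates the shifted group's NMI
  by construction.
* Library size: per-cell lognormal factor `L_c` (log-sd 0.3) so that
  normalization is not a no-op.
* QC genes: `n_mito_genes` (13, the mouse mitochondrial protein-coding
  count) named `mt-sim*`; `n_hb_genes` (6) named `Hba-sim*`/`Hbb-sim*`
  with a low base mean (0.05) so hemoglobin detection is sporadic, as
  for ambient blood contamination.
* Gradient type: cells of one optional type are ranked 1..n; cell i
  expresses the first ceil(i/n · G) of the type's program genes (nested
  repertoires), so true potency equals rank. With noise off the counts
  are the rounded means and recovery is exact up to the inherent ties
  (two adjacent ranks can share a repertoire size).

What the generator does not emulate: doublets, ambient RNA, batch
effects, realistic gene-gene correlation beyond the program structure,
and the full 63,300-cell scale of a real atlas. Passing tests therefore
demonstrate correctness of the computations and the qualitative
detectability claims, not performance on real tissue.

## Quality control

Rules are applied in a fixed order — (1) genes in fewer than 3 cells,
(2) cells with < 400 or > 12,000 detected genes (computed after rule 1),
(3) mitochondrial load, (4) cells detecting more than 5 hemoglobin
genes, (5) genes detected in no more than 10 cells — with strict
boundary semantics: exactly 400 genes is retained, exactly 3 cells is
retained, exactly 10 cells is removed. The mitochondrial rule has two
modes: `percent` (default; limit = 10% of UMIs, the field-standard
reading) and `absolute` (more than 10 mitochondrial UMIs, the literal
reading, which removes nearly every real cell). Re-applying the filter
to its own output is a no-op on well-behaved data, which the suite
checks on simulated data; it is not an algebraic guarantee, because rule
5 can in principle push a borderline cell below the rule-2 floor.

## Markers

Log-normalization is ln(1 + 10⁴·count/total). HVG selection follows the
standardized-variance (vst) idea: a second-degree polynomial of
log10(variance) on log10(mean) replaces the usual loess (keeping the
dependency footprint small), with a second fitting pass that drops the
top decile of positive residuals so strong HVGs cannot inflate their own
expected variance; standardized counts are clipped at sqrt(n_cells).
Differential expression is a two-sided Wilcoxon rank-sum test on
normalized values, log-fold-change ln((mean expm1+1)/(mean expm1+1))
with pseudocount 1 (so the conventional 0.25 threshold applies),
Benjamini–Hochberg adjustment, and a significance flag of |logFC| > 0.25
and p < 0.05. Profiles for the heterogeneity statistic are the top 100
genes per cell type by (p, |logFC|, gene id), padded by rank with a
warning when fewer than 100 are significant. The within-type
old-vs-young contrast is the default; one-vs-rest contrasts use the same
machinery.

## Heterogeneity (the central statistic)

Expression of the 100 profile genes is discretized per gene into B = 10
equal-width bins over the range observed across the compared cells
(right-closed bins; the maximum falls in the top bin; constant genes go
to bin 0). NMI between two cells is the plug-in mutual information of
the joint histogram of their bin vectors over genes, normalized by the
arithmetic mean of the two entropies (geometric/min/max are selectable);
a zero-entropy vector yields 0 by convention. Per replicate (R = 100 by
default) and group, `n_cells_per_class` (100 by default) cells are
subsampled — without replacement when the group allows — and the median
of all pairwise NMI values recorded. The observed statistic is
D = median_r m_A(r) − median_r m_B(r), and

    p = 2 · min(#(m_A > m_B) + t/2, #(m_A < m_B) + t/2) / R,

clamped to [1/R, 1] (t = ties). This symmetric tie-splitting form is the
reading that makes the exchangeable case (identical groups compared with
common random numbers) return exactly p = 1.

Calibration properties to be aware of, both measured by the suite:

* The replicate medians are precise, so any *consistent* group
  difference drives p to its floor 1/R. The p-value is best read as a
  sign-consistency measure; the magnitude of D and its direction
  stability across seeds carry the scientific content. In a dataset
  where every type has real (planted or biological) expression
  differences between groups, several types may reach the floor; the
  dispersion knob is identified by a stable direction across reseeds.
* Under a one-population null with a *fixed* gene profile, the p < 0.05
  rate is ≈ 0.06 (200 simulated datasets, groups of 100 cells,
  50-cell subsamples, R = 50). Re-selecting top-100 DEGs inside each
  null dataset raises it to ≈ 0.13 — a selection-bias property of the
  DE step, not of the statistic — and enlarging the groups to 200 cells
  drives the rate toward 0 (the subsample-to-group ratio controls how
  much dataset-level chance structure the replicates share).

## Consensus NMF

Each restart minimizes the Frobenius loss by multiplicative updates
(random uniform init, ≤ 500 iterations, relative tolerance 1e-5;
scikit-learn's implementation), and spectra rows are L2-normalized with
the usage rescaled to compensate. Restarted spectra are pooled (defaults
k = 16 × 10 restarts = 160 spectra); each spectrum's mean cosine
distance to its k nearest neighbors *from other restarts* (knn default =
30% of restarts) is the stability score, and spectra above the filtering
threshold 0.2 are removed. Survivors are clustered by average-linkage on
cosine distance, cut at k clusters, and each cluster's element-wise
median (re-normalized) is the consensus spectrum. Component count is a
user decision; the module emits the per-spectrum distance table as the
diagnostic rather than auto-selecting k.

## Pathway activity

Scores are deliberately simple: z-score each gene across cells on the
log-normalized matrix and average the z over the pathway's member genes
present in the matrix (sets with fewer than 3 present genes are
dropped). This is a documented simplification of Vision-style signature
scoring — the downstream logic needs only a per-cell activity with a
group contrast. Differential activity is Wilcoxon + BH per pathway.
Pathway name lists from different sources are intersected after
casefolding, punctuation stripping (parenthesized text is kept) and
whitespace collapsing, preserving the first list's spelling.

## Potency

The gene-count signature (GCS) is the number of detected genes per cell.
The score (higher = less differentiated): correlate every gene's
log-normalized expression with the GCS (Pearson), average the
log-normalized expression of the top 200 correlated genes, smooth twice
over a 30-neighbor cosine kNN graph built on a 30-component PCA of the
top-2000 HVGs (each pass replaces a cell's score with the mean of its
neighborhood including itself), and rank-normalize to [0, 1]. The
published CytoTRACE's NMF-based Markov smoothing is intentionally not
reproduced; two passes of kNN mean-smoothing implement the "two-step
smoothing" idea with far less machinery.

## MM/GBSA aggregation

Inputs are pre-tabulated per-frame component energies for complex,
receptor and ligand (kcal/mol; SASA in Å²). Over the equilibrium window
(default 20–30 ns) each component is averaged per table; the internal
term is Ebond + Eangle + Etorsion; the nonpolar solvation term is
GSA = 0.0072 × SASA when not supplied directly (the surface-tension
coefficient subsumes γ; no offset term is printed in the source
formula, so none is applied); each Δ-term is complex − (receptor +
ligand) and ΔGbind is their sum, which closes to 1e-9 by construction.
Frame grids need not match across tables — only window means are
combined — and per-term standard errors combine the three tables' SEMs
in quadrature. The binder screen keeps names with ΔGbind strictly below
−6.5 kcal/mol. No energies are computed from structures; docking and MD
are out of scope.

## Pipeline, seeds, and problem sizes

`run_pipeline` derives each stage's seed as `global_seed + stage_index`,
so disabling one stage does not shift another's stream; the manifest
records seeds and per-stage counts and is bit-identical across reruns
with the same configuration. The test suite scales the study design
down to keep everything desk-sized: heterogeneity recovery uses 5 cell
types × 200 cells/type/group with R = 50 replicates of 50-cell
subsamples over 20 seeds; the null calibration uses 200 single-type
datasets of 2 × 100 cells; NMF recovery uses 300 cells × 400 genes with
10 restarts; potency uses 300 cells × 800 genes. These sizes are the
package's own choices for a fast, reproducible suite; the defaults in
the code (R = 100, 100 cells/class, k = 16 × 10 restarts) follow the
study design.

## Known limitations

* The heterogeneity p-value is an empirical sign-proportion, not a
  calibrated frequentist test; see the calibration notes above.
* The HVG trend fit is polynomial, not loess; rankings can differ from
  Seurat's vst in the tails.
* The potency score is a simplified re-implementation and is validated
  against the generator's gradient, not against the published tool.
* Equal-width discretization is sensitive to single extreme cells,
  which compress everyone else into few bins; profiles built from
  log-normalized values keep this mild.
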