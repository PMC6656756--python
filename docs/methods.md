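# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Clonotype calling from assembled chains

Input is the per-cell output of a TCR assembler (e.g. TraCeR) on
full-length single-cell RNA-seq reads: per chain, V and J segment calls,
CDR3 nucleotide and amino-acid sequence, a productivity flag and an
estimated chain abundance in TPM.

1. **Abundance filter.** Chains are kept only when their TPM strictly
   exceeds a chain-type threshold — 10 for α, 15 for β. All thresholds in
   the package ("larger than") are read as strict inequalities and applied
   uniformly.
2. **Dominant pair.** Per cell, the dominant pair is the productive α–β
   combination with the highest combined expression. "Combined" is the sum
   of the two chain TPMs: the ranking is over pairs, not chains, and the
   sum is the simplest symmetric aggregate. Exact ties are broken by
   lexicographic order of (α CDR3nt, β CDR3nt), which is deterministic and
   data-independent. Cells lacking a productive chain of either type have
   no dominant pair and drop out of TCR-based analyses.
3. **Clonotype identity.** Two cells share a clonotype iff the
   (V, J, CDR3-nucleotide) keys of both chains match exactly.
   Nucleotide-level identity is the default because clonal descent implies
   an identical rearrangement; amino-acid identity is offered as an option
   for convergence analyses. Clonotype IDs are "C" plus the zero-padded
   rank of the canonicalised key in lexicographic order, so labels are
   invariant to input order. Non-dominant chains do not participate in
   clonotype identity.
4. **Invariant cells.** A cell is MAIT if *any* of its productive α chains
   (not only the dominant one) joins TRAV1-2 to TRAJ33, TRAJ20 or TRAJ12,
   and iNKT for TRAV10–TRAJ18. The two V segments are disjoint, so the
   rules cannot conflict; MAIT is evaluated first.

## Expression QC, gating and normalisation

- **Simplified TPM.** TPM_ij = 10⁶ · (C_ij / ℓ_i) / Σ_i (C_ij / ℓ_i), valid
  under the assumption that mapped reads are of approximately equal length.
  Cells with zero total count are emitted as zero columns with a warning
  rather than an error — the QC step removes them anyway.
- **Cell filters.** A cell fails QC if its library size or detected-gene
  count falls below the population median minus 3× the median absolute
  deviation, if its mitochondrial count fraction exceeds 10%, or if its
  mean CD3D/CD3E/CD3G TPM does not exceed 10 (T-cell identity gate). The
  MAD uses the 1.4826 normal-consistency constant by default (the
  convention of the robust-outlier literature these thresholds echo); a raw
  MAD is available via `mad_scale="raw"`, which can only tighten the
  thresholds. All thresholds are computed once on the full input
  population, not re-derived after removals. Mitochondrial genes default to
  the "MT-" symbol prefix, overridable by an explicit gene set.
- **In-silico FACS.** The CD8 score is the mean TPM of CD8A and CD8B, the
  CD4 score is the CD4 TPM; a score above 30 is positive, below 3 negative,
  otherwise indeterminate, and a cell's label combines the two axes only
  when both are determinate ("undetermined" otherwise).
- **Normalisation.** Counts are divided by per-cell size factors —
  externally computed factors (e.g. pooling deconvolution) are accepted;
  the default is library size scaled to mean one — then transformed as
  log2(x + 1) (pseudocount 1, the common convention; configurable), then
  each gene is centred per patient so that every patient's cell mean is
  zero, removing additive donor effects. Genes with mean raw count ≤ 1
  are removed before normalisation. Re-implementing pooling-deconvolution
  size-factor estimation is out of scope; the hook preserves the pipeline
  contract.

## STARTRAC indices

Definitions are given in the README. Implementation decisions:

- **dist.** Expected counts are computed directly from the margins
  (E_kj = row_k · col_j / total) rather than through a library call so that
  zero-margin combinations can be handled explicitly: their R_o/e is
  reported as NaN ("undefined"), never 0 or ∞, because a zero margin
  fabricates no evidence of enrichment. The chi-squared statistic sums over
  cells with E > 0, dof = (K−1)(J−1) over non-degenerate margins, and the
  p-value is NaN when dof = 0. The non-degenerate path is cross-checked
  against `scipy.stats.chi2_contingency` in the tests.
- **expa edge cases.** With a single clonotype the formula is 0/0. The
  index is defined as 1 when that clonotype has more than one cell (a
  cluster composed of one clonally expanded clonotype is maximal
  expansion) and undefined (NaN) for a single-cell cluster, which carries
  no expansion information. Uniform clonotype sizes return exactly 0. The
  0·log 0 = 0 convention applies throughout, and results are clamped to
  [0, 1] against floating-point drift.
- **Scope of distributions vs weights.** In the cluster-level migr/tran
  averages, each clonotype's tissue/cluster distribution spans *all* of its
  cells in the dataset, while the weights p_cls^t are that clonotype's
  share of the *cluster's* clonotype-bearing cells — the literal reading of
  the two definitions. A lineage seen in a cluster therefore contributes
  the migration behaviour of its whole clonal family.
- **Pairwise indices.** Proportions are renormalised over the two chosen
  categories; clonotypes with no cells in either category are excluded,
  and the cluster-level weights are the clonotype's cell count in the
  cluster restricted to the two categories, renormalised to one. This
  keeps the weighted average within [0, 1] bit and prevents uninformative
  clonotypes from diluting it.
- **Invariant cells.** MAIT/iNKT cells are excluded from expa/migr/tran
  (their semi-invariant TCRs recur across individuals without clonal
  descent) but retained in dist; both behaviours are configurable.

## Marker genes (ANOVA + Tukey HSD)

Per gene, a one-way ANOVA F test across clusters with Benjamini–Hochberg
adjustment over genes; a gene is significant iff the adjusted p < 0.05 and
at least one cluster pair is simultaneously HSD-significant (p < 0.01,
studentized-range distribution with the ANOVA within-group dof) and shows
an absolute mean difference above 1 on the normalised/centred log2 scale of
the input (the scale the clustering uses). The same pair must pass both the
HSD and the effect-size gate. Unequal cluster sizes use the Tukey–Kramer
standard error. Significant genes are assigned to the cluster with the
highest mean. Zero-variance genes (detected by exact range) are recorded
non-significant with a note; clusters with fewer than two cells are
excluded with a warning. Because the studentized-range survival function is
expensive, qualification is decided against its critical quantile and exact
p-values are evaluated only for qualifying pairs — an exact optimisation,
not an approximation. In the balanced two-cluster case the HSD p-value
equals the two-sided t-test p-value (q = t√2), which the tests exploit as
an independent check alongside `statsmodels.pairwise_tukeyhsd`.

## Synthetic-data generator

**Repertoire.** Clonotype sizes are geometric on {1, 2, ...} with
configurable mean (explicit size lists are accepted), drawn until the total
cell budget is met, the last clone trimmed to fit. Each clonotype belongs
to one patient — TCR rearrangements are private to an individual — and
draws a tissue-allocation probability vector from a symmetric Dirichlet
(concentration → 0 confines a lineage to one tissue; → ∞ spreads it
uniformly) and a cluster-allocation vector from a Dirichlet whose base
weights are the per-cluster budgets, so budgets set *expected* cluster
sizes rather than exact counts (clonotype-level allocation cannot hit exact
totals). Chain V/J segments come from pools disjoint from the invariant
rearrangements; CDR3s are unique random codon strings between fixed
Cys-Ala / Phe-Gly flanks (translated with Biopython), so nucleotide and
amino-acid identity modes are both exercised. Dominant-chain TPMs are
truncated log-normal above the filter thresholds; optional secondary
productive chains (below the dominant's TPM) and decoy chains
(below-threshold productive, or abundant non-productive) exercise
filtering and pair selection without disturbing the planted partition.
Defaults: 12 patients, tissues P/N/T, six clusters of 200 cells, clone-size
mean 2, MAIT fraction 1.03% and iNKT fraction 0.03% (the approximate
composition of sorted αβ T-cell data), log-normal TPM with median 200.

**Expression.** Each cell's library size is uniform within ±25% of 4,000
counts — a deliberately bounded law, so the QC median − 3×MAD filters have
a sharp separation between normal cells and planted outliers — and is
distributed over genes by a Dirichlet-multinomial: population-specific
gene proportions jittered per cell by a Dirichlet with total concentration
1/dispersion. Marginally the counts are beta-binomial, the finite-library
analogue of a negative-binomial gene model, while row sums follow the
library-size law exactly (which is what the QC filters consume). Three
populations are built in — CD8 (CD8A/B high, CD4 absent), CD4 and Treg
(CD4 with IL2RA/FOXP3) — all with CD3D/E/G at ~1.2% of the library each;
mitochondrial genes carry 4% of the library in healthy cells. Planted
low-quality cells are "depth" (library × 0.05) or "mito" (mitochondrial
mass raised to 45%). Off-lineage markers are absent rather than merely
low: this is the large-effect-size regime in which in-silico gating is
unambiguous and recovery should be exact.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: batch and plate effects, ambient RNA and doublet
artefacts, realistic V(D)J recombination statistics and allele frequencies,
expression–clonotype coupling (a lineage's transcriptional state is drawn
independently of its TCR), zero-inflation beyond the Dirichlet-multinomial,
and continuous gradients between gating compartments. Exact pipeline
recovery on these data demonstrates correctness of the computations, not
robustness to the full noise structure of real experiments.

## Problem sizes and numerical conventions

The default test and acceptance runs use repertoires of 300–2,000 cells,
expression matrices of ~800 genes × 1,000 cells, and the marker-gene
calibration uses 1,000 genes × 200 cells × 5 replicates — sizes at which
every statistical property being asserted (monotonicity over 5 parameter
settings × 20 seeds, 3σ binomial bands on rejection rates, exact recovery
margins ≥ 10× thresholds) is comfortably resolved. All randomness flows
from one integer seed through a single explicit `numpy.random.Generator`
per generator call; no global RNG state is touched. Tolerances: TPM column
sums are conserved to 1e-6 relative; entropies match a naive-loop oracle to
1e-12; per-patient centring is exact to 1e-9. Undefined quantities
(single-cell-cluster expa, zero-margin R_o/e, correlations of constant
sequences) are reported as NaN, never silently as 0.

## Known limitations

- Clonotype identity is exact-match only; no similarity clustering of
  CDR3s, γδ chains, or antigen-specificity inference.
- The pooling-deconvolution size-factor method itself is not
  re-implemented; only its output is consumed.
- The subsampling behaviour of the entropic indices is biased low (a
  half-sampled clonotype looks more confined than it is); comparisons
  between datasets of very different depth should be made with matched
  subsampling.
- STARTRAC-dist can be computed pooled or per patient (`--by-patient`);
  pooled is the default, and no between-patient inference is provided
  beyond reporting per-patient values.
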