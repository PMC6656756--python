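# startrac

Single T-cell analysis by RNA-seq and TCR tracking: a Python toolkit for
quantifying the dynamics of T-cell populations when each cell carries both a
transcriptome and an assembled αβ T-cell receptor.

Full-length single-cell RNA-seq of sorted T cells (Smart-seq2 class
protocols) yields, per cell, a gene expression profile *and* the paired
TCR α/β chain sequences assembled from the same reads. Because the TCR is a
heritable clonal barcode, cells sharing an identical receptor descend from
one ancestral T cell — so the joint data reveal not just *what states* T
cells occupy (clusters, tissues) but *how lineages move* between them. This
package implements the quantitative machinery for that analysis, aimed at
computational immunologists working with paired expression + TCR data from
tumours, adjacent tissue and blood:

- **`startrac.repertoire`** — paired-TCR clonotype calling from per-cell
  assembled chains: abundance filtering (α TPM > 10, β TPM > 15), selection
  of the productive dominant α–β pair per cell, clonotype assignment by
  exact (V, J, CDR3) identity on both chains, and classification of
  invariant MAIT (TRAV1-2 + TRAJ33/20/12) and iNKT (TRAV10 + TRAJ18) cells.
- **`startrac.expression`** — simplified TPM, robust cell QC (library size
  and detected genes under median − 3×MAD, mitochondrial fraction > 10%,
  mean CD3D/E/G TPM ≤ 10), in-silico FACS gating into CD4/CD8 compartments
  (positive > 30 TPM, negative < 3), size-factor normalisation and
  per-patient centring.
- **`startrac.indices`** — the STARTRAC index family (see below).
- **`startrac.sharing`** — repertoire descriptives: chain recurrence
  distributions, α/β recurrence concordance, clonotype-sharing matrices
  between cluster × tissue groups.
- **`startrac.deg`** — cluster marker genes by one-way ANOVA with
  Benjamini–Hochberg correction plus Tukey HSD pair tests and an
  effect-size gate.
- **`startrac.simulate`** — synthetic repertoires and count matrices with
  known ground truth, so the whole pipeline is testable without any
  controlled-access dataset.

## The indices

For a table of cells annotated with tissue *j* ∈ {P, N, T}, cluster *k* and
clonotype *t*:

- **STARTRAC-dist** — tissue enrichment of a cluster as
  *R*<sub>o/e</sub> = Observed / Expected, with expected counts from the
  chi-squared test of independence on the cluster × tissue contingency
  table. *R*<sub>o/e</sub> > 1 means enrichment, < 1 depletion.
- **STARTRAC-expa** — clonal expansion of a cluster with *N* clonotypes and
  clonotype frequencies *p<sub>i</sub>*:
  *I*<sub>expa</sub> = 1 − (−Σ<sub>i</sub> *p<sub>i</sub>* log₂ *p<sub>i</sub>*) / log₂ *N*
  (one minus the evenness of the repertoire; 0 = no expansion,
  1 = a single expanded clonotype).
- **STARTRAC-migr** — per clonotype, the Shannon entropy of its cell
  distribution across tissues, −Σ<sub>j</sub> *p<sub>j</sub><sup>t</sup>* log₂ *p<sub>j</sub><sup>t</sup>*;
  per cluster, the average of clonotype entropies weighted by each
  clonotype's share *p*<sub>cls</sub><sup>t</sup> of the cluster's cells.
- **STARTRAC-tran** — the same construction over clusters instead of
  tissues, measuring state transitions within clonal lineages.
- **Pairwise variants** restrict the entropy to two chosen tissues or
  clusters with proportions renormalised over the pair (≤ 1 bit).

MAIT and iNKT cells carry semi-invariant TCRs shared between individuals,
so they are excluded from the clonotype-based indices by default while
still counted in the distribution index.

## Worked example

Simulate a repertoire of three CD8 clusters (750 cells, geometric clone
sizes with mean 4, moderately confined tissue distributions), call
clonotypes from the chain table, and compute the index report:

```python
from startrac import (RepertoireSpec, simulate_repertoire, frame_to_chains,
                      build_repertoire, index_report)

spec = RepertoireSpec(
    seed=42,
    cluster_budgets={"CD8_TEM": 250, "CD8_TEX": 250, "CD8_TRM": 250},
    clone_size_mean=4.0,
    tissue_concentration=0.5,
)
cells, chains, truth = simulate_repertoire(spec)

table, clonotypes, pairs = build_repertoire(frame_to_chains(chains))
print(f"{len(table)} cells -> {len(clonotypes)} clonotypes")

report, dist = index_report(cells)
print(report.round(3).to_string())
print(dist.roe.round(2).to_string())
print(f"chi2 = {dist.chi2:.1f}, dof = {dist.dof}, p = {dist.pvalue:.3g}")
```

Output:

```
750 cells -> 196 clonotypes
         n_cells  n_clonotypes   expa   migr   tran
cluster
CD8_TEM      257           119  0.048  0.738  0.879
CD8_TEX      244           114  0.047  0.681  0.848
CD8_TRM      234           108  0.057  0.569  0.840

tissue      N     P     T
cluster
CD8_TEM  1.01  0.94  1.06
CD8_TEX  1.02  0.85  1.17
CD8_TRM  0.96  1.22  0.76
chi2 = 14.2, dof = 4, p = 0.0067
```

Reading it: the chain-level pipeline recovered exactly the 196 planted
clonotypes. Clusters are mildly clonal (`expa` ≈ 0.05: most clonotypes are
small), clonal lineages spread substantially across tissues (`migr` ≈
0.6–0.7 bits of a possible log₂ 3 ≈ 1.58) and across the three states
(`tran` ≈ 0.85 bits), and the *R*<sub>o/e</sub> table shows e.g. CD8_TRM
depleted from tumour (0.76) and enriched in blood (1.22) in this draw, with
the chi-squared test confirming a non-random tissue distribution.

The same steps are available from the shell:

```sh
startrac simulate --seed 42 --out sim/
startrac clonotype --chains sim/chains.tsv --out clonotypes.tsv
startrac indices --cells sim/cells.tsv --pair P,T --out indices/
startrac qc --counts sim/counts.mtx --genes sim/genes.tsv \
    --barcodes sim/barcodes.tsv --model sim/genemodel.tsv --out qc.tsv
```

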