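"""Cluster marker genes by ANOVA + Tukey HSD on normalised expression.

A gene is called a significant cluster marker when

1. the one-way ANOVA F test across clusters is significant after
   Benjamini–Hochberg adjustment over genes (adjusted p < ``alpha``);
2. at least one cluster pair is simultaneously significant under Tukey's
   honest-significant-difference test (pair p < ``pair_alpha``) and shows an
   absolute mean difference above ``min_diff`` on the normalised/centred
   log2 scale of the input matrix.

Significant genes are assigned to the cluster with the highest mean
expression.  Unequal cluster sizes use the Tukey–Kramer standard error, and
pair p-values come from the studentized-range distribution with the ANOVA
within-group degrees of freedom.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["deg_among_clusters"]


def deg_among_clusters(
    expr: pd.DataFrame,
    clusters: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    pair_alpha: float = 0.01,
    min_diff: float = 1.0,
) -> pd.DataFrame:
    """Differential expression of every gene across cell clusters.

    ``expr`` is genes × cells (normalised, per-patient centred log2 values);
    ``clusters`` maps cell id → cluster label.  Clusters with fewer than two
    cells are excluded with a warning; at least two clusters must remain.

    Returns one record per gene: F statistic, raw and BH-adjusted p-values,
    the best significant pair (smallest HSD p among pairs that also exceed
    ``min_diff``), the assigned cluster (highest mean; only for significant
    genes) and a note for degenerate cases (zero-variance genes are recorded
    as non-significant).
    """
    clusters = pd.Series(dict(clusters)) if not isinstance(clusters, pd.Series) else clusters
    clusters = clusters.reindex(expr.columns)
    if clusters.isna().any():
        missing = expr.columns[clusters.isna()]
        raise ValueError(f"no cluster for cells: {missing[:5].tolist()}")

    sizes = clusters.value_counts()
    small = sizes[sizes < 2]
    if len(small) > 0:
        warnings.warn(
            f"excluding clusters with fewer than 2 cells: {sorted(small.index)}",
            stacklevel=2,
        )
        keep = clusters.isin(sizes[sizes >= 2].index)
        expr = expr.loc[:, keep.values]
        clusters = clusters[keep]
    labels = sorted(clusters.unique())
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two clusters with >=2 cells")

    x = expr.to_numpy(dtype=float)
    n_genes, n_cells = x.shape
    group_idx = [np.flatnonzero((clusters == lab).to_numpy()) for lab in labels]
    n_k = np.array([len(ix) for ix in group_idx], dtype=float)

    means = np.column_stack([x[:, ix].mean(axis=1) for ix in group_idx])  # genes × k
    grand = x.mean(axis=1)
    ss_between = ((means - grand[:, None]) ** 2 * n_k[None, :]).sum(axis=1)
    ss_within = np.zeros(n_genes)
    for j, ix in enumerate(group_idx):
        ss_within += ((x[:, ix] - means[:, [j]]) ** 2).sum(axis=1)
    df_between = k - 1
    df_within = n_cells - k
    mse = ss_within / df_within

    zero_var = x.max(axis=1) == x.min(axis=1)  # constant genes: F is 0/0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / df_between) / mse
    f_stat[zero_var] = np.nan
    pvals = np.full(n_genes, np.nan)
    ok = ~np.isnan(f_stat)
    pvals[ok] = stats.f.sf(f_stat[ok], df_between, df_within)

    padj = np.full(n_genes, np.nan)
    if ok.any():
        padj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]

    # Tukey-Kramer HSD over all cluster pairs, vectorised over genes.  The
    # studentized-range sf is expensive, so qualification is decided against
    # the critical quantile and exact p-values are evaluated only for pairs
    # that qualify.
    q_crit = float(stats.studentized_range.ppf(1.0 - pair_alpha, k, df_within))
    pair_p_best = np.full(n_genes, np.nan)
    pair_a = np.full(n_genes, None, dtype=object)
    pair_b = np.full(n_genes, None, dtype=object)
    pair_diff = np.full(n_genes, np.nan)
    has_pair = np.zeros(n_genes, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(k):
            for j in range(i + 1, k):
                diff = means[:, i] - means[:, j]
                se = np.sqrt(mse / 2.0 * (1.0 / n_k[i] + 1.0 / n_k[j]))
                q = np.abs(diff) / se
                qualifies = ok & (q > q_crit) & (np.abs(diff) > min_diff)
                p_pair = np.full(n_genes, np.nan)
                if qualifies.any():
                    p_pair[qualifies] = stats.studentized_range.sf(
                        q[qualifies], k, df_within
                    )
                better = qualifies & (
                    ~has_pair | (p_pair < np.where(np.isnan(pair_p_best), np.inf, pair_p_best))
                )
                pair_p_best[better] = p_pair[better]
                pair_a[better] = labels[i]
                pair_b[better] = labels[j]
                pair_diff[better] = diff[better]
                has_pair |= qualifies

    significant = ok & (padj < alpha) & has_pair
    assigned = np.full(n_genes, None, dtype=object)
    best_cluster = np.argmax(means, axis=1)
    assigned[significant] = [labels[c] for c in best_cluster[significant]]

    notes = np.full(n_genes, "", dtype=object)
    notes[zero_var] = "zero-variance"

    return pd.DataFrame(
        {
            "gene": expr.index,
            "f_statistic": f_stat,
            "pvalue": pvals,
            "padj": padj,
            "pair_a": pair_a,
            "pair_b": pair_b,
            "pair_diff": pair_diff,
            "pair_pvalue": pair_p_best,
            "significant": significant,
            "cluster": assigned,
            "note": notes,
        }
    ).set_index("gene")
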