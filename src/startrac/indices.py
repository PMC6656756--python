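"""STARTRAC indices: tissue enrichment, clonal expansion, migration, transition.

Given a cell table annotated with patient, tissue of origin (peripheral blood
P, adjacent normal N, tumour T by convention), transcriptome cluster and
clonotype, four index families quantify T-cell dynamics:

* **dist** — tissue enrichment of each cluster as R_o/e, the ratio of the
  observed cell count of a cluster × tissue combination to the count expected
  under independence (the chi-squared expected count).  R_o/e > 1 flags
  enrichment, < 1 depletion.
* **expa** — clonal expansion of a cluster as one minus the evenness
  (normalised Shannon entropy) of its clonotype size distribution:
  ``1 − (−Σ p_i log2 p_i) / log2 N`` over the N clonotypes of the cluster.
* **migr** — per clonotype, the Shannon entropy of its cell distribution
  across tissues; per cluster, the average of clonotype entropies weighted by
  each clonotype's share of the cluster's cells.
* **tran** — identical construction with clusters in place of tissues,
  measuring state transitions within a clonal lineage.

Pairwise variants restrict the entropy to two chosen tissues (or clusters)
with proportions renormalised over the pair, giving at most 1 bit.

MAIT and iNKT cells carry semi-invariant TCRs shared across individuals, so
they are excluded from the clonotype-based indices (expa/migr/tran) by
default while still counted in the tissue-distribution index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "startrac_dist",
    "startrac_expa",
    "clonotype_entropy",
    "cluster_weighted_index",
    "pairwise_index",
    "index_report",
    "read_cell_table",
    "DEFAULT_COLUMNS",
]

# Column map compatible with the study-style annotation table; override any
# entry when reading a table with different headers.
DEFAULT_COLUMNS = {
    "cell_id": "cell_id",
    "patient": "patient",
    "tissue": "tissue",
    "cluster": "cluster",
    "clonotype_id": "clonotype_id",
    "invariant_class": "invariant_class",
}


@dataclass
class ContingencyTable:
    """Observed/expected cluster × tissue counts with the chi-squared test."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    dof: int
    pvalue: float
    roe: pd.DataFrame  # NaN where the expected count is zero

    def enrichment(self, threshold: float = 1.0) -> pd.DataFrame:
        """Boolean mask of enriched combinations (R_o/e above ``threshold``)."""
        return self.roe > threshold


def _entropy_bits(proportions: np.ndarray) -> float:
    """Shannon entropy in bits with the 0·log 0 = 0 convention."""
    p = proportions[proportions > 0]
    return float(-(p * np.log2(p)).sum())


def startrac_dist(
    cells: pd.DataFrame,
    cluster_col: str = "cluster",
    tissue_col: str = "tissue",
) -> ContingencyTable:
    """Tissue-enrichment index R_o/e for every cluster × tissue combination.

    Expected counts come from the chi-squared test of independence,
    E_kj = (row_k total)(col_j total)/grand total.  Combinations with a zero
    margin have no defined expectation and their R_o/e is NaN rather than a
    fabricated 0 or infinity.  With fewer than two non-degenerate rows or
    columns the test itself is undefined (dof 0, p-value NaN) while R_o/e is
    still reported (identically 1 where defined).
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    observed = pd.crosstab(cells[cluster_col], cells[tissue_col]).astype(float)
    # Categorical annotations declare the admissible label sets; keep unused
    # levels as zero margins so their R_o/e is reported as undefined.
    if isinstance(cells[cluster_col].dtype, pd.CategoricalDtype):
        observed = observed.reindex(cells[cluster_col].cat.categories, fill_value=0.0)
    if isinstance(cells[tissue_col].dtype, pd.CategoricalDtype):
        observed = observed.reindex(
            columns=cells[tissue_col].cat.categories, fill_value=0.0
        )
    o = observed.to_numpy()
    row = o.sum(axis=1, keepdims=True)
    col = o.sum(axis=0, keepdims=True)
    total = o.sum()
    e = row @ col / total
    expected = pd.DataFrame(e, index=observed.index, columns=observed.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        roe = np.where(e > 0, o / e, np.nan)
    nz_rows = int((row > 0).sum())
    nz_cols = int((col > 0).sum())
    dof = (nz_rows - 1) * (nz_cols - 1)
    mask = e > 0
    chi2 = float(((o[mask] - e[mask]) ** 2 / e[mask]).sum())
    pvalue = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    return ContingencyTable(
        observed=observed,
        expected=expected,
        chi2=chi2,
        dof=dof,
        pvalue=pvalue,
        roe=pd.DataFrame(roe, index=observed.index, columns=observed.columns),
    )


def startrac_expa(clone_sizes: Sequence[int]) -> float:
    """Clonal-expansion index of one cluster from its clonotype sizes.

    ``1 − H/log2 N`` where H is the Shannon entropy of the clonotype
    frequencies p_i = size_i / Σ size.  0 means all clonotypes are equally
    frequent (no expansion); 1 means a single clonally expanded clonotype.
    A lone clonotype of more than one cell is maximal expansion (1.0); a
    cluster of exactly one cell carries no expansion information and yields
    NaN, as does an empty input.
    """
    sizes = np.asarray(list(clone_sizes), dtype=float)
    if sizes.size == 0:
        return float("nan")
    if (sizes <= 0).any() or not np.allclose(sizes, np.round(sizes)):
        raise ValueError("clone sizes must be positive integers")
    n = sizes.size
    total = sizes.sum()
    if n == 1:
        return 1.0 if total > 1 else float("nan")
    if np.all(sizes == sizes[0]):
        return 0.0  # uniform frequencies: evenness exactly 1
    h = _entropy_bits(sizes / total)
    return float(np.clip(1.0 - h / math.log2(n), 0.0, 1.0))


def clonotype_entropy(counts: Sequence[float]) -> float:
    """Shannon entropy (bits) of one clonotype's distribution over categories.

    Zero iff the clonotype is confined to one category; log2(#categories)
    iff it is spread uniformly.
    """
    c = np.asarray(list(counts), dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no distribution")
    return _entropy_bits(c / total)


def _analysis_cells(
    cells: pd.DataFrame,
    clonotype_col: str,
    invariant_col: Optional[str],
    exclude_invariant: bool,
) -> pd.DataFrame:
    out = cells[cells[clonotype_col].notna()]
    if exclude_invariant and invariant_col is not None and invariant_col in out.columns:
        out = out[out[invariant_col].isin(["conventional"]) | out[invariant_col].isna()]
    return out


def cluster_weighted_index(
    cells: pd.DataFrame,
    cluster: str,
    mode: str,
    cluster_col: str = "cluster",
    tissue_col: str = "tissue",
    clonotype_col: str = "clonotype_id",
    invariant_col: Optional[str] = "invariant_class",
    exclude_invariant: bool = True,
) -> float:
    """Cluster-level migration or transition index.

    ``Σ_t p_cls^t · I^t`` where the weight p_cls^t is the fraction of the
    cluster's clonotype-bearing cells belonging to clonotype t, and I^t is
    the clonotype's entropy over tissues (mode "migr") or clusters (mode
    "tran").  Each clonotype's distribution spans all of its cells in the
    dataset, not only those inside the cluster.  Returns NaN for a cluster
    with no eligible cells.
    """
    if mode not in ("migr", "tran"):
        raise ValueError("mode must be 'migr' or 'tran'")
    cat_col = tissue_col if mode == "migr" else cluster_col
    pool = _analysis_cells(cells, clonotype_col, invariant_col, exclude_invariant)
    members = pool[pool[cluster_col] == cluster]
    if len(members) == 0:
        return float("nan")
    weights = members[clonotype_col].value_counts(normalize=True)
    global_counts = pool.groupby([clonotype_col, cat_col], observed=True).size()
    value = 0.0
    for clonotype, w in weights.items():
        dist = global_counts.loc[clonotype]
        value += w * clonotype_entropy(dist.to_numpy())
    return value


def pairwise_index(
    cells: pd.DataFrame,
    cluster: str,
    mode: str,
    pair: tuple[str, str],
    cluster_col: str = "cluster",
    tissue_col: str = "tissue",
    clonotype_col: str = "clonotype_id",
    invariant_col: Optional[str] = "invariant_class",
    exclude_invariant: bool = True,
) -> float:
    """Pairwise migration/transition index restricted to two categories.

    Per clonotype, cell proportions are recalculated over the two categories
    only, so the entropy is at most 1 bit.  Clonotypes with no cells in
    either category are excluded; the cluster value is the weighted average
    over the remaining clonotypes, with weights given by each clonotype's
    cell count in the cluster restricted to the two categories, renormalised
    to one.  Returns NaN when no clonotype qualifies.
    """
    if mode not in ("migr", "tran"):
        raise ValueError("mode must be 'migr' or 'tran'")
    a, b = pair
    if a == b:
        raise ValueError("pair members must be distinct")
    cat_col = tissue_col if mode == "migr" else cluster_col
    pool = _analysis_cells(cells, clonotype_col, invariant_col, exclude_invariant)
    pool = pool[pool[cat_col].isin([a, b])]
    members = pool[pool[cluster_col] == cluster]
    if len(members) == 0:
        return float("nan")
    weights = members[clonotype_col].value_counts(normalize=True)
    counts = pool.groupby([clonotype_col, cat_col], observed=True).size()
    value = 0.0
    for clonotype, w in weights.items():
        dist = counts.loc[clonotype]
        value += w * clonotype_entropy(dist.to_numpy())
    return value


def index_report(
    cells: pd.DataFrame,
    cluster_col: str = "cluster",
    tissue_col: str = "tissue",
    clonotype_col: str = "clonotype_id",
    invariant_col: Optional[str] = "invariant_class",
    exclude_invariant: bool = True,
) -> tuple[pd.DataFrame, ContingencyTable]:
    """Per-cluster expa/migr/tran table plus the tissue-enrichment table.

    Invariant (MAIT/iNKT) cells are excluded from expa/migr/tran but kept in
    the distribution index.  The per-cluster frame reports the number of
    eligible cells and clonotypes entering each value; clusters with no
    eligible cells get NaN indices.
    """
    dist = startrac_dist(cells, cluster_col=cluster_col, tissue_col=tissue_col)
    pool = _analysis_cells(cells, clonotype_col, invariant_col, exclude_invariant)
    rows = []
    for cluster in sorted(cells[cluster_col].unique()):
        members = pool[pool[cluster_col] == cluster]
        sizes = members[clonotype_col].value_counts()
        rows.append(
            {
                "cluster": cluster,
                "n_cells": int(len(members)),
                "n_clonotypes": int(len(sizes)),
                "expa": startrac_expa(sizes.to_numpy()) if len(sizes) else float("nan"),
                "migr": cluster_weighted_index(
                    cells, cluster, "migr",
                    cluster_col=cluster_col, tissue_col=tissue_col,
                    clonotype_col=clonotype_col, invariant_col=invariant_col,
                    exclude_invariant=exclude_invariant,
                ),
                "tran": cluster_weighted_index(
                    cells, cluster, "tran",
                    cluster_col=cluster_col, tissue_col=tissue_col,
                    clonotype_col=clonotype_col, invariant_col=invariant_col,
                    exclude_invariant=exclude_invariant,
                ),
            }
        )
    return pd.DataFrame(rows).set_index("cluster"), dist


def read_cell_table(path, columns: Optional[dict] = None) -> pd.DataFrame:
    """Read an annotated cell table TSV, renaming columns to canonical names.

    ``columns`` maps canonical names (keys of DEFAULT_COLUMNS) to the file's
    actual headers, e.g. ``{"cluster": "majorCluster", "tissue": "sampleType"}``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [k for k in ("cell_id", "tissue", "cluster") if k not in df.columns]
    if missing:
        raise ValueError(f"cell table missing required columns: {missing}")
    return df
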