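"""Repertoire-level descriptive analytics: chain recurrence and TCR sharing.

Three views of how TCR sequences recur across cells and groups:

* chain recurrence — for each distinct α (or β) chain appearing in a
  dominant pair, the number of cells carrying it, plus the
  frequency-of-frequencies table (how many distinct chains recur r times);
* α/β concordance — because both chains of a clonal lineage recur together,
  the recurrence level of a cell's α chain tracks that of its β chain; the
  joint table and a rank correlation quantify this;
* sharing matrix — for any grouping of cells (cluster × tissue being the
  canonical one), the number of distinct clonotypes present in both groups
  of each pair, a direct readout of cross-tissue migration and state
  transition at the repertoire level.  A directional cell-level variant
  counts the cells of group A whose clonotype also occurs in group B.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire import ALPHA, BETA, DominantPair

__all__ = [
    "ChainRecurrence",
    "chain_recurrence",
    "alpha_beta_concordance",
    "sharing_matrix",
    "fit_recurrence_powerlaw",
]


@dataclass
class ChainRecurrence:
    """Recurrence of distinct chains of one type across cells."""

    chain_type: str
    counts: pd.Series  # (v, j, cdr3_nt) -> number of cells
    freq_of_freq: pd.Series  # recurrence level r -> number of distinct chains

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())

    @property
    def n_chains(self) -> int:
        return int(len(self.counts))


def chain_recurrence(
    cells: Iterable[tuple[str, DominantPair]],
) -> dict[str, ChainRecurrence]:
    """Count, per chain type, how many cells carry each distinct chain.

    Only dominant pairs contribute, so each cell adds exactly one α and one
    β observation; recurrence totals therefore conserve the cell count.
    """
    counters = {ALPHA: Counter(), BETA: Counter()}
    for _, pair in cells:
        counters[ALPHA][pair.alpha.key()] += 1
        counters[BETA][pair.beta.key()] += 1
    out = {}
    for chain_type, counter in counters.items():
        counts = pd.Series(dict(counter), dtype=int).sort_index() if counter else pd.Series(dtype=int)
        fof = counts.value_counts().sort_index() if len(counts) else pd.Series(dtype=int)
        out[chain_type] = ChainRecurrence(chain_type, counts, fof)
    return out


def alpha_beta_concordance(
    cells: Sequence[tuple[str, DominantPair]],
) -> tuple[pd.DataFrame, float]:
    """Joint distribution of α and β recurrence levels over cells.

    Each cell contributes once at (recurrence of its α chain, recurrence of
    its β chain).  Returns the aggregated table (alpha_recurrence,
    beta_recurrence, n_cells, proportion) and the Spearman rank correlation
    of the two coordinates over cells — NaN (flagged undefined) when either
    coordinate is constant.
    """
    cells = list(cells)
    rec = chain_recurrence(cells)
    if not cells:
        empty = pd.DataFrame(
            columns=["alpha_recurrence", "beta_recurrence", "n_cells", "proportion"]
        )
        return empty, float("nan")
    coords = [
        (rec[ALPHA].counts[pair.alpha.key()], rec[BETA].counts[pair.beta.key()])
        for _, pair in cells
    ]
    df = pd.DataFrame(coords, columns=["alpha_recurrence", "beta_recurrence"])
    table = (
        df.value_counts()
        .rename("n_cells")
        .reset_index()
        .sort_values(["alpha_recurrence", "beta_recurrence"])
        .reset_index(drop=True)
    )
    table["proportion"] = table["n_cells"] / table["n_cells"].sum()
    a = df["alpha_recurrence"].to_numpy()
    b = df["beta_recurrence"].to_numpy()
    if np.all(a == a[0]) or np.all(b == b[0]):
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(a, b).statistic)
    return table, rho


def sharing_matrix(
    cells: pd.DataFrame,
    group_by: Sequence[str] | pd.Series = ("cluster", "tissue"),
    clonotype_col: str = "clonotype_id",
    mode: str = "clonotype",
    groups: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Clonotype sharing between cell groups.

    ``group_by`` is either a list of annotation columns (labels are the
    joined column values) or a precomputed per-cell label Series.  In
    "clonotype" mode, entry (A, B) is the number of distinct clonotypes with
    at least one cell in both groups, so the matrix is symmetric and the
    diagonal counts each group's clonotypes.  In "cell" mode, entry (A, B)
    is the number of cells of A whose clonotype also appears in B
    (directional, hence asymmetric).  ``groups`` optionally declares the
    admissible label set; labels outside it raise.
    """
    if mode not in ("clonotype", "cell"):
        raise ValueError("mode must be 'clonotype' or 'cell'")
    sub = cells[cells[clonotype_col].notna()]
    if isinstance(group_by, pd.Series):
        labels = group_by.reindex(sub.index)
    else:
        cols = list(group_by)
        labels = sub[cols[0]].astype(str)
        for col in cols[1:]:
            labels = labels + "." + sub[col].astype(str)
    if groups is not None:
        declared = set(groups)
        unknown = set(labels.unique()) - declared
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        order = list(groups)
    else:
        order = sorted(labels.unique())
    clonosets = {
        g: set(sub.loc[labels == g, clonotype_col]) for g in order
    }
    mat = pd.DataFrame(0, index=order, columns=order, dtype=int)
    if mode == "clonotype":
        for ga in order:
            for gb in order:
                mat.loc[ga, gb] = len(clonosets[ga] & clonosets[gb])
    else:
        for ga in order:
            members = sub.loc[labels == ga, clonotype_col]
            for gb in order:
                mat.loc[ga, gb] = int(members.isin(clonosets[gb]).sum())
    return mat


def fit_recurrence_powerlaw(freq_of_freq: pd.Series) -> tuple[float, float]:
    """Least-squares line on log10(recurrence level) vs log10(#chains).

    Levels with zero chain count are excluded.  Returns (slope, intercept);
    the straight-line fit in double-log space is the usual summary of the
    heavy-tailed chain abundance distribution.
    """
    fof = freq_of_freq[freq_of_freq > 0]
    if len(fof) < 2:
        raise ValueError("need at least two nonzero recurrence levels to fit")
    x = np.log10(fof.index.to_numpy(dtype=float))
    y = np.log10(fof.to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
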