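"""Expression-level quality control, TPM, in-silico FACS gating and centring.

Operates on a genes × cells count matrix from full-length (Smart-seq2 class)
single-T-cell RNA-seq.  The normalisation steps mirror a standard plate-based
pipeline:

* a simplified TPM that length-normalises counts within each cell under the
  assumption that all mapped reads have approximately the same length;
* robust cell filters — library size and detected-gene count below the
  population median minus ``nmads`` median absolute deviations, mitochondrial
  count fraction above 10%, and a T-cell identity gate requiring mean
  CD3D/CD3E/CD3G TPM above 10;
* in-silico FACS: CD4/CD8 compartment labels from expression thresholds
  (positive above 30 TPM, negative below 3, indeterminate between);
* size-factor normalisation (library-size factors by default, externally
  computed factors — e.g. pooling deconvolution — accepted), log2 transform,
  and per-patient gene centring so donor effects have zero mean.

All matrices are pandas DataFrames with gene symbols as the index and cell
identifiers as columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "QCReport",
    "CD3_GENES",
    "GATE_LABELS",
    "compute_tpm",
    "qc_filter_cells",
    "in_silico_facs",
    "normalize_and_center",
    "filter_low_genes",
    "read_count_matrix",
    "read_gene_model",
]

CD3_GENES = ("CD3D", "CD3E", "CD3G")
CD4_GENE = "CD4"
CD8_GENES = ("CD8A", "CD8B")

GATE_LABELS = ("CD4+CD8-", "CD4-CD8+", "CD4+CD8+", "CD4-CD8-", "undetermined")

# MAD consistency constant for a normal distribution.
_NORMAL_MAD_SCALE = 1.4826


@dataclass
class GeneModel:
    """Gene annotation: effective length (bp) and mitochondrial membership.

    Mitochondrial genes default to the ``MT-`` symbol prefix; an explicit
    gene set overrides the prefix rule.
    """

    lengths: pd.Series
    mito_genes: Optional[frozenset[str]] = None
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        self.lengths = pd.Series(self.lengths, dtype=float)
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0].tolist()
            raise ValueError(f"gene lengths must be positive; offending: {bad[:5]}")
        if self.mito_genes is not None:
            self.mito_genes = frozenset(self.mito_genes)

    def is_mito(self, genes: Sequence[str]) -> np.ndarray:
        if self.mito_genes is not None:
            return np.array([g in self.mito_genes for g in genes])
        return np.array([g.startswith(self.mito_prefix) for g in genes])

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "GeneModel":
        """Build from a TSV-derived frame with columns symbol, length_bp, is_mito."""
        lengths = pd.Series(df["length_bp"].values, index=df["symbol"], dtype=float)
        mito = frozenset(df.loc[df["is_mito"].astype(int) == 1, "symbol"])
        return cls(lengths=lengths, mito_genes=mito)


@dataclass
class QCReport:
    """Per-cell QC metrics, failing rules, and the thresholds that were used."""

    metrics: pd.DataFrame  # library_size, n_genes, mito_fraction, cd3_mean_tpm
    failures: pd.DataFrame  # boolean columns fail_library, fail_genes, fail_mito, fail_cd3
    thresholds: dict = field(default_factory=dict)

    @property
    def passed(self) -> pd.Series:
        return ~self.failures.any(axis=1)

    def failing_rules(self, cell_id: str) -> list[str]:
        row = self.failures.loc[cell_id]
        return [c for c in self.failures.columns if row[c]]


def _aligned_lengths(counts: pd.DataFrame, model: GeneModel) -> pd.Series:
    missing = counts.index.difference(model.lengths.index)
    if len(missing) > 0:
        raise ValueError(
            f"gene model lacks lengths for {len(missing)} genes, "
            f"e.g. {missing[:5].tolist()}"
        )
    return model.lengths.reindex(counts.index)


def compute_tpm(counts: pd.DataFrame, model: GeneModel) -> pd.DataFrame:
    """Simplified transcripts-per-million.

    TPM_ij = 1e6 · (C_ij / len_i) / Σ_i (C_ij / len_i).  Valid when mapped
    reads are of approximately equal length, so read counts are proportional
    to transcript molecules after length division.  Cells with zero total
    count are emitted as all-zero columns with a warning.
    """
    lengths = _aligned_lengths(counts, model)
    rate = counts.to_numpy(dtype=float) / lengths.to_numpy()[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) have zero total count; "
            "their TPM columns are emitted as zeros",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, colsum)
    tpm = 1e6 * rate / safe
    tpm[:, zero] = 0.0
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def _mad(values: np.ndarray, scale: str) -> float:
    med = np.median(values)
    raw = np.median(np.abs(values - med))
    return raw * (_NORMAL_MAD_SCALE if scale == "normal" else 1.0)


def qc_filter_cells(
    counts: pd.DataFrame,
    model: GeneModel,
    nmads: float = 3.0,
    mito_max: float = 0.10,
    cd3_min_tpm: float = 10.0,
    mad_scale: str = "normal",
) -> QCReport:
    """Flag low-quality cells.

    A cell fails if any of:

    * library size below ``median − nmads·MAD`` of all cells' library sizes;
    * detected genes (counts > 0) below ``median − nmads·MAD`` of all cells;
    * mitochondrial count fraction strictly above ``mito_max``;
    * mean TPM of CD3D, CD3E, CD3G not strictly above ``cd3_min_tpm``.

    Thresholds are computed once on the full input population.  ``mad_scale``
    is "normal" (MAD × 1.4826, the usual consistency convention) or "raw".
    """
    if counts.shape[1] == 0:
        raise ValueError("count matrix has no cells")
    if mad_scale not in ("normal", "raw"):
        raise ValueError("mad_scale must be 'normal' or 'raw'")
    missing_cd3 = [g for g in CD3_GENES if g not in counts.index]
    if missing_cd3:
        raise ValueError(f"CD3 genes absent from matrix: {missing_cd3}")

    arr = counts.to_numpy(dtype=float)
    library_size = arr.sum(axis=0)
    n_genes = (arr > 0).sum(axis=0)
    mito_mask = model.is_mito(counts.index)
    mito_fraction = np.divide(
        arr[mito_mask].sum(axis=0),
        library_size,
        out=np.zeros_like(library_size, dtype=float),
        where=library_size > 0,
    )
    tpm = compute_tpm(counts, model)
    cd3_mean = tpm.loc[list(CD3_GENES)].mean(axis=0).to_numpy()

    lib_thr = float(np.median(library_size) - nmads * _mad(library_size, mad_scale))
    gene_thr = float(np.median(n_genes) - nmads * _mad(n_genes.astype(float), mad_scale))

    metrics = pd.DataFrame(
        {
            "library_size": library_size,
            "n_genes": n_genes,
            "mito_fraction": mito_fraction,
            "cd3_mean_tpm": cd3_mean,
        },
        index=counts.columns,
    )
    failures = pd.DataFrame(
        {
            "fail_library": library_size < lib_thr,
            "fail_genes": n_genes < gene_thr,
            "fail_mito": mito_fraction > mito_max,
            "fail_cd3": ~(cd3_mean > cd3_min_tpm),
        },
        index=counts.columns,
    )
    thresholds = {
        "library_size_min": lib_thr,
        "n_genes_min": gene_thr,
        "mito_fraction_max": mito_max,
        "cd3_mean_tpm_min": cd3_min_tpm,
        "nmads": nmads,
        "mad_scale": mad_scale,
    }
    return QCReport(metrics=metrics, failures=failures, thresholds=thresholds)


def in_silico_facs(tpm: pd.DataFrame, hi: float = 30.0, lo: float = 3.0) -> pd.Series:
    """Classify cells into CD4/CD8 compartments from expression alone.

    The CD8 score is the mean TPM of CD8A and CD8B; the CD4 score is the CD4
    TPM.  A score above ``hi`` is positive, below ``lo`` negative, between
    the two indeterminate.  The label combines the two axes when both are
    determinate and is "undetermined" otherwise.
    """
    needed = [CD4_GENE, *CD8_GENES]
    missing = [g for g in needed if g not in tpm.index]
    if missing:
        raise ValueError(f"gating genes absent from matrix: {missing}")
    cd4 = tpm.loc[CD4_GENE].to_numpy(dtype=float)
    cd8 = tpm.loc[list(CD8_GENES)].mean(axis=0).to_numpy(dtype=float)

    def axis(score: np.ndarray) -> np.ndarray:
        out = np.full(score.shape, "?", dtype=object)
        out[score > hi] = "+"
        out[score < lo] = "-"
        return out

    cd4_sign, cd8_sign = axis(cd4), axis(cd8)
    labels = np.where(
        (cd4_sign == "?") | (cd8_sign == "?"),
        "undetermined",
        np.char.add(
            np.char.add("CD4", cd4_sign.astype(str)),
            np.char.add("CD8", cd8_sign.astype(str)),
        ),
    )
    return pd.Series(labels, index=tpm.columns, name="gate")


def normalize_and_center(
    counts: pd.DataFrame,
    patient_of: Mapping[str, str] | pd.Series,
    size_factors: Optional[pd.Series] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Size-factor normalise, log2-transform and centre by patient.

    ``size_factors`` are per-cell positive scalars (e.g. from a pooling
    deconvolution method); when omitted, library-size factors scaled to mean
    one are used.  Counts are divided by their factor, transformed as
    log2(x + pseudocount), then each gene is centred so its mean over every
    patient's cells is zero — removing additive donor effects.
    """
    patient_of = pd.Series(dict(patient_of)) if not isinstance(patient_of, pd.Series) else patient_of
    unknown = counts.columns.difference(patient_of.index)
    if len(unknown) > 0:
        raise ValueError(
            f"no patient recorded for {len(unknown)} cells, e.g. {unknown[:5].tolist()}"
        )
    if size_factors is None:
        lib = counts.sum(axis=0).astype(float)
        size_factors = lib / lib.mean()
    else:
        size_factors = pd.Series(size_factors, dtype=float)
        missing = counts.columns.difference(size_factors.index)
        if len(missing) > 0:
            raise ValueError(f"size factors missing for cells: {missing[:5].tolist()}")
        if (size_factors.reindex(counts.columns) <= 0).any():
            raise ValueError("size factors must be strictly positive")
    sf = size_factors.reindex(counts.columns).to_numpy()
    norm = np.log2(counts.to_numpy(dtype=float) / sf + pseudocount)
    out = pd.DataFrame(norm, index=counts.index, columns=counts.columns)
    patients = patient_of.reindex(counts.columns)
    centered = out.sub(out.T.groupby(patients.values).transform("mean").T)
    return centered


def filter_low_genes(counts: pd.DataFrame, min_mean_count: float = 1.0) -> pd.DataFrame:
    """Drop genes whose mean count over cells is ≤ ``min_mean_count``."""
    keep = counts.mean(axis=1) > min_mean_count
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_count_matrix(
    path,
    genes_path=None,
    barcodes_path=None,
) -> pd.DataFrame:
    """Read a genes × cells count matrix.

    ``path`` may be a MatrixMarket ``.mtx`` file (with one-column gene and
    barcode sidecar files) or a dense TSV with gene symbols in the first
    column and cell identifiers in the header.
    """
    path = str(path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        if genes_path is None or barcodes_path is None:
            raise ValueError(".mtx input requires genes_path and barcodes_path")
        mat = mmread(path).toarray()
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0]
        cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0]
        return pd.DataFrame(mat, index=genes, columns=cells)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_model(path) -> GeneModel:
    """Read a gene model TSV with columns symbol, length_bp, is_mito."""
    return GeneModel.from_table(pd.read_csv(path, sep="\t"))
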