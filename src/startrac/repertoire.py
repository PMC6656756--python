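"""Paired αβ TCR repertoire construction from per-cell assembled chains.

Single-cell TCR assembly (e.g. TraCeR on Smart-seq2 reads) yields, per cell,
zero or more α and β chain contigs with V/J segment calls, CDR3 sequences, a
productivity flag and an estimated chain abundance in TPM.  This module turns
those raw per-cell chain records into a clonotype-resolved repertoire:

1. abundance filtering — chains whose TPM does not exceed a chain-type
   specific threshold (α > 10, β > 15 by default) are discarded;
2. dominant-pair selection — per cell, the productive α–β combination of
   highest combined expression defines the cell's TCR;
3. clonotype assignment — cells with identical dominant pairs (V segment,
   J segment and CDR3 on both chains) form one clonotype, the presumed
   progeny of a single ancestral T cell;
4. invariant-cell classification — MAIT cells (TRAV1-2 joined to TRAJ33,
   TRAJ20 or TRAJ12) and iNKT cells (TRAV10–TRAJ18) are recognised from
   their semi-invariant α chains.

Clonotype identity defaults to nucleotide-level CDR3 comparison; amino-acid
identity is available for cross-patient convergence analyses.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "TCRChain",
    "DominantPair",
    "Clonotype",
    "ALPHA",
    "BETA",
    "MAIT_V",
    "MAIT_J",
    "INKT_V",
    "INKT_J",
    "filter_chains",
    "select_dominant_pair",
    "assign_clonotypes",
    "classify_invariant",
    "build_repertoire",
    "frame_to_chains",
    "read_chain_table",
    "write_clonotype_table",
]

ALPHA = "alpha"
BETA = "beta"

# Semi-invariant α-chain rearrangements.
MAIT_V = "TRAV1-2"
MAIT_J = frozenset({"TRAJ33", "TRAJ20", "TRAJ12"})
INKT_V = "TRAV10"
INKT_J = "TRAJ18"


@dataclass(frozen=True)
class TCRChain:
    """One assembled TCR chain of one cell."""

    cell_id: str
    chain_type: str  # "alpha" or "beta"
    v_segment: str
    j_segment: str
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    abundance_tpm: float

    def __post_init__(self) -> None:
        if self.chain_type not in (ALPHA, BETA):
            raise ValueError(
                f"chain_type must be {ALPHA!r} or {BETA!r}, got {self.chain_type!r}"
            )
        if self.abundance_tpm < 0:
            raise ValueError(
                f"abundance_tpm must be non-negative, got {self.abundance_tpm}"
            )
        if self.productive and self.cdr3_nt and len(self.cdr3_nt) % 3 != 0:
            warnings.warn(
                f"productive chain of cell {self.cell_id!r} has CDR3 nucleotide "
                f"length {len(self.cdr3_nt)} not a multiple of 3",
                stacklevel=2,
            )

    def key(self, aa_identity: bool = False) -> tuple[str, str, str]:
        """(V, J, CDR3) identity key; nucleotide CDR3 unless ``aa_identity``."""
        cdr3 = self.cdr3_aa if aa_identity else self.cdr3_nt
        return (self.v_segment, self.j_segment, cdr3)


@dataclass(frozen=True)
class DominantPair:
    """The productive α–β chain pair of highest combined expression in a cell."""

    alpha: TCRChain
    beta: TCRChain

    def __post_init__(self) -> None:
        if not (self.alpha.productive and self.beta.productive):
            raise ValueError("both chains of a dominant pair must be productive")
        if self.alpha.cell_id != self.beta.cell_id:
            raise ValueError("both chains of a dominant pair must come from one cell")

    def key(self, aa_identity: bool = False) -> tuple[tuple, tuple]:
        return (self.alpha.key(aa_identity), self.beta.key(aa_identity))


@dataclass
class Clonotype:
    """A dominant α–β pair shared by one or more cells."""

    clonotype_id: str
    alpha_key: tuple[str, str, str]
    beta_key: tuple[str, str, str]
    member_cells: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.member_cells)


def filter_chains(
    chains: Sequence[TCRChain],
    alpha_min_tpm: float = 10.0,
    beta_min_tpm: float = 15.0,
) -> list[TCRChain]:
    """Keep chains whose TPM strictly exceeds the chain-type threshold.

    The thresholds are exclusive: an α chain at exactly ``alpha_min_tpm`` is
    removed.  Input order is preserved and the input is not modified.
    """
    if alpha_min_tpm < 0 or beta_min_tpm < 0:
        raise ValueError("abundance thresholds must be non-negative")
    for c in chains:
        if c.abundance_tpm < 0:  # defensive; TCRChain already validates
            raise ValueError(f"negative abundance for cell {c.cell_id!r}")
    thr = {ALPHA: alpha_min_tpm, BETA: beta_min_tpm}
    return [c for c in chains if c.abundance_tpm > thr[c.chain_type]]


def select_dominant_pair(
    chains_of_one_cell: Sequence[TCRChain],
) -> Optional[DominantPair]:
    """Pick the productive α–β pair of highest combined TPM for one cell.

    Returns ``None`` when no productive α or no productive β is present.
    Combined expression is the sum of the two chain TPMs; exact ties are
    broken by lexicographic order of (α CDR3nt, β CDR3nt) so the choice is
    deterministic and data-independent.
    """
    cell_ids = {c.cell_id for c in chains_of_one_cell}
    if len(cell_ids) > 1:
        raise ValueError(f"chains from multiple cells passed: {sorted(cell_ids)}")
    alphas = [c for c in chains_of_one_cell if c.chain_type == ALPHA and c.productive]
    betas = [c for c in chains_of_one_cell if c.chain_type == BETA and c.productive]
    if not alphas or not betas:
        return None
    best = min(
        ((a, b) for a in alphas for b in betas),
        key=lambda ab: (
            -(ab[0].abundance_tpm + ab[1].abundance_tpm),
            ab[0].cdr3_nt,
            ab[1].cdr3_nt,
        ),
    )
    return DominantPair(alpha=best[0], beta=best[1])


def assign_clonotypes(
    cells: Iterable[tuple[str, DominantPair]],
    aa_identity: bool = False,
) -> tuple[pd.Series, list[Clonotype]]:
    """Group cells with identical dominant pairs into clonotypes.

    Two cells belong to the same clonotype iff the (V, J, CDR3) keys of both
    their α and β chains match exactly.  Clonotype identifiers are "C" plus
    the zero-padded rank of the canonicalised pair key in lexicographic
    order, so the labelling is invariant to input order.

    Returns a cell_id → clonotype_id Series and the clonotype list (sorted
    by id).
    """
    by_key: dict[tuple, Clonotype] = {}
    cell_to_key: dict[str, tuple] = {}
    for cell_id, pair in cells:
        if cell_id in cell_to_key:
            raise ValueError(f"duplicate cell_id {cell_id!r}")
        key = pair.key(aa_identity)
        cell_to_key[cell_id] = key
        if key not in by_key:
            by_key[key] = Clonotype(clonotype_id="", alpha_key=key[0], beta_key=key[1])
        by_key[key].member_cells.add(cell_id)
    width = max(4, len(str(len(by_key))))
    for rank, key in enumerate(sorted(by_key), start=1):
        by_key[key].clonotype_id = f"C{rank:0{width}d}"
    mapping = pd.Series(
        {cid: by_key[key].clonotype_id for cid, key in cell_to_key.items()},
        name="clonotype_id",
        dtype=object,
    )
    clonotypes = sorted(by_key.values(), key=lambda c: c.clonotype_id)
    return mapping, clonotypes


def classify_invariant(cell_chains: Sequence[TCRChain]) -> str:
    """Label a cell MAIT, iNKT or conventional from its productive α chains.

    Every productive α chain of the cell is scanned, not only the dominant
    one.  MAIT requires TRAV1-2 joined to TRAJ33, TRAJ20 or TRAJ12; iNKT
    requires TRAV10 joined to TRAJ18.  The two V segments are disjoint so
    the rules cannot both fire.
    """
    cell_ids = {c.cell_id for c in cell_chains}
    if len(cell_ids) > 1:
        raise ValueError(f"chains from multiple cells passed: {sorted(cell_ids)}")
    alphas = [c for c in cell_chains if c.chain_type == ALPHA and c.productive]
    for a in alphas:
        if a.v_segment == MAIT_V and a.j_segment in MAIT_J:
            return "MAIT"
    for a in alphas:
        if a.v_segment == INKT_V and a.j_segment == INKT_J:
            return "iNKT"
    return "conventional"


def build_repertoire(
    chains: Sequence[TCRChain],
    alpha_min_tpm: float = 10.0,
    beta_min_tpm: float = 15.0,
    aa_identity: bool = False,
) -> tuple[pd.DataFrame, list[Clonotype], dict[str, DominantPair]]:
    """Full pipeline: filter chains, pick dominant pairs, call clonotypes.

    Returns a per-cell table (cell_id, clonotype_id, invariant_class) for
    cells with a complete productive pair, the clonotype list, and the
    dominant pair of each such cell.  Invariant classification uses all
    productive α chains that survive the abundance filter.
    """
    kept = filter_chains(chains, alpha_min_tpm, beta_min_tpm)
    per_cell: dict[str, list[TCRChain]] = defaultdict(list)
    for c in kept:
        per_cell[c.cell_id].append(c)
    pairs: dict[str, DominantPair] = {}
    invariant: dict[str, str] = {}
    for cell_id, cc in per_cell.items():
        pair = select_dominant_pair(cc)
        if pair is None:
            continue
        pairs[cell_id] = pair
        invariant[cell_id] = classify_invariant(cc)
    mapping, clonotypes = assign_clonotypes(pairs.items(), aa_identity=aa_identity)
    table = pd.DataFrame(
        {
            "cell_id": list(pairs),
            "clonotype_id": [mapping[c] for c in pairs],
            "invariant_class": [invariant[c] for c in pairs],
        }
    )
    return table, clonotypes, pairs


# ---------------------------------------------------------------------------
# I/O: TraCeR-style chain summary tables
# ---------------------------------------------------------------------------

_CHAIN_CODE = {"A": ALPHA, "B": BETA, "alpha": ALPHA, "beta": BETA}


def frame_to_chains(df: pd.DataFrame) -> list[TCRChain]:
    """Convert a chain-table DataFrame (TSV schema) to TCRChain records.

    Expected columns: cell_id, chain (A/B), v_gene, j_gene, cdr3_nt,
    cdr3_aa, productive (TRUE/FALSE), tpm.
    """
    required = {"cell_id", "chain", "v_gene", "j_gene", "cdr3_nt", "cdr3_aa",
                "productive", "tpm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chain table missing columns: {sorted(missing)}")
    chains = []
    for row in df.itertuples(index=False):
        chain_type = _CHAIN_CODE.get(row.chain)
        if chain_type is None:
            raise ValueError(f"unknown chain code {row.chain!r}")
        chains.append(
            TCRChain(
                cell_id=row.cell_id,
                chain_type=chain_type,
                v_segment=row.v_gene,
                j_segment=row.j_gene,
                cdr3_nt="" if pd.isna(row.cdr3_nt) else row.cdr3_nt,
                cdr3_aa="" if pd.isna(row.cdr3_aa) else row.cdr3_aa,
                productive=str(row.productive).strip().upper() in ("TRUE", "1", "T"),
                abundance_tpm=float(row.tpm),
            )
        )
    return chains


def read_chain_table(path) -> list[TCRChain]:
    """Read a tab-separated per-cell chain table (TraCeR-style summary)."""
    return frame_to_chains(pd.read_csv(path, sep="\t", dtype=str))


def write_clonotype_table(clonotypes: Sequence[Clonotype], path) -> None:
    """Write clonotypes as TSV: ids, chain keys, size and member cells."""
    rows = []
    for ct in clonotypes:
        av, aj, ant = ct.alpha_key
        bv, bj, bnt = ct.beta_key
        rows.append(
            {
                "clonotype_id": ct.clonotype_id,
                "alpha_v": av,
                "alpha_j": aj,
                "alpha_cdr3nt": ant,
                "beta_v": bv,
                "beta_j": bj,
                "beta_cdr3nt": bnt,
                "n_cells": ct.size,
                "cell_ids": ";".join(sorted(ct.member_cells)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
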