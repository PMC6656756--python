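"""Synthetic clonal repertoires and expression matrices with known truth.

Every downstream computation in this package — chain filtering, clonotype
calling, invariant classification, QC, gating, the STARTRAC indices and the
DEG procedure — can be exercised against these generators without any
controlled-access download.  The generators emulate the statistical
structure the indices assume:

* **repertoire** — clonotypes with sizes from a geometric law (or explicit
  sizes) are nested within patients and their cells are spread over tissues
  and clusters by Dirichlet-multinomial allocation, so a single
  concentration parameter tunes how confined (→0) or uniform (→∞) each
  clonotype's tissue/cluster footprint is.  A configurable fraction of
  clonotypes carries the MAIT (TRAV1-2 + TRAJ33/20/12) or iNKT
  (TRAV10 + TRAJ18) α rearrangement; the default fractions match the
  roughly 1% MAIT / 0.03% iNKT composition typical of sorted αβ T cells.
  Dominant-chain TPMs are drawn above the abundance-filter thresholds
  (truncated log-normal); optional secondary productive chains and
  below-threshold / non-productive decoy chains exercise the filters.
* **expression** — per-cell counts follow a Dirichlet-multinomial: a bounded
  library size (uniform around a base depth) is distributed over genes
  according to population-specific proportions jittered by a Dirichlet with
  total concentration 1/dispersion, the multivariate analogue of
  negative-binomial noise.  Marker genes (CD3D/E/G, CD4, CD8A/B, IL2RA,
  FOXP3) carry population-specific mass; mitochondrial genes carry ~4% of
  the library.  Planted low-quality cells get either a collapsed library
  (low-depth) or mitochondrial mass far above the 10% QC bound (mito-heavy).

All randomness flows from one integer seed through a single explicit
``numpy.random.Generator``; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .expression import GeneModel
from .repertoire import INKT_J, INKT_V, MAIT_J, MAIT_V

__all__ = [
    "RepertoireSpec",
    "ExpressionSpec",
    "simulate_repertoire",
    "simulate_expression",
]

# Codons with no stop codon reachable, for CDR3 synthesis.
_CODONS = (
    "GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT",
    "AAA", "CTG", "ATG", "AAT", "CCT", "CAG", "CGT", "AGC",
)
_CDR3_PREFIX = "TGTGCC"  # canonical Cys-Ala start
_CDR3_SUFFIX = "TTTGGC"  # Phe-Gly end

_TRAV_POOL = tuple(f"TRAV{i}" for i in (2, 3, 4, 5, 6, 8, 9, 12, 13, 14, 16, 17, 19, 21))
_TRAJ_POOL = tuple(f"TRAJ{i}" for i in (4, 6, 10, 15, 23, 28, 30, 37, 40, 43, 45, 48))
_TRBV_POOL = tuple(f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 11, 12, 15, 19, 20, 28))
_TRBJ_POOL = tuple(f"TRBJ{i}" for i in (1, 2))


@dataclass
class RepertoireSpec:
    """Parameters of a synthetic annotated repertoire.

    ``cluster_budgets`` set the expected cluster sizes (allocation weights);
    the total cell count equals their sum.  ``tissue_concentration`` and
    ``cluster_concentration`` are symmetric Dirichlet parameters governing
    how each clonotype spreads over tissues/clusters (small → confined,
    large → uniform).  ``clone_size_mean`` parameterises a geometric clone
    size law on {1, 2, ...}; ``clone_sizes`` overrides it with explicit
    sizes.  The seed is mandatory.
    """

    seed: int
    n_patients: int = 12
    tissues: tuple[str, ...] = ("P", "N", "T")
    cluster_budgets: Mapping[str, int] = field(
        default_factory=lambda: {f"C{i:02d}": 200 for i in range(1, 7)}
    )
    clone_size_mean: float = 2.0
    clone_sizes: Optional[Sequence[int]] = None
    tissue_concentration: float = 1.0
    cluster_concentration: float = 1.0
    mait_fraction: float = 0.0103
    inkt_fraction: float = 0.0003
    tpm_log_mean: float = float(np.log(200.0))
    tpm_log_sd: float = 0.5
    alpha_min_tpm: float = 10.0
    beta_min_tpm: float = 15.0
    secondary_chain_rate: float = 0.1
    decoy_chain_rate: float = 0.2

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if len(self.tissues) < 1:
            raise ValueError("need at least one tissue")
        if not self.cluster_budgets or any(b < 1 for b in self.cluster_budgets.values()):
            raise ValueError("cluster budgets must all be >= 1")
        if self.clone_sizes is None and self.clone_size_mean < 1:
            raise ValueError("geometric clone-size mean must be >= 1")
        if self.clone_sizes is not None and (
            len(self.clone_sizes) == 0 or any(s < 1 for s in self.clone_sizes)
        ):
            raise ValueError("explicit clone sizes must be positive")
        if self.tissue_concentration <= 0 or self.cluster_concentration <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if not 0 <= self.mait_fraction + self.inkt_fraction <= 1:
            raise ValueError("invariant fractions must lie in [0, 1]")


def _truncated_lognormal(rng, mean_log, sd_log, lower, size=None):
    """Log-normal draws conditioned on exceeding ``lower``."""
    out = rng.lognormal(mean_log, sd_log, size=size)
    bad = out <= lower
    while np.any(bad):
        out = np.where(bad, rng.lognormal(mean_log, sd_log, size=np.shape(out)), out)
        bad = out <= lower
    return out


def _unique_cdr3(rng, used: set[str]) -> str:
    while True:
        k = int(rng.integers(4, 9))
        body = "".join(_CODONS[int(i)] for i in rng.integers(0, len(_CODONS), size=k))
        nt = _CDR3_PREFIX + body + _CDR3_SUFFIX
        if nt not in used:
            used.add(nt)
            return nt


def _clone_sizes(rng, spec: RepertoireSpec, total: int) -> np.ndarray:
    if spec.clone_sizes is not None:
        sizes = np.asarray(spec.clone_sizes, dtype=int)
        if sizes.sum() > total:
            raise ValueError(
                f"explicit clone sizes sum to {sizes.sum()} but budgets allow {total}"
            )
        return sizes
    p = 1.0 / spec.clone_size_mean
    sizes: list[int] = []
    acc = 0
    while acc < total:
        draw = rng.geometric(p, size=max(16, (total - acc) // 2))
        for s in draw:
            s = int(s)
            if acc + s >= total:
                sizes.append(total - acc)
                acc = total
                break
            sizes.append(s)
            acc += s
    return np.asarray(sizes, dtype=int)


def simulate_repertoire(
    spec: RepertoireSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw an annotated repertoire with ground truth.

    Returns ``(cells, chains, truth)``: the annotated cell table (cell_id,
    patient, tissue, cluster, clonotype_id, invariant_class), the per-cell
    chain table in the TSV schema consumed by the repertoire pipeline, and
    a truth record containing the planted clonotype partition, chain keys,
    clone sizes and invariant labels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    clusters = list(spec.cluster_budgets)
    budgets = np.array([spec.cluster_budgets[c] for c in clusters], dtype=float)
    k = len(clusters)
    j = len(spec.tissues)
    total = int(budgets.sum())

    sizes = _clone_sizes(rng, spec, total)
    n_clonotypes = len(sizes)

    # Invariant designation: mark clonotypes until the target cell counts
    # (fraction of total) are covered, MAIT first.
    invariant_label = ["conventional"] * n_clonotypes
    mait_target = round(total * spec.mait_fraction)
    inkt_target = round(total * spec.inkt_fraction)
    order = rng.permutation(n_clonotypes)
    mait_cells = inkt_cells = 0
    for idx in order:
        if mait_cells < mait_target:
            invariant_label[idx] = "MAIT"
            mait_cells += int(sizes[idx])
        elif inkt_cells < inkt_target:
            invariant_label[idx] = "iNKT"
            inkt_cells += int(sizes[idx])
        else:
            break

    used_alpha: set[str] = set()
    used_beta: set[str] = set()
    cluster_alpha = spec.cluster_concentration * k * budgets / budgets.sum()

    id_width = max(4, len(str(n_clonotypes)))
    cell_rows = []
    chain_rows = []
    truth_keys = {}
    cell_counter = 0
    for t in range(n_clonotypes):
        tid = f"T{t + 1:0{id_width}d}"
        size = int(sizes[t])
        label = invariant_label[t]
        patient = f"P{int(rng.integers(spec.n_patients)) + 1:02d}"
        if label == "MAIT":
            av, aj = MAIT_V, str(rng.choice(sorted(MAIT_J)))
        elif label == "iNKT":
            av, aj = INKT_V, INKT_J
        else:
            av = str(rng.choice(_TRAV_POOL))
            aj = str(rng.choice(_TRAJ_POOL))
        bv = str(rng.choice(_TRBV_POOL))
        bj = str(rng.choice(_TRBJ_POOL))
        a_nt = _unique_cdr3(rng, used_alpha)
        b_nt = _unique_cdr3(rng, used_beta)
        a_aa = str(Seq(a_nt).translate())
        b_aa = str(Seq(b_nt).translate())
        truth_keys[tid] = {"alpha": (av, aj, a_nt), "beta": (bv, bj, b_nt)}

        tissue_probs = rng.dirichlet(np.full(j, spec.tissue_concentration))
        cluster_probs = rng.dirichlet(cluster_alpha)
        cell_tissues = rng.choice(j, size=size, p=tissue_probs)
        cell_clusters = rng.choice(k, size=size, p=cluster_probs)
        a_tpm = _truncated_lognormal(
            rng, spec.tpm_log_mean, spec.tpm_log_sd, spec.alpha_min_tpm, size=size
        )
        b_tpm = _truncated_lognormal(
            rng, spec.tpm_log_mean, spec.tpm_log_sd, spec.beta_min_tpm, size=size
        )
        for i in range(size):
            cell_counter += 1
            cid = f"cell{cell_counter:05d}"
            cell_rows.append(
                {
                    "cell_id": cid,
                    "patient": patient,
                    "tissue": spec.tissues[cell_tissues[i]],
                    "cluster": clusters[cell_clusters[i]],
                    "clonotype_id": tid,
                    "invariant_class": label,
                }
            )
            chain_rows.append(
                dict(cell_id=cid, chain="A", v_gene=av, j_gene=aj, cdr3_nt=a_nt,
                     cdr3_aa=a_aa, productive="TRUE", tpm=float(a_tpm[i]))
            )
            chain_rows.append(
                dict(cell_id=cid, chain="B", v_gene=bv, j_gene=bj, cdr3_nt=b_nt,
                     cdr3_aa=b_aa, productive="TRUE", tpm=float(b_tpm[i]))
            )
            if rng.random() < spec.secondary_chain_rate:
                # A weaker productive alpha: survives the abundance filter but
                # never outranks the dominant pair.
                sec_nt = _unique_cdr3(rng, used_alpha)
                sec_tpm = float(
                    rng.uniform(spec.alpha_min_tpm + 1e-6, float(a_tpm[i]))
                )
                chain_rows.append(
                    dict(cell_id=cid, chain="A", v_gene=str(rng.choice(_TRAV_POOL)),
                         j_gene=str(rng.choice(_TRAJ_POOL)), cdr3_nt=sec_nt,
                         cdr3_aa=str(Seq(sec_nt).translate()), productive="TRUE",
                         tpm=sec_tpm)
                )
            if rng.random() < spec.decoy_chain_rate:
                # Either a below-threshold productive chain or an abundant
                # non-productive one; both must be rejected upstream.
                is_alpha = bool(rng.random() < 0.5)
                dec_nt = _unique_cdr3(rng, used_alpha if is_alpha else used_beta)
                thr = spec.alpha_min_tpm if is_alpha else spec.beta_min_tpm
                if rng.random() < 0.5:
                    tpm, prod = float(rng.uniform(0.1, thr)), "TRUE"
                else:
                    tpm, prod = float(rng.uniform(thr * 2, thr * 20)), "FALSE"
                chain_rows.append(
                    dict(
                        cell_id=cid,
                        chain="A" if is_alpha else "B",
                        v_gene=str(rng.choice(_TRAV_POOL if is_alpha else _TRBV_POOL)),
                        j_gene=str(rng.choice(_TRAJ_POOL if is_alpha else _TRBJ_POOL)),
                        cdr3_nt=dec_nt,
                        cdr3_aa=str(Seq(dec_nt).translate()),
                        productive=prod,
                        tpm=tpm,
                    )
                )

    cells = pd.DataFrame(cell_rows)
    chains = pd.DataFrame(chain_rows)
    truth = {
        "clonotype_of_cell": dict(zip(cells["cell_id"], cells["clonotype_id"])),
        "invariant_of_cell": dict(zip(cells["cell_id"], cells["invariant_class"])),
        "clonotype_keys": truth_keys,
        "clone_sizes": {tid: int(s) for tid, s in zip(sorted(truth_keys), sizes)},
        "params": {**asdict(spec), "clone_sizes": (
            list(map(int, spec.clone_sizes)) if spec.clone_sizes is not None else None
        )},
    }
    return cells, chains, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

_DEFAULT_PROFILES: dict[str, dict[str, float]] = {
    # Gene → fraction of the cell's library.  CD3 is common to all T cells;
    # lineage markers are exclusive and off-lineage markers are absent, the
    # large-effect-size regime where in-silico gating is unambiguous.
    "CD8": {"CD3D": 0.012, "CD3E": 0.012, "CD3G": 0.012,
            "CD8A": 0.012, "CD8B": 0.012, "CD4": 0.0,
            "IL2RA": 0.0, "FOXP3": 0.0},
    "CD4": {"CD3D": 0.012, "CD3E": 0.012, "CD3G": 0.012,
            "CD8A": 0.0, "CD8B": 0.0, "CD4": 0.012,
            "IL2RA": 0.0, "FOXP3": 0.0},
    "Treg": {"CD3D": 0.012, "CD3E": 0.012, "CD3G": 0.012,
             "CD8A": 0.0, "CD8B": 0.0, "CD4": 0.012,
             "IL2RA": 0.015, "FOXP3": 0.008},
}

_GATE_OF_POPULATION = {"CD8": "CD4-CD8+", "CD4": "CD4+CD8-", "Treg": "CD4+CD8-"}

MARKER_GENES = ("CD3D", "CD3E", "CD3G", "CD4", "CD8A", "CD8B", "IL2RA", "FOXP3")


@dataclass
class ExpressionSpec:
    """Parameters of the synthetic count matrix.

    ``dispersion`` is the inverse of the Dirichlet concentration that
    jitters per-cell gene proportions (0 → pure multinomial); the marginal
    counts are beta-binomial, the finite-library analogue of a
    negative-binomial gene model.  Library sizes are uniform within
    ``±library_jitter`` of ``base_library``.  Low-quality cells are planted
    as "mito" (mitochondrial mass raised to ``mito_heavy_weight``) or
    "depth" (library multiplied by ``low_depth_factor``).
    """

    seed: int
    population_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in _DEFAULT_PROFILES.items()}
    )
    population_of: Optional[Mapping[str, str]] = None  # cluster -> population
    n_background: int = 800
    background_shape: float = 1.0
    dispersion: float = 0.0005
    base_library: int = 4000
    library_jitter: float = 0.25
    n_mito: int = 8
    mito_weight: float = 0.04
    mito_heavy_fraction: float = 0.05
    mito_heavy_weight: float = 0.45
    low_depth_fraction: float = 0.05
    low_depth_factor: float = 0.05

    def validate(self) -> None:
        for pop, profile in self.population_profiles.items():
            if any(w < 0 for w in profile.values()):
                raise ValueError(f"negative marker weight in population {pop!r}")
            if sum(profile.values()) + self.mito_weight >= 1:
                raise ValueError(f"marker + mito mass of {pop!r} leaves no background")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 < self.low_depth_factor < 1:
            raise ValueError("low_depth_factor must be in (0, 1)")
        if not 0 <= self.mito_heavy_fraction + self.low_depth_fraction < 1:
            raise ValueError("planted low-quality fractions must leave normal cells")


def simulate_expression(
    spec: ExpressionSpec,
    cells: pd.DataFrame,
) -> tuple[pd.DataFrame, GeneModel, dict]:
    """Draw a genes × cells count matrix matched to an annotated cell table.

    Returns ``(counts, gene_model, truth)``; truth records each cell's
    population, planted low-quality status ("none"/"mito"/"depth") and the
    gate label implied by its population.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    clusters = sorted(cells["cluster"].unique())
    pops = sorted(spec.population_profiles)
    if spec.population_of is None:
        population_of = {c: pops[i % len(pops)] for i, c in enumerate(clusters)}
    else:
        population_of = dict(spec.population_of)
        missing = set(clusters) - set(population_of)
        if missing:
            raise ValueError(f"population_of lacks clusters: {sorted(missing)}")
        unknown = set(population_of.values()) - set(pops)
        if unknown:
            raise ValueError(f"population_of names unknown populations: {sorted(unknown)}")

    mito_genes = [f"MT-G{i + 1}" for i in range(spec.n_mito)]
    background_genes = [f"BG{i + 1:04d}" for i in range(spec.n_background)]
    genes = list(MARKER_GENES) + mito_genes + background_genes
    n_genes = len(genes)

    # Fixed background heterogeneity shared by all populations.
    background_raw = rng.gamma(spec.background_shape, size=spec.n_background)
    background_raw /= background_raw.sum()

    weights_of_pop: dict[str, np.ndarray] = {}
    for pop in pops:
        profile = spec.population_profiles[pop]
        w = np.zeros(n_genes)
        for g, frac in profile.items():
            if g not in MARKER_GENES:
                raise ValueError(f"profile gene {g!r} is not a marker gene")
            w[genes.index(g)] = frac
        w[len(MARKER_GENES):len(MARKER_GENES) + spec.n_mito] = (
            spec.mito_weight / spec.n_mito
        )
        background_mass = 1.0 - w.sum()
        w[len(MARKER_GENES) + spec.n_mito:] = background_raw * background_mass
        weights_of_pop[pop] = w

    n_cells = len(cells)
    cell_ids = cells["cell_id"].tolist()
    n_mito_heavy = round(n_cells * spec.mito_heavy_fraction)
    n_low_depth = round(n_cells * spec.low_depth_fraction)
    planted = rng.choice(n_cells, size=n_mito_heavy + n_low_depth, replace=False)
    low_quality = np.full(n_cells, "none", dtype=object)
    low_quality[planted[:n_mito_heavy]] = "mito"
    low_quality[planted[n_mito_heavy:]] = "depth"

    mito_slice = slice(len(MARKER_GENES), len(MARKER_GENES) + spec.n_mito)
    counts = np.zeros((n_genes, n_cells), dtype=int)
    populations = []
    for c, (cid, cluster) in enumerate(zip(cell_ids, cells["cluster"])):
        pop = population_of[cluster]
        populations.append(pop)
        w = weights_of_pop[pop].copy()
        if low_quality[c] == "mito":
            non_mito = 1.0 - spec.mito_weight
            w[mito_slice] = spec.mito_heavy_weight / spec.n_mito
            scale = (1.0 - spec.mito_heavy_weight) / non_mito
            w[: mito_slice.start] *= scale
            w[mito_slice.stop:] *= scale
        lib = spec.base_library * rng.uniform(
            1 - spec.library_jitter, 1 + spec.library_jitter
        )
        if low_quality[c] == "depth":
            lib *= spec.low_depth_factor
        lib = max(1, int(round(lib)))
        pos = w > 0
        p = np.zeros(n_genes)
        p[pos] = rng.dirichlet(w[pos] / spec.dispersion)
        counts[:, c] = rng.multinomial(lib, p)

    lengths = pd.Series(
        rng.integers(500, 3001, size=n_genes).astype(float), index=genes
    )
    model = GeneModel(lengths=lengths, mito_genes=frozenset(mito_genes))
    counts_df = pd.DataFrame(counts, index=genes, columns=cell_ids)
    truth = {
        "population_of_cell": dict(zip(cell_ids, populations)),
        "low_quality_of_cell": dict(zip(cell_ids, low_quality)),
        "gate_of_cell": {
            cid: _GATE_OF_POPULATION.get(pop, "undetermined")
            for cid, pop in zip(cell_ids, populations)
        },
        "population_of_cluster": population_of,
        "params": {
            **asdict(spec),
            "population_profiles": {
                p: dict(v) for p, v in spec.population_profiles.items()
            },
            "population_of": population_of,
        },
    }
    return counts_df, model, truth
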