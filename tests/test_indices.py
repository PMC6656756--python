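"""STARTRAC index family: closed forms, oracle equivalence, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.stats import chi2_contingency

from startrac import (
    cluster_weighted_index,
    clonotype_entropy,
    index_report,
    pairwise_index,
    startrac_dist,
    startrac_expa,
)

# ---------------------------------------------------------------------------
# Independent naive oracles (plain loops, no shared code with the package)
# ---------------------------------------------------------------------------


def oracle_entropy(counts):
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def oracle_expa(sizes):
    n = len(sizes)
    if n == 0:
        return float("nan")
    if n == 1:
        return 1.0 if sum(sizes) > 1 else float("nan")
    return 1.0 - oracle_entropy(sizes) / math.log2(n)


def oracle_cluster_index(cells, cluster, cat_col):
    """Weighted clonotype entropy by explicit per-clonotype loops."""
    sub = cells[(cells["cluster"] == cluster) & cells["clonotype_id"].notna()]
    sub = sub[sub["invariant_class"] == "conventional"]
    pool = cells[cells["clonotype_id"].notna()]
    pool = pool[pool["invariant_class"] == "conventional"]
    if len(sub) == 0:
        return float("nan")
    total = 0.0
    for clonotype in sub["clonotype_id"].unique():
        weight = (sub["clonotype_id"] == clonotype).sum() / len(sub)
        members = pool[pool["clonotype_id"] == clonotype]
        counts = [
            (members[cat_col] == cat).sum() for cat in members[cat_col].unique()
        ]
        total += weight * oracle_entropy(counts)
    return total


class TestExpa:
    @pytest.mark.parametrize(
        "sizes,expected",
        [
            ([1, 1, 1, 1], 0.0),  # uniform singletons: evenness 1
            ([5], 1.0),  # one expanded clonotype
            ([2, 1, 1], 1.0 - 1.5 / math.log2(3)),
            ([3, 3, 3], 0.0),  # equal sizes are even regardless of expansion
        ],
    )
    def test_closed_forms(self, sizes, expected):
        assert startrac_expa(sizes) == pytest.approx(expected, abs=1e-12)
        assert startrac_expa(sizes) == pytest.approx(oracle_expa(sizes), abs=1e-12)

    def test_single_cell_cluster_undefined(self):
        assert math.isnan(startrac_expa([1]))

    def test_empty_undefined(self):
        assert math.isnan(startrac_expa([]))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            startrac_expa([0, 2])
        with pytest.raises(ValueError):
            startrac_expa([1.5, 2])

    @settings(max_examples=100, derandomize=True)
    @given(sizes=hst.lists(hst.integers(min_value=1, max_value=50), min_size=2, max_size=30))
    def test_bounds_and_oracle_agreement(self, sizes):
        value = startrac_expa(sizes)
        assert 0.0 <= value <= 1.0
        assert value == pytest.approx(oracle_expa(sizes), abs=1e-12)


class TestClonotypeEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((2, 2), 1.0),
            ((4, 0, 0), 0.0),
            ((1, 1, 1, 1), 2.0),
            ((2, 1, 1), 1.5),
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert clonotype_entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            clonotype_entropy([0, 0])

    @settings(max_examples=100, derandomize=True)
    @given(counts=hst.lists(hst.integers(min_value=0, max_value=100), min_size=1, max_size=10))
    def test_entropy_bounds(self, counts):
        if sum(counts) == 0:
            return
        h = clonotype_entropy(counts)
        assert -1e-12 <= h <= math.log2(len(counts)) + 1e-12
        assert h == pytest.approx(oracle_entropy(counts), abs=1e-12)


class TestDist:
    def test_hand_computed_two_by_two(self):
        cells = pd.DataFrame(
            {
                "cluster": ["A"] * 40 + ["B"] * 40,
                "tissue": ["P"] * 30 + ["T"] * 10 + ["P"] * 10 + ["T"] * 30,
            }
        )
        ct = startrac_dist(cells)
        assert np.allclose(ct.expected.to_numpy(), 20.0)
        assert np.allclose(ct.roe.to_numpy(), [[1.5, 0.5], [0.5, 1.5]])
        assert ct.chi2 == pytest.approx(20.0)
        assert ct.dof == 1
        # identity: sum of E * Roe equals total observed
        assert (ct.expected * ct.roe).to_numpy().sum() == pytest.approx(80.0)

    def test_matches_scipy_chi2_contingency(self, small_repertoire):
        cells, _, _ = small_repertoire
        ct = startrac_dist(cells)
        ref = chi2_contingency(ct.observed.to_numpy(), correction=False)
        assert ct.chi2 == pytest.approx(ref.statistic)
        assert ct.pvalue == pytest.approx(ref.pvalue)
        assert ct.dof == ref.dof
        assert np.allclose(ct.expected.to_numpy(), ref.expected_freq)

    def test_proportional_table_gives_unit_roe(self):
        # every cluster split across tissues in the same 2:1:1 proportions
        rows = []
        for cluster, n in (("A", 40), ("B", 80)):
            rows += [(cluster, "P")] * (n // 2)
            rows += [(cluster, "N")] * (n // 4)
            rows += [(cluster, "T")] * (n // 4)
        ct = startrac_dist(pd.DataFrame(rows, columns=["cluster", "tissue"]))
        assert np.allclose(ct.roe.to_numpy(), 1.0)
        assert ct.chi2 == pytest.approx(0.0)

    def test_single_cluster_degenerate(self):
        cells = pd.DataFrame({"cluster": ["A"] * 10, "tissue": ["P"] * 6 + ["T"] * 4})
        ct = startrac_dist(cells)
        assert np.allclose(ct.roe.to_numpy(), 1.0)
        assert ct.dof == 0
        assert math.isnan(ct.pvalue)

    def test_zero_margin_roe_undefined_not_zero(self):
        cells = pd.DataFrame(
            {
                "cluster": ["A", "A", "B", "B"],
                "tissue": pd.Categorical(
                    ["P", "T", "P", "T"], categories=["P", "T", "N"]
                ),
            }
        )
        ct = startrac_dist(cells)
        assert ct.roe["N"].isna().all()
        assert ct.roe[["P", "T"]].notna().all().all()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            startrac_dist(pd.DataFrame({"cluster": [], "tissue": []}))


def _toy_cells(rows):
    return pd.DataFrame(
        rows, columns=["cell_id", "cluster", "tissue", "clonotype_id", "invariant_class"]
    ).assign(invariant_class=lambda d: d["invariant_class"].fillna("conventional"))


class TestClusterWeightedIndex:
    def test_hand_case_half_bit(self):
        # cluster X: clonotype A (2 cells split P/T -> 1 bit), B (2 cells all T -> 0)
        rows = [
            ("c1", "X", "P", "A", None),
            ("c2", "X", "T", "A", None),
            ("c3", "X", "T", "B", None),
            ("c4", "X", "T", "B", None),
        ]
        assert cluster_weighted_index(_toy_cells(rows), "X", "migr") == pytest.approx(0.5)

    def test_confined_clonotypes_zero(self):
        rows = [(f"c{i}", "X", "P", f"T{i % 3}", None) for i in range(9)]
        assert cluster_weighted_index(_toy_cells(rows), "X", "migr") == pytest.approx(0.0)

    def test_uniform_over_three_tissues_is_log2_3(self):
        rows = []
        for t, tissue in enumerate(["P", "N", "T"]):
            rows += [(f"c{i}{t}", "X", tissue, "A", None) for i in range(4)]
        assert cluster_weighted_index(_toy_cells(rows), "X", "migr") == pytest.approx(
            math.log2(3)
        )

    def test_distribution_spans_whole_dataset_not_cluster(self):
        # clonotype A has cells in clusters X and Y across tissues; the migr
        # entropy seen from X must include the Y cells' tissues
        rows = [
            ("c1", "X", "P", "A", None),
            ("c2", "Y", "T", "A", None),
        ]
        assert cluster_weighted_index(_toy_cells(rows), "X", "migr") == pytest.approx(1.0)

    def test_empty_cluster_undefined(self):
        rows = [("c1", "X", "P", "A", None)]
        assert math.isnan(cluster_weighted_index(_toy_cells(rows), "Z", "migr"))

    def test_invariant_cells_excluded_by_default(self):
        rows = [
            ("c1", "X", "P", "A", None),
            ("c2", "X", "T", "A", None),
            ("c3", "X", "P", "M", "MAIT"),
            ("c4", "X", "T", "M", "MAIT"),
        ]
        cells = _toy_cells(rows)
        only_conventional = cluster_weighted_index(cells, "X", "migr")
        with_invariant = cluster_weighted_index(cells, "X", "migr", exclude_invariant=False)
        assert only_conventional == pytest.approx(1.0)
        assert with_invariant == pytest.approx(1.0)  # both clonotypes split 1/1
        # removing the conventional clonotype shows exclusion matters
        mait_only = cells[cells["invariant_class"] == "MAIT"]
        assert math.isnan(cluster_weighted_index(mait_only, "X", "migr"))

    def test_oracle_equivalence_on_simulated_repertoire(self, full_repertoire):
        cells, _, _ = full_repertoire
        for cluster in cells["cluster"].unique():
            for mode, col in (("migr", "tissue"), ("tran", "cluster")):
                got = cluster_weighted_index(cells, cluster, mode)
                want = oracle_cluster_index(cells, cluster, col)
                assert got == pytest.approx(want, abs=1e-12), (cluster, mode)

    def test_report_bounds_on_simulated_repertoire(self, full_repertoire):
        cells, _, _ = full_repertoire
        report, dist = index_report(cells)
        j = cells["tissue"].nunique()
        k = cells["cluster"].nunique()
        valid = report.dropna()
        assert ((valid["expa"] >= 0) & (valid["expa"] <= 1)).all()
        assert (valid["migr"] <= math.log2(j) + 1e-12).all()
        assert (valid["tran"] <= math.log2(k) + 1e-12).all()
        assert (dist.expected.to_numpy().sum()) == pytest.approx(len(cells))

    def test_relabeling_invariance(self, small_repertoire):
        cells, _, _ = small_repertoire
        report, _ = index_report(cells)
        renamed = cells.assign(
            tissue=cells["tissue"].map({"P": "blood", "N": "normal", "T": "tumour"}),
            clonotype_id="X" + cells["clonotype_id"],
        )
        report2, _ = index_report(renamed)
        pd.testing.assert_frame_equal(report, report2)

    def test_subsampling_stability(self, full_repertoire):
        """Half-sample indices track full-data values up to entropy-estimation
        bias (subsampling shrinks per-clonotype distributions, so entropic
        indices are biased low by a fraction of a bit)."""
        cells, _, _ = full_repertoire
        report, _ = index_report(cells)
        rng = np.random.default_rng(42)
        diffs = []
        for _ in range(5):
            half = cells.sample(frac=0.5, random_state=int(rng.integers(2**31)))
            sub_report, _ = index_report(half)
            joined = report.join(sub_report, rsuffix="_half").dropna()
            diffs.append((joined["migr"] - joined["migr_half"]).abs().mean())
            # the bias is downward: subsampling must not inflate migration
            assert (joined["migr_half"] <= joined["migr"] + 0.1).all()
        assert np.mean(diffs) < 0.3


class TestPairwiseIndex:
    def test_renormalised_pair_entropy_one_bit(self):
        rows = (
            [(f"p{i}", "X", "P", "A", None) for i in range(2)]
            + [(f"t{i}", "X", "T", "A", None) for i in range(2)]
            + [(f"n{i}", "X", "N", "A", None) for i in range(5)]
        )
        value = pairwise_index(_toy_cells(rows), "X", "migr", ("P", "T"))
        assert value == pytest.approx(1.0)

    def test_point_mass_after_restriction_is_zero(self):
        rows = [(f"c{i}", "X", "P", "A", None) for i in range(3)]
        assert pairwise_index(_toy_cells(rows), "X", "migr", ("P", "T")) == pytest.approx(0.0)

    def test_absent_clonotypes_excluded(self):
        # clonotype B lives only in N: must not dilute the (P, T) average
        rows = [
            ("c1", "X", "P", "A", None),
            ("c2", "X", "T", "A", None),
            ("c3", "X", "N", "B", None),
            ("c4", "X", "N", "B", None),
        ]
        assert pairwise_index(_toy_cells(rows), "X", "migr", ("P", "T")) == pytest.approx(1.0)

    def test_identical_pair_rejected(self):
        rows = [("c1", "X", "P", "A", None)]
        with pytest.raises(ValueError):
            pairwise_index(_toy_cells(rows), "X", "migr", ("P", "P"))

    def test_at_most_one_bit_on_simulated_repertoire(self, full_repertoire):
        cells, _, _ = full_repertoire
        for cluster in cells["cluster"].unique()[:3]:
            v = pairwise_index(cells, cluster, "migr", ("P", "T"))
            assert math.isnan(v) or 0.0 <= v <= 1.0 + 1e-12
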