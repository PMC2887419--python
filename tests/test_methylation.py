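"""Methylation-state classification, region extraction and pair testing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cgikit import (
    InsufficientDataError,
    MethState,
    classify_cpg,
    classify_cpgs_table,
    classify_island,
    compare_island_pair,
    extract_weber_regions,
    island_mean_methylation,
    swa_heterogeneity,
    tissue_label,
)
from cgikit.genome_io import GenomicInterval


def records(values, n_support=5):
    return [(f"t{i}", v, n_support) for i, v in enumerate(values)]


def mannwhitney_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumeration over label assignments.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)), capped at 1; ties handled by
    midranks, identically distributed assignments enumerated exhaustively.
    """
    pooled = np.concatenate([a, b])
    n_a = len(a)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1

    def u_of(idx_a):
        r_a = ranks[list(idx_a)].sum()
        return r_a - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n_a)]
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestTissueLabel:
    @pytest.mark.parametrize(
        "value, state",
        [
            (80.0, MethState.METHYLATED),  # boundary: exactly 80 is methylated
            (95.0, MethState.METHYLATED),
            (20.0, MethState.INTERMEDIATE),  # boundary: exactly 20 is intermediate
            (79.999, MethState.INTERMEDIATE),
            (19.999, MethState.UNMETHYLATED),
            (0.0, MethState.UNMETHYLATED),
        ],
    )
    def test_cutoffs(self, value, state):
        assert tissue_label(value) is state


class TestClassifyCpg:
    def test_all_tissues_methylated(self):
        assert classify_cpg(records([85, 90, 95, 88, 92, 99])) is MethState.METHYLATED

    def test_differential_when_both_extremes_present(self):
        # 2 methylated, 2 unmethylated, 2 intermediate: intermediate 2/6 < 50%
        assert classify_cpg(records([90, 85, 5, 10, 50, 60])) is MethState.DIFFERENTIAL

    def test_too_few_tissues_unclassified(self):
        assert classify_cpg(records([90, 85, 95, 88, 92])) is MethState.UNCLASSIFIED

    def test_low_clone_records_dropped(self):
        recs = [(f"t{i}", 90.0, 1) for i in range(8)]
        assert classify_cpg(recs) is MethState.UNCLASSIFIED

    def test_never_unmethylated_veto_routes_to_differential(self):
        # methylated in 5/6 tissues, but a single unmethylated tissue vetoes
        # the methylated call; both extremes present -> differential
        assert classify_cpg(records([90, 90, 90, 90, 90, 5])) is MethState.DIFFERENTIAL

    def test_majority_without_extreme_conflict_is_unclassified(self):
        # 3 methylated vs 3 intermediate: no >50% majority, no differential
        assert classify_cpg(records([90, 90, 90, 50, 50, 50])) is MethState.UNCLASSIFIED

    def test_samples_averaged_within_tissue(self):
        recs = [("s0", 70, 5), ("s0", 95, 5)] + [(f"s{i}", 90, 5) for i in range(1, 6)]
        # tissue s0 averages to 82.5 -> methylated; 6 tissues all methylated
        assert classify_cpg(recs) is MethState.METHYLATED

    def test_table_classification_agrees_with_per_cpg(self):
        rng = np.random.default_rng(9)
        rows = []
        for pos in range(0, 40):
            for i in range(8):
                rows.append(
                    ("chr1", pos * 10, f"t{i}", float(rng.uniform(0, 100)), int(rng.integers(1, 6)))
                )
        df = pd.DataFrame(rows, columns=["chrom", "cpg_position", "tissue", "mean_methylation", "n_support"])
        table_states = classify_cpgs_table(df)
        for (chrom, pos), state in table_states.items():
            sub = df[(df.chrom == chrom) & (df.cpg_position == pos)]
            assert classify_cpg(sub[["tissue", "mean_methylation", "n_support"]]) is state


class TestClassifyIsland:
    def test_unmethylated_majority_over_classified(self):
        # 10 CpGs, 6 classified: 4 unmethylated + 2 intermediate -> unmethylated
        states = dict.fromkeys(range(4), MethState.UNMETHYLATED)
        states.update(dict.fromkeys(range(4, 6), MethState.INTERMEDIATE))
        assert classify_island(list(range(10)), states) is MethState.UNMETHYLATED

    def test_coverage_rule(self):
        states = dict.fromkeys(range(4), MethState.UNMETHYLATED)  # 4 of 10 covered
        assert classify_island(list(range(10)), states) is MethState.UNCLASSIFIED

    def test_differential_majority(self):
        states = dict.fromkeys(range(4), MethState.DIFFERENTIAL)
        states.update(dict.fromkeys(range(4, 6), MethState.INTERMEDIATE))
        assert classify_island(list(range(10)), states) is MethState.DIFFERENTIAL

    def test_methylated_veto_by_single_unmethylated_cpg(self):
        states = dict.fromkeys(range(5), MethState.METHYLATED)
        states[5] = MethState.UNMETHYLATED
        assert classify_island(list(range(6)), states) is MethState.UNCLASSIFIED

    def test_states_partition(self):
        # every combination yields exactly one state
        rng = np.random.default_rng(1)
        options = list(MethState)
        for _ in range(200):
            n = int(rng.integers(1, 12))
            states = {i: options[rng.integers(0, len(options))] for i in range(n)}
            out = classify_island(list(range(n)), states)
            assert out in MethState


class TestWeberRegions:
    def test_differential_pair(self):
        res = extract_weber_regions({"r1": {"fibroblast": 0.1, "sperm": 0.5}})
        assert res.kept == ("r1",) and res.differential == ("r1",)

    def test_concordant_pair(self):
        res = extract_weber_regions({"r1": {"fibroblast": 0.1, "sperm": 0.2}})
        assert res.kept == ("r1",) and res.concordant_unmethylated == ("r1",)

    def test_methylated_everywhere_dropped(self):
        res = extract_weber_regions({"r1": {"fibroblast": 0.4, "sperm": 0.6}})
        assert res.kept == ()

    def test_conservation_kept_equals_concordant_plus_differential(self):
        rng = np.random.default_rng(4)
        regions = {
            f"r{i}": {"a": float(rng.uniform(0, 0.6)), "b": float(rng.uniform(0, 0.6))}
            for i in range(100)
        }
        res = extract_weber_regions(regions)
        assert len(res.kept) == len(res.differential) + len(res.concordant_unmethylated)


class TestIslandMeanMethylation:
    def reads(self, triples):
        return pd.DataFrame(triples, columns=["cpg_position", "mean_methylation", "n_support"])

    def test_mean_over_covered(self):
        table = self.reads([(0, 10, 12), (10, 20, 15), (20, 30, 11)])
        assert island_mean_methylation([0, 10, 20, 30], table) == pytest.approx(20.0)

    def test_exactly_half_covered_is_undefined(self):
        table = self.reads([(0, 10, 12), (10, 20, 15)])
        assert island_mean_methylation([0, 10, 20, 30], table) is None

    def test_low_read_cytosines_excluded(self):
        table = self.reads([(0, 10, 9), (10, 20, 15), (20, 30, 11)])
        # position 0 has only 9 reads: coverage 2 of 4, not > 50%
        assert island_mean_methylation([0, 10, 20, 30], table) is None

    def test_strands_averaged(self):
        table = self.reads([(0, 10, 12), (0, 30, 12), (10, 50, 15), (20, 40, 11)])
        assert island_mean_methylation([0, 10, 20], table) == pytest.approx((20 + 50 + 40) / 3)


class TestSwaHeterogeneity:
    def meth(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "cpg_position", "tissue", "mean_methylation", "n_support"]
        )

    def outer(self, start, end):
        return GenomicInterval(chrom="chr1", start=start, end=end)

    def test_two_inner_one_tissue(self):
        inner = [self.outer(0, 100), self.outer(200, 300)]
        rows = [("chr1", 10, "t1", 10.0, 5), ("chr1", 210, "t1", 90.0, 5)]
        res = swa_heterogeneity([self.outer(0, 1000)], inner, self.meth(rows))
        assert list(res.max_difference.values()) == [pytest.approx(80.0)]

    def test_max_over_tissues(self):
        inner = [self.outer(0, 100), self.outer(200, 300)]
        rows = [
            ("chr1", 10, "t1", 50.0, 5), ("chr1", 210, "t1", 65.0, 5),
            ("chr1", 10, "t2", 20.0, 5), ("chr1", 210, "t2", 60.0, 5),
        ]
        res = swa_heterogeneity([self.outer(0, 1000)], inner, self.meth(rows))
        assert list(res.max_difference.values()) == [pytest.approx(40.0)]

    def test_max_over_pairs_of_three_inner(self):
        inner = [self.outer(0, 100), self.outer(200, 300), self.outer(400, 500)]
        rows = [
            ("chr1", 10, "t1", 10.0, 5),
            ("chr1", 210, "t1", 50.0, 5),
            ("chr1", 410, "t1", 90.0, 5),
        ]
        res = swa_heterogeneity([self.outer(0, 1000)], inner, self.meth(rows))
        assert list(res.max_difference.values()) == [pytest.approx(80.0)]

    def test_outer_without_two_inner_skipped(self):
        res = swa_heterogeneity([self.outer(0, 1000)], [self.outer(0, 100)], self.meth([]))
        assert res.n_tested == 0 and res.n_skipped == 1


class TestCompareIslandPair:
    def test_identical_multisets_not_significant(self):
        res = compare_island_pair([5, 5, 7], [5, 5, 7])
        assert res.p_value == pytest.approx(1.0) and not res.significant

    def test_separated_triples_exact_p(self):
        res = compare_island_pair([1, 2, 3], [10, 11, 12])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert not res.significant

    def test_large_separated_samples_significant(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 10, size=30)
        b = rng.uniform(50, 60, size=30)
        res = compare_island_pair(a, b)
        assert res.significant and res.p_value < 1e-6

    def test_empty_side_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_island_pair([], [1.0])

    def test_matches_exact_enumeration_small_samples(self):
        rng = np.random.default_rng(11)
        cases = []
        for n_a in (2, 3, 4, 6):
            for n_b in (2, 3, 6):
                cases.append((rng.integers(0, 5, n_a).astype(float), rng.integers(0, 5, n_b).astype(float)))
        cases.append((np.array([1.0, 1.0, 2.0]), np.array([1.0, 3.0, 3.0])))
        for a, b in cases:
            expected = mannwhitney_exact_oracle(a, b)
            res = compare_island_pair(a, b)
            assert res.p_value == pytest.approx(expected, abs=1e-9), (a, b)
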