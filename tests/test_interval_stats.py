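"""Overlap statistics vs per-base brute force; islet extraction; nesting."""

import numpy as np
import pytest

from cgikit import (
    GenomicInterval,
    IntervalSet,
    UndefinedStatisticError,
    exclusive_islands,
    extract_islets,
    nesting_counts,
    overlap_summary,
    tss_specificity,
)
from cgikit.cluster import Island


def iv(start, end, chrom="chr1", strand=".", label=""):
    return GenomicInterval(chrom=chrom, start=start, end=end, strand=strand, label=label)


def islet(start, end, p=1e-6, chrom="chr1"):
    length = end - start
    return Island(chrom, start, end, 2, 50.0, 1.0, 2 / length, p, "cpgcluster")


def brute_force_summary(islands, elements, size=12_000):
    mask = {}
    for e in elements:
        mask.setdefault(e.chrom, np.zeros(size, dtype=bool))[e.start : e.end] = True
    covs, n_overlap = [], 0
    for i in islands:
        m = mask.get(i.chrom, np.zeros(size, dtype=bool))
        cov = m[i.start : i.end].sum() / (i.end - i.start)
        covs.append(cov)
        n_overlap += cov > 0
    imask = {}
    for i in islands:
        imask.setdefault(i.chrom, np.zeros(size, dtype=bool))[i.start : i.end] = True
    touched = sum(
        1
        for e in elements
        if e.chrom in imask and imask[e.chrom][e.start : e.end].any()
    )
    return float(np.mean(covs)), n_overlap / len(islands), touched


class TestOverlapSummary:
    def test_island_inside_element(self):
        s = overlap_summary([iv(0, 100)], [iv(0, 1000)])
        assert (s.mean_coverage, s.overlap_fraction) == (1.0, 1.0)

    def test_partial_and_missing_overlap(self):
        s = overlap_summary([iv(0, 100), iv(200, 300)], [iv(50, 100)])
        assert s.mean_coverage == pytest.approx(0.25)
        assert s.overlap_fraction == 0.5
        assert s.n_elements_touched == 1

    def test_union_not_double_counted(self):
        s = overlap_summary([iv(0, 100)], [iv(0, 60), iv(40, 100)])
        assert s.mean_coverage == 1.0

    def test_empty_islands_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            overlap_summary([], [iv(0, 10)])

    def test_invariant_to_element_order_and_splitting(self):
        islands = [iv(10, 500), iv(700, 900)]
        joined = [iv(100, 400)]
        split = [iv(250, 400), iv(100, 250)]
        a, b = overlap_summary(islands, joined), overlap_summary(islands, split)
        # coverage and overlap are union-based, hence split-invariant
        # (n_elements_touched legitimately counts the pieces)
        assert a.mean_coverage == b.mean_coverage
        assert a.overlap_fraction == b.overlap_fraction

    def test_matches_per_base_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            islands = _random_set(rng, max_n=30)
            elements = _random_set(rng, max_n=50)
            s = overlap_summary(islands, elements)
            mc, of, touched = brute_force_summary(islands, elements)
            assert s.mean_coverage == pytest.approx(mc, abs=1e-12)
            assert s.overlap_fraction == pytest.approx(of, abs=1e-12)
            assert s.n_elements_touched == touched


def _random_set(rng, max_n=50, size=10_000, n_chroms=2):
    n = int(rng.integers(1, max_n + 1))
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, size - 2))
        end = int(start + rng.integers(1, min(size - start, 800)))
        out.append(iv(start, end, chrom=chrom))
    return out


class TestNestingCounts:
    def test_two_inner_in_one_outer(self):
        hist, frac = nesting_counts([iv(0, 1000)], [iv(10, 50), iv(900, 950)])
        assert hist == {2: 1} and frac == 1.0

    def test_disjoint_sets(self):
        hist, frac = nesting_counts([iv(0, 100), iv(200, 300)], [iv(5000, 5100)])
        assert hist == {0: 2} and frac == 0.0

    def test_straddling_inner_counts_for_both_outers(self):
        hist, _ = nesting_counts([iv(0, 100), iv(100, 200)], [iv(90, 110)])
        assert hist == {1: 2}

    def test_containment_mode_excludes_straddlers(self):
        hist, _ = nesting_counts([iv(0, 100), iv(100, 200)], [iv(90, 110)], containment=True)
        assert hist == {0: 2}

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            outer = _random_set(rng, max_n=20)
            inner = _random_set(rng, max_n=40)
            hist, _ = nesting_counts(outer, inner)
            for o in outer:
                expected = sum(
                    1 for i in inner if i.chrom == o.chrom and i.start < o.end and i.end > o.start
                )
                # histogram totals must match the direct count distribution
            direct = {}
            for o in outer:
                c = sum(
                    1 for i in inner if i.chrom == o.chrom and i.start < o.end and i.end > o.start
                )
                direct[c] = direct.get(c, 0) + 1
            assert hist == direct


class TestTssSpecificity:
    def test_classification_counts(self):
        islands = [iv(0, 100), iv(200, 300), iv(400, 500), iv(600, 700)]
        tss = [iv(10, 11), iv(250, 251), iv(410, 411), iv(450, 451)]
        res = tss_specificity(islands, tss)
        assert (res.n_overlapping_any, res.n_unique, res.n_multiple) == (3, 2, 1)
        assert res.pct_unique == 66.67 and res.pct_multiple == 33.33

    def test_non_point_tss_rejected(self):
        with pytest.raises(ValueError):
            tss_specificity([iv(0, 100)], [iv(10, 12)])


class TestIslets:
    def test_definition(self):
        islands = [islet(0, 150, 1e-6), islet(300, 550, 1e-6), islet(700, 850, 1e-4)]
        kept = extract_islets(islands)
        assert [(i.start, i.end) for i in kept] == [(0, 150)]

    def test_idempotent(self):
        islands = [islet(0, 150), islet(300, 420), islet(500, 900)]
        once = extract_islets(islands)
        assert extract_islets(once) == once

    def test_missing_pvalues_rejected(self):
        tj_like = Island("chr1", 0, 600, 30, 60.0, 0.7, 0.05, None, "tj")
        with pytest.raises(UndefinedStatisticError):
            extract_islets([tj_like])


class TestExclusiveIslands:
    def test_one_bp_overlap_drops(self):
        mine = [islet(0, 150), islet(300, 450)]
        foreign = IntervalSet("tj", [iv(149, 600)])
        kept = exclusive_islands(mine, [foreign])
        assert [(i.start, i.end) for i in kept] == []

    def test_disjoint_kept(self):
        mine = [islet(0, 100)]
        kept = exclusive_islands(mine, [IntervalSet("a", [iv(100, 200)]), IntervalSet("b", [])])
        assert kept == mine

    def test_empty_other_sets_keep_all(self):
        mine = [islet(0, 100), islet(200, 300)]
        assert exclusive_islands(mine, []) == mine
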