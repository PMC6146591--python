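import itertools
import logging
import math

import numpy as np
import pytest
from scipy.stats import chi2, hypergeom

from nsamap.assoc_stats import (
    ContingencyTable,
    chi_square_test,
    density_profile,
    fisher_exact,
    odds_ratio,
    permutation_test,
    profile_correlation,
    shuffle_intervals,
    window_association,
)
from nsamap.io_formats import ChromSizes, GenomicInterval, PeakSet


# ---------------------------------------------------------------------------
# odds ratio


def test_odds_ratio_no_association():
    assert odds_ratio(ContingencyTable(1, 1, 1, 1)) == 1.0


def test_odds_ratio_single_cell_table():
    # 170/40 colocalized/isolated spots vs 110/83: cross-product ratio
    t = ContingencyTable(170, 40, 110, 83)
    assert odds_ratio(t) == pytest.approx((170 * 83) / (40 * 110))
    assert odds_ratio(t) == pytest.approx(3.2068, abs=1e-3)


def test_odds_ratio_row_scale_invariance():
    a = ContingencyTable(7, 3, 11, 13)
    b = ContingencyTable(7 * 5, 3 * 5, 11, 13)
    assert odds_ratio(a) == pytest.approx(odds_ratio(b))


def test_odds_ratio_zero_cell(caplog):
    with caplog.at_level(logging.WARNING):
        assert odds_ratio(ContingencyTable(5, 0, 0, 5)) == math.inf
    assert "infinite" in caplog.text
    corrected = odds_ratio(ContingencyTable(5, 0, 0, 5), haldane=True)
    assert corrected == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))


# ---------------------------------------------------------------------------
# chi-square


def test_chi_square_single_cell_table():
    stat, p = chi_square_test(ContingencyTable(170, 40, 110, 83))
    # closed form N(ad-bc)^2 / (r1 r2 c1 c2)
    expect = 403 * (170 * 83 - 40 * 110) ** 2 / (210 * 193 * 280 * 123)
    assert stat == pytest.approx(expect)
    assert p == pytest.approx(chi2.sf(expect, 1))
    assert p < 5e-7


def test_chi_square_perfect_independence():
    stat, p = chi_square_test(ContingencyTable(10, 10, 10, 10))
    assert stat == 0.0 and p == 1.0


def test_chi_square_matches_cell_sum_oracle(rng):
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(1, 80, size=4))
        t = ContingencyTable(a, b, c, d)
        n = t.total
        expected = [
            (a + b) * (a + c) / n, (a + b) * (b + d) / n,
            (c + d) * (a + c) / n, (c + d) * (b + d) / n,
        ]
        brute = sum(
            (o - e) ** 2 / e for o, e in zip((a, b, c, d), expected)
        )
        stat, _ = chi_square_test(t)
        assert stat == pytest.approx(brute)


def test_chi_square_zero_margin_errors():
    with pytest.raises(ValueError):
        chi_square_test(ContingencyTable(0, 0, 5, 5))


# ---------------------------------------------------------------------------
# Fisher's exact


def test_fisher_trivial_and_extreme():
    assert fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)
    # 2 / C(10, 5)
    assert fisher_exact(ContingencyTable(5, 0, 0, 5)) == pytest.approx(2 / 252)


def fisher_oracle(t):
    """Two-sided exact p by full enumeration over tables with fixed margins."""
    r1, c1, n = t.a + t.b, t.a + t.c, t.total
    p_obs = hypergeom.pmf(t.a, n, c1, r1)
    total = 0.0
    for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = hypergeom.pmf(a, n, c1, r1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(60):
        cells = [int(x) for x in rng.integers(0, 11, size=4)]
        if sum(cells) == 0 or sum(cells) > 40:
            continue
        t = ContingencyTable(*cells)
        assert fisher_exact(t) == pytest.approx(fisher_oracle(t), abs=1e-9)


# ---------------------------------------------------------------------------
# density profiles


def test_density_profile_counts_and_conservation(sizes):
    pts = [("chrA", 10), ("chrA", 20), ("chrA", 30), ("chrB", 400_000)]
    prof = density_profile(pts, sizes, bin=1000)
    assert prof.counts["chrA"][0] == 3
    assert prof.counts["chrB"][400] == 1
    assert prof.n_points == 4


def test_density_profile_chromosome_sized_bins(sizes):
    pts = [("chrA", 10), ("chrB", 400_000), ("chrB", 499_999)]
    prof = density_profile(pts, sizes, bin=1_000_000)
    assert list(prof.counts["chrA"]) == [1]
    assert list(prof.counts["chrB"]) == [2]


def test_profile_correlation_identity_and_reversal(sizes):
    rng = np.random.default_rng(7)
    pts = [("chrA", int(x)) for x in rng.integers(0, 1_000_000, size=500)]
    p1 = density_profile(pts, sizes, bin=100_000)
    rho, _ = profile_correlation(p1, p1, "spearman")
    assert rho == 1.0
    # strictly monotone counts, reversed -> spearman -1
    small = ChromSizes({"c": 50})
    a = density_profile([("c", i) for i in range(50) for _ in range(i + 1)],
                        small, bin=10)
    b_counts = {"c": a.counts["c"][::-1].copy()}
    from nsamap.assoc_stats import DensityProfile

    b = DensityProfile(bin=10, counts=b_counts)
    rho, _ = profile_correlation(a, b, "spearman")
    assert rho == pytest.approx(-1.0)


def test_profile_correlation_binning_mismatch(sizes):
    p1 = density_profile([("chrA", 1)], sizes, bin=1000)
    p2 = density_profile([("chrA", 1)], sizes, bin=2000)
    with pytest.raises(ValueError):
        profile_correlation(p1, p2)


# ---------------------------------------------------------------------------
# interval shuffling


def test_shuffle_preserves_lengths_and_is_seeded(sizes):
    peaks = PeakSet("p", [
        GenomicInterval("chrA", 0, 10_000),
        GenomicInterval("chrA", 500_000, 800_000),
        GenomicInterval("chrB", 0, 200_000),
    ])
    a = shuffle_intervals(peaks, sizes, np.random.default_rng(3))
    b = shuffle_intervals(peaks, sizes, np.random.default_rng(3))
    assert sorted(iv.length for iv in a) == sorted(iv.length for iv in peaks)
    assert a.intervals == b.intervals
    c = shuffle_intervals(peaks, sizes, np.random.default_rng(4))
    assert c.intervals != a.intervals


def test_shuffle_rejects_oversized_interval():
    sizes = ChromSizes({"c": 100})
    peaks = PeakSet("p", [GenomicInterval("c", 0, 100)])
    # exactly chromosome-sized is fine
    shuffled = shuffle_intervals(peaks, sizes, np.random.default_rng(0))
    assert shuffled.intervals[0].length == 100
    big = ChromSizes({"c": 99})
    with pytest.raises(ValueError):
        shuffle_intervals(peaks, big, np.random.default_rng(0))


def test_shuffle_start_distribution_is_uniform():
    sizes = ChromSizes({"c": 1_000})
    peaks = PeakSet("p", [GenomicInterval("c", 0, 100)])
    rng = np.random.default_rng(11)
    starts = [
        shuffle_intervals(peaks, sizes, rng).intervals[0].start
        for _ in range(10_000)
    ]
    # starts uniform on [0, 900]; chi-square goodness of fit over 10 bins
    counts, _ = np.histogram(starts, bins=10, range=(0, 901))
    expected = len(starts) / 10
    stat = float(((counts - expected) ** 2 / expected).sum())
    assert chi2.sf(stat, df=9) > 0.01


# ---------------------------------------------------------------------------
# permutation test


def reads_in_stat(peaks, points):
    return sum(
        1 for c, m in points
        if any(iv.chrom == c and iv.start <= m < iv.end for iv in peaks.intervals)
    )


def test_permutation_minimum_p(sizes):
    # observed strictly greater than every null draw -> p = 1/(n_perm+1)
    peaks = PeakSet("p", [GenomicInterval("chrA", 0, 1_000)])
    points = [("chrA", i) for i in range(0, 1000, 10)]  # all inside the peak
    res = permutation_test(
        reads_in_stat, peaks, points, sizes, n_perm=1000, seed=5
    )
    assert res.observed == 100
    assert res.p == pytest.approx(1 / 1001)
    assert res.p < 0.001


def test_permutation_tail_less(sizes):
    peaks = PeakSet("p", [GenomicInterval("chrA", 0, 1_000)])
    points = [("chrB", 10)]
    res = permutation_test(
        reads_in_stat, peaks, points, sizes, n_perm=99, tail="less", seed=5
    )
    assert res.observed == 0
    # observed is minimal, but null is almost always 0 too -> p near 1
    assert 0 < res.p <= 1


def test_permutation_rejects_zero_n_perm(sizes):
    peaks = PeakSet("p", [GenomicInterval("chrA", 0, 1_000)])
    with pytest.raises(ValueError):
        permutation_test(reads_in_stat, peaks, [], sizes, n_perm=0)


# ---------------------------------------------------------------------------
# window association


def test_window_association_perfect_and_disjoint():
    sizes = ChromSizes({"c": 10_000})
    half = PeakSet("a", [GenomicInterval("c", 0, 5_000)])
    t = window_association(half, half, sizes, window=1000)
    assert (t.a, t.b, t.c, t.d) == (5, 0, 0, 5)
    assert odds_ratio(t) == math.inf
    other = PeakSet("b", [GenomicInterval("c", 5_000, 10_000)])
    t2 = window_association(half, other, sizes, window=1000)
    assert t2.a == 0


def test_window_association_matches_bruteforce(rng):
    sizes = ChromSizes({"c1": 5_000, "c2": 3_000})
    for _ in range(100):
        def rand_set(label):
            ivs = []
            for chrom, limit in sizes.items():
                pos = 0
                for _ in range(int(rng.integers(0, 5))):
                    pos += int(rng.integers(1, 800))
                    end = min(pos + int(rng.integers(1, 700)), limit)
                    if pos >= end or pos >= limit:
                        break
                    ivs.append(GenomicInterval(chrom, pos, end))
                    pos = end
            return PeakSet(label, ivs)

        a, b = rand_set("a"), rand_set("b")
        window = int(rng.integers(50, 500))
        got = window_association(a, b, sizes, window)
        counts = {"a": 0, "b": 0, "c": 0, "d": 0}
        for chrom, limit in sizes.items():
            for w0 in range(0, limit, window):
                w1 = min(w0 + window, limit)
                hit_a = any(iv.chrom == chrom and iv.start < w1 and w0 < iv.end
                            for iv in a.intervals)
                hit_b = any(iv.chrom == chrom and iv.start < w1 and w0 < iv.end
                            for iv in b.intervals)
                key = {True: {True: "a", False: "b"}, False: {True: "c", False: "d"}}
                counts[key[hit_a][hit_b]] += 1
        assert (got.a, got.b, got.c, got.d) == tuple(counts.values())
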