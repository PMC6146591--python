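import logging

import numpy as np
import pytest

from nsamap.io_formats import ChromSizes, GenomicInterval, PairRecord, PeakSet
from nsamap.peaks import (
    PeakCallParams,
    boundary_alignment,
    call_broad_peaks,
    candidate_peaks,
    cluster_dna_ends,
    overlap_peaksets,
    proximity_count,
    reads_in_peaks,
    union_peaks,
)
from .conftest import make_pair


def pairs_at(midpoints, chrom="chrA", prefix="r"):
    """Pairs whose DNA-end midpoints are the given positions."""
    out = []
    for i, m in enumerate(midpoints):
        out.append(
            make_pair(f"{prefix}{i}", ("chrB", 0, 50), (chrom, int(m), int(m) + 1))
        )
    return out


# ---------------------------------------------------------------------------
# clustering


def test_cluster_gap_rule():
    pairs = pairs_at([100, 150, 500_000])
    clusters = cluster_dna_ends(pairs, PeakCallParams(cluster_max_gap=1000))
    assert [(c.midpoints, c.read_count) for c in clusters] == [
        ((100, 150), 2),
        ((500_000,), 1),
    ]


def test_cluster_all_within_gap():
    pairs = pairs_at([0, 50, 120, 180])
    (cluster,) = cluster_dna_ends(pairs, PeakCallParams(cluster_max_gap=100))
    assert cluster.read_count == 4 and cluster.span == 180


def brute_single_linkage(midpoints, gap):
    """O(n^2) single-linkage: repeatedly merge any two clusters whose
    nearest members are within the gap."""
    clusters = [{m} for m in midpoints]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if min(
                    abs(a - b) for a in clusters[i] for b in clusters[j]
                ) <= gap:
                    clusters[i] |= clusters.pop(j)
                    merged = True
                    break
            if merged:
                break
    return sorted(tuple(sorted(c)) for c in clusters)


def test_cluster_matches_bruteforce_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(1, 40))
        gap = int(rng.integers(1, 500))
        mids = rng.integers(0, 5000, size=n)
        got = cluster_dna_ends(pairs_at(mids), PeakCallParams(cluster_max_gap=gap))
        got_sets = sorted(tuple(c.midpoints) for c in got)
        # brute oracle works on multisets of positions
        expect = brute_single_linkage(list(map(int, mids)), gap)
        got_unique = sorted(tuple(sorted(set(m))) for m in got_sets)
        assert got_unique == expect


# ---------------------------------------------------------------------------
# candidate peaks


@pytest.mark.parametrize(
    "n_reads, span, kept",
    [(9, 600_000, True), (8, 600_000, False), (20, 400_000, False),
     (9, 500_000, True)],
)
def test_candidate_peak_thresholds(n_reads, span, kept):
    mids = np.linspace(0, span, n_reads).astype(int)
    clusters = cluster_dna_ends(pairs_at(mids), PeakCallParams(cluster_max_gap=span))
    result = candidate_peaks(clusters, PeakCallParams())
    assert (len(result) == 1) is kept


def test_candidate_filter_monotone(rng):
    mids = rng.integers(0, 2_000_000, size=200)
    clusters = cluster_dna_ends(pairs_at(mids), PeakCallParams(cluster_max_gap=50_000))
    prev = None
    for min_reads in (1, 5, 9, 20):
        n = len(candidate_peaks(clusters, PeakCallParams(min_reads=min_reads,
                                                         min_cluster_span=1)))
        if prev is not None:
            assert n <= prev
        prev = n
    prev = None
    for span in (1, 100_000, 500_000, 2_000_000):
        n = len(candidate_peaks(clusters, PeakCallParams(min_reads=1,
                                                         min_cluster_span=span)))
        if prev is not None:
            assert n <= prev
        prev = n


# ---------------------------------------------------------------------------
# broad peaks


BIG = ChromSizes({"chr1": 100_000_000})


def test_broad_peaks_uniform_background_yields_none():
    rng = np.random.default_rng(101)
    mids = rng.integers(0, 100_000_000, size=10_000)
    called = call_broad_peaks(pairs_at(mids, chrom="chr1"), BIG)
    assert len(called) == 0


def test_broad_peaks_recover_planted_region():
    rng = np.random.default_rng(102)
    n = 10_000
    n_in = 3_000
    planted = (40_000_000, 41_000_000)
    mids = np.concatenate([
        rng.integers(*planted, size=n_in),
        rng.integers(0, 100_000_000, size=n - n_in),
    ])
    called = call_broad_peaks(pairs_at(mids, chrom="chr1"), BIG)
    assert len(called) == 1
    iv = called.intervals[0]
    covered = max(0, min(iv.end, planted[1]) - max(iv.start, planted[0]))
    assert covered >= 0.8 * (planted[1] - planted[0])


def test_broad_peaks_duplication_invariance():
    rng = np.random.default_rng(103)
    mids = np.concatenate([
        rng.integers(10_000_000, 11_000_000, size=2_000),
        rng.integers(0, 100_000_000, size=5_000),
    ])
    pairs = pairs_at(mids, chrom="chr1")
    doubled = pairs + [
        PairRecord(p.rna, p.dna, p.read_id + "_dup") for p in pairs
    ]
    a = call_broad_peaks(pairs, BIG)
    b = call_broad_peaks(doubled, BIG)
    assert a.intervals == b.intervals


def test_broad_peaks_order_invariant_and_deterministic():
    rng = np.random.default_rng(104)
    mids = np.concatenate([
        rng.integers(10_000_000, 11_000_000, size=2_000),
        rng.integers(0, 100_000_000, size=5_000),
    ])
    pairs = pairs_at(mids, chrom="chr1")
    a = call_broad_peaks(pairs, BIG)
    b = call_broad_peaks(pairs[::-1], BIG)
    c = call_broad_peaks(pairs, BIG)
    assert a.intervals == b.intervals == c.intervals
    assert a.read_counts == c.read_counts


def test_broad_peaks_empty_input_warns(caplog):
    with caplog.at_level(logging.WARNING):
        called = call_broad_peaks([], BIG)
    assert len(called) == 0 and "empty" in caplog.text


# ---------------------------------------------------------------------------
# reads in peaks


def peakset(ivs, label="p"):
    return PeakSet(label, [GenomicInterval(*iv) for iv in ivs])


def test_reads_in_peaks_trivial(sizes):
    pairs = pairs_at([10, 500, 900_000])
    whole = peakset([("chrA", 0, 1_000_000)])
    assert reads_in_peaks(pairs, whole) == (3, 1.0)
    assert reads_in_peaks(pairs, PeakSet("none", [])) == (0, 0.0)


def test_reads_in_peaks_matches_bruteforce(rng):
    for _ in range(100):
        mids = rng.integers(0, 10_000, size=int(rng.integers(1, 50)))
        pairs = pairs_at(mids)
        ivs = []
        pos = 0
        for _ in range(int(rng.integers(1, 8))):
            pos += int(rng.integers(1, 2000))
            end = pos + int(rng.integers(1, 1500))
            ivs.append(("chrA", pos, end))
            pos = end
        ps = peakset(ivs)
        expect = sum(
            1 for m in mids if any(s <= m < e for _, s, e in ivs)
        )
        n, frac = reads_in_peaks(pairs, ps)
        assert n == expect and frac == expect / len(mids)


# ---------------------------------------------------------------------------
# set overlap / union


def test_overlap_identical_and_disjoint():
    a = peakset([("chrA", 0, 100), ("chrA", 200, 300)])
    assert overlap_peaksets(a, a) == (2, 1.0)
    b = peakset([("chrB", 0, 100)])
    assert overlap_peaksets(a, b) == (0, 0.0)


def test_overlap_matches_bruteforce(rng):
    def random_set(label):
        ivs = []
        for chrom in ("chrA", "chrB"):
            pos = 0
            for _ in range(int(rng.integers(0, 10))):
                pos += int(rng.integers(1, 300))
                end = pos + int(rng.integers(1, 400))
                ivs.append(GenomicInterval(chrom, pos, end))
                pos = end
        return PeakSet(label, ivs)

    for _ in range(100):
        a, b = random_set("a"), random_set("b")
        expect = sum(
            1
            for x in a.intervals
            if any(
                x.chrom == y.chrom and x.start < y.end and y.start < x.end
                for y in b.intervals
            )
        )
        n, frac = overlap_peaksets(a, b)
        assert n == expect
        if len(a):
            assert frac == expect / len(a)


def test_union_examples():
    a = peakset([("chrA", 0, 100)])
    b = peakset([("chrA", 50, 150)])
    assert [(iv.start, iv.end) for iv in union_peaks(a, b)] == [(0, 150)]
    # bookended intervals merge
    c = peakset([("chrA", 150, 200)])
    assert [(iv.start, iv.end) for iv in union_peaks(union_peaks(a, b), c)] == [(0, 200)]
    disjoint = peakset([("chrB", 0, 10)])
    u = union_peaks(a, disjoint)
    assert [(iv.chrom, iv.start, iv.end) for iv in u] == [
        ("chrA", 0, 100), ("chrB", 0, 10)
    ]
    empty = PeakSet("e", [])
    assert union_peaks(a, empty).intervals == a.intervals


# ---------------------------------------------------------------------------
# proximity


def test_proximity_inside_and_threshold():
    points = peakset([("chrA", 1000, 2000)])
    # target inside -> distance 0
    assert proximity_count(points, pairs_at([1500]), 0) == 1
    # nearest target at edge distance 201 with max_dist 200 -> not counted
    assert proximity_count(points, pairs_at([2200]), 200) == 0
    assert proximity_count(points, pairs_at([2200]), 201) == 1
    assert proximity_count(points, pairs_at([799]), 200) == 0
    assert proximity_count(points, pairs_at([800]), 200) == 1


def test_proximity_matches_bruteforce(rng):
    for _ in range(100):
        mids = sorted(int(x) for x in rng.integers(0, 5000, size=int(rng.integers(1, 30))))
        ivs = []
        pos = 0
        for _ in range(int(rng.integers(1, 8))):
            pos += int(rng.integers(1, 600))
            end = pos + int(rng.integers(1, 400))
            ivs.append(("chrA", pos, end))
            pos = end
        max_dist = int(rng.integers(0, 300))
        expect = 0
        for _, s, e in ivs:
            best = min(
                0 if s <= m < e else (s - m if m < s else m - e + 1) for m in mids
            )
            expect += best <= max_dist
        assert proximity_count(peakset(ivs), pairs_at(mids), max_dist) == expect


# ---------------------------------------------------------------------------
# boundary alignment


def test_boundary_alignment_identity():
    a = peakset([("chrA", 0, 100), ("chrA", 100, 250), ("chrB", 10, 50)])
    n_aligned, n_total, n_tiled = boundary_alignment(a, a, tolerance=0)
    assert (n_aligned, n_total, n_tiled) == (6, 6, 3)


def test_boundary_alignment_offset_beyond_tolerance():
    a = peakset([("chrA", 10_000, 20_000)])
    b = peakset([("chrA", 10_501, 20_501)])
    assert boundary_alignment(a, b, tolerance=500)[0] == 0
    assert boundary_alignment(a, b, tolerance=501)[0] == 2


def test_peak_tiled_by_consecutive_intervals():
    tads = peakset([
        ("chrA", 0, 100), ("chrA", 100, 250), ("chrA", 250, 400),
        ("chrA", 500, 600),
    ])
    spanning = peakset([("chrA", 0, 400)])  # exactly 3 consecutive TADs
    assert boundary_alignment(spanning, tads, tolerance=0) == (2, 2, 1)
    broken = peakset([("chrA", 0, 600)])  # gap 400-500 breaks the chain
    assert boundary_alignment(broken, tads, tolerance=0)[2] == 0
    assert boundary_alignment(broken, tads, tolerance=100)[2] == 1


def boundary_oracle(a, b, tol):
    bounds_b = {}
    for iv in b.intervals:
        bounds_b.setdefault(iv.chrom, []).extend([iv.start, iv.end])
    n_aligned = 0
    n_tiled = 0
    for iv in a.intervals:
        near = bounds_b.get(iv.chrom, [])
        s_ok = any(abs(x - iv.start) <= tol for x in near)
        e_ok = any(abs(x - iv.end) <= tol for x in near)
        n_aligned += s_ok + e_ok
        if not (s_ok and e_ok):
            continue
        ivs_b = sorted(
            [x for x in b.intervals if x.chrom == iv.chrom],
            key=lambda x: x.start,
        )
        tiled = False
        for i in range(len(ivs_b)):
            if abs(ivs_b[i].start - iv.start) > tol:
                continue
            for j in range(i, len(ivs_b)):
                chain_ok = all(
                    abs(ivs_b[k + 1].start - ivs_b[k].end) <= tol
                    for k in range(i, j)
                )
                if chain_ok and abs(ivs_b[j].end - iv.end) <= tol:
                    tiled = True
        n_tiled += tiled
    return n_aligned, 2 * len(a), n_tiled


def test_boundary_alignment_matches_bruteforce(rng):
    for _ in range(100):
        def rand_set(label):
            ivs = []
            pos = 0
            for _ in range(int(rng.integers(1, 10))):
                pos += int(rng.integers(1, 60))
                end = pos + int(rng.integers(10, 200))
                ivs.append(GenomicInterval("chrA", pos, end))
                pos = end
            return PeakSet(label, ivs)

        a, b = rand_set("a"), rand_set("b")
        tol = int(rng.integers(0, 40))
        assert boundary_alignment(a, b, tol) == boundary_oracle(a, b, tol)
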