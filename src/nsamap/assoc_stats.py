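"""Contingency statistics, genome-binned density profiles and permutation nulls.

The permutation null re-places each interval uniformly at random on its own
chromosome, preserving its length and rejecting overlaps with already-placed
intervals; empirical p-values use the add-one (Phipson-Smyth) estimator, so
with 1,000 permutations the smallest attainable p is 1/1001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .io_formats import ChromSizes, GenomicInterval, PeakSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = condition 1 yes/no, columns = condition 2 yes/no.

    ``a`` = both, ``b`` = condition 1 only, ``c`` = condition 2 only,
    ``d`` = neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total < 1:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def odds_ratio(table: ContingencyTable, haldane: bool = False) -> float:
    """Sample cross-product odds ratio (a*d)/(b*c).

    With ``haldane=True`` the Haldane-Anscombe correction adds 0.5 to each
    cell; otherwise a zero ``b*c`` returns +inf with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        if a * d == 0:
            log.warning("odds ratio undefined (zero cross products); returning nan")
            return float("nan")
        log.warning("odds ratio infinite (b*c == 0)")
        return float("inf")
    return (a * d) / (b * c)


def chi_square_test(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test with 1 df; no continuity correction by default."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square test undefined for a zero margin")
    res = sps.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact (hypergeometric) p-value."""
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# density profiles


@dataclass
class DensityProfile:
    """Counts of points per fixed-width bin tiling the genome.

    ``counts`` maps chromosome -> per-bin counts, in ``sizes`` order; the
    last bin of each chromosome may be short.
    """

    bin: int
    counts: dict[str, np.ndarray]

    @property
    def values(self) -> np.ndarray:
        return np.concatenate(list(self.counts.values())) if self.counts else np.array([])

    @property
    def n_points(self) -> int:
        return int(self.values.sum())

    def same_binning(self, other: "DensityProfile") -> bool:
        if self.bin != other.bin or list(self.counts) != list(other.counts):
            return False
        return all(
            self.counts[c].shape == other.counts[c].shape for c in self.counts
        )


def density_profile(
    points: Iterable[tuple[str, int]], sizes: ChromSizes, bin: int
) -> DensityProfile:
    """Bin point midpoints into a genome-tiling density profile.

    ``points`` is an iterable of (chromosome, position) tuples; every point
    must lie on a chromosome in ``sizes``.
    """
    if bin < 1:
        raise ValueError("bin width must be >= 1")
    counts = {
        chrom: np.zeros(-(-length // bin), dtype=np.int64)
        for chrom, length in sizes.items()
    }
    for chrom, pos in points:
        counts[chrom][pos // bin] += 1
    return DensityProfile(bin=bin, counts=counts)


def profile_correlation(
    p1: DensityProfile, p2: DensityProfile, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation across all bins of two identically binned profiles."""
    if not p1.same_binning(p2):
        raise ValueError("profiles have mismatched binning")
    x, y = p1.values, p2.values
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# permutation machinery


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    tail: str
    seed: Optional[int] = None
    n_perm: int = 0


def _intervals_overlap(start: int, end: int, placed: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in placed)


def shuffle_intervals(
    peaks: PeakSet,
    sizes: ChromSizes,
    rng: np.random.Generator,
    max_attempts: int = 1000,
    mask: Optional[PeakSet] = None,
) -> PeakSet:
    """Re-place every interval uniformly at random on its own chromosome.

    Lengths are preserved; placements overlapping an already-placed interval
    (or the optional excluded-region ``mask``) are re-drawn, up to
    ``max_attempts`` times each.  Within a chromosome, longer intervals are
    placed first to keep rejection sampling efficient.
    """
    masked = mask.by_chrom() if mask is not None else {}
    placed_all: list[GenomicInterval] = []
    for chrom in sizes:
        ivs = [iv for iv in peaks.intervals if iv.chrom == chrom]
        ivs.sort(key=lambda iv: -iv.length)
        placed: list[tuple[int, int]] = [
            (m.start, m.end) for m in masked.get(chrom, [])
        ]
        length_of_chrom = sizes[chrom]
        for iv in ivs:
            if iv.length > length_of_chrom:
                raise ValueError(
                    f"interval of length {iv.length} exceeds {chrom} "
                    f"({length_of_chrom} bp)"
                )
            for _ in range(max_attempts):
                start = int(rng.integers(0, length_of_chrom - iv.length + 1))
                end = start + iv.length
                if not _intervals_overlap(start, end, placed):
                    placed.append((start, end))
                    placed_all.append(
                        GenomicInterval(chrom, start, end, name=iv.name)
                    )
                    break
            else:
                raise RuntimeError(
                    f"could not place interval of length {iv.length} on "
                    f"{chrom} after {max_attempts} attempts"
                )
    return PeakSet(f"{peaks.label}_shuffled", placed_all)


def permutation_test(
    observed_stat_fn: Callable[[PeakSet, object], float],
    peaks_to_shuffle: PeakSet,
    fixed_operand,
    sizes: ChromSizes,
    n_perm: int = 1000,
    tail: str = "greater",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """Empirical permutation test with chromosome-preserving interval shuffling.

    ``observed_stat_fn(peaks, fixed_operand)`` is any deterministic statistic;
    the null is built by re-evaluating it on shuffled copies of
    ``peaks_to_shuffle``.  The add-one estimator
    ``p = (1 + #{null >= observed}) / (1 + n_perm)`` (mirrored for
    ``tail='less'``) is valid and never returns 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = float(observed_stat_fn(peaks_to_shuffle, fixed_operand))
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = shuffle_intervals(peaks_to_shuffle, sizes, rng)
        null[i] = observed_stat_fn(shuffled, fixed_operand)
    if tail == "greater":
        extreme = int(np.sum(null >= observed))
    else:
        extreme = int(np.sum(null <= observed))
    p = (1 + extreme) / (1 + n_perm)
    return PermutationResult(
        observed=observed, null=null, p=p, tail=tail, seed=seed, n_perm=n_perm
    )


# ---------------------------------------------------------------------------
# genomic-window association


def window_association(
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    sizes: ChromSizes,
    window: int = 1000,
) -> ContingencyTable:
    """Classify genome-tiling windows by >=1 bp overlap with each peak set.

    Returns the 2x2 window-count table (a = overlap both, b = A only,
    c = B only, d = neither), suitable for :func:`fisher_exact` /
    :func:`odds_ratio`.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    a = b = c = d = 0
    by_a, by_b = peaks_a.by_chrom(), peaks_b.by_chrom()
    for chrom, length in sizes.items():
        n_win = -(-length // window)
        hit_a = np.zeros(n_win, dtype=bool)
        hit_b = np.zeros(n_win, dtype=bool)
        for hits, ivs in ((hit_a, by_a.get(chrom, ())), (hit_b, by_b.get(chrom, ()))):
            for iv in ivs:
                hits[iv.start // window : (iv.end - 1) // window + 1] = True
        a += int(np.sum(hit_a & hit_b))
        b += int(np.sum(hit_a & ~hit_b))
        c += int(np.sum(~hit_a & hit_b))
        d += int(np.sum(~hit_a & ~hit_b))
    return ContingencyTable(a, b, c, d)
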