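"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study conditions of the real assay on a toy
genome (four autosome stand-ins of 30-60 Mb plus a 45-kb rDNA repeating
unit), under two scenarios that mirror the stable- vs sporadic-interaction
models:

* ``"speckled"`` - non-nascent nsaRNA / pre-mRNA DNA ends fall inside
  planted enriched domains with probability ``in_peak_prob`` (default 0.72,
  the in-peak read share the real data exhibit), otherwise uniformly in the
  unplanted background;
* ``"diffuse"`` - no planted domains; DNA ends are uniform.

Planted domain lengths are log-uniform over [100 kb, 13 Mb], the reported
size range of speckle-proximal domains.  Pre-mRNA pairs are
interchromosomal with probability 0.93; rRNA pairs ligate to the rDNA unit
with high probability against a small background rate, planting a large
rRNA-rDNA odds ratio.  A configurable fraction of nsaRNA / pre-mRNA pairs
is drawn as nascent contamination (DNA end within the nascent distance of
the RNA end).  Background draws are rejected out of planted domains and out
of the nascent window, so truth labels are exact by construction; boundary
probe pairs (gaps of 1999/2000/2001 nt, intron overlaps of 9/10/11 nt) are
emitted by default to exercise the filter thresholds end-to-end.

Image stacks hold an ellipsoidal nucleus, 20-35 Gaussian SC35 clusters and
1-3 FISH spots per cell, each spot planted overlapping a cluster with the
group's colocalization probability or else well separated from all
clusters.

Everything is deterministic under the master seed, byte-for-byte across
runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import FilterParams
from .imaging import ImageStack
from .io_formats import (
    ChromSizes,
    DEFAULT_NSA_SPECIES,
    Gene,
    GeneAnnotation,
    GenomicInterval,
    PairRecord,
    PeakSet,
    Transcript,
)

log = logging.getLogger(__name__)

#: approximate mature lengths (nt) of the nsaRNA species
NSA_SPECIES_LENGTHS = {
    "U1": 164, "U2": 188, "U4": 145, "U4atac": 131, "U5": 116,
    "U6": 107, "U6atac": 125, "U11": 136, "U12": 150,
    "7SK": 331, "Malat1": 8700,
}

DEFAULT_CHROMS = (
    ("chr1", 60_000_000),
    ("chr2", 50_000_000),
    ("chr3", 40_000_000),
    ("chr4", 30_000_000),
)


@dataclass(frozen=True)
class ImagingParams:
    """Synthetic single-cell imaging conditions.

    Defaults emulate the single-cell experiment: 82 cells probed inside an
    enriched domain with colocalization probability 0.84 and 100 control
    cells at 0.57, 1-3 FISH spots and 20-35 SC35 clusters per nucleus.
    """

    n_images_probe: int = 82
    n_images_control: int = 100
    coloc_prob_probe: float = 0.84
    coloc_prob_control: float = 0.57
    spots_per_cell: tuple[int, int] = (1, 3)
    clusters_per_cell: tuple[int, int] = (20, 35)
    shape: tuple[int, int, int] = (14, 56, 56)
    cluster_sigma: float = 1.2
    spot_sigma: float = 1.0
    cluster_amplitude: float = 3.0
    spot_amplitude: float = 5.0
    noise_mean: float = 0.1
    noise_sd: float = 0.03
    min_center_separation: float = 4.0
    isolation_distance: float = 5.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset (see module docstring)."""

    chroms: tuple[tuple[str, int], ...] = DEFAULT_CHROMS
    rdna_chrom: str = "rDNA"
    rdna_length: int = 45_000
    scenario: str = "speckled"
    n_planted_peaks: int = 10
    peak_length_range: tuple[int, int] = (100_000, 13_000_000)
    n_nsarna: int = 15_000
    n_rrna: int = 2_000
    n_premrna: int = 5_000
    n_other: int = 3_000
    in_peak_prob: float = 0.72
    nascent_fraction: float = 0.10
    interchromosomal_prob: float = 0.93
    rrna_rdna_prob: float = 0.80
    rdna_background_prob: float = 0.001
    n_coding_genes: int = 30
    read_len: int = 50
    include_boundary_probes: bool = True
    filter_params: FilterParams = FilterParams()
    imaging: ImagingParams = ImagingParams()
    seed: int = 0

    def __post_init__(self):
        for p in (
            self.in_peak_prob, self.nascent_fraction, self.interchromosomal_prob,
            self.rrna_rdna_prob, self.rdna_background_prob,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.scenario not in ("speckled", "diffuse"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if min(self.n_nsarna, self.n_rrna, self.n_premrna, self.n_other) < 0:
            raise ValueError("pair counts must be >= 0")


@dataclass
class TruthSet:
    """Planted ground truth, record-for-record consistent with the files."""

    peaks: PeakSet
    labels: pd.DataFrame  # read_id, rna_class, species, nascent, in_peak


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sizes: ChromSizes
    annotation: GeneAnnotation
    pairs: list[PairRecord]
    truth: TruthSet


# ---------------------------------------------------------------------------
# annotation

_EDGE_MARGIN = 200_000


def _place(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    chrom: str,
    chrom_len: int,
    span: int,
    margin: int = _EDGE_MARGIN,
    max_attempts: int = 1000,
) -> int:
    """Uniformly place a span on a chromosome avoiding occupied intervals."""
    lo, hi = margin, chrom_len - margin - span
    if hi < lo:
        raise ValueError(f"span {span} does not fit on {chrom} ({chrom_len} bp)")
    taken = occupied.setdefault(chrom, [])
    for _ in range(max_attempts):
        start = int(rng.integers(lo, hi + 1))
        if not any(s < start + span and start < e for s, e in taken):
            taken.append((start, start + span))
            return start
    raise RuntimeError(f"could not place span of {span} bp on {chrom}")


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GeneAnnotation, ChromSizes]:
    """Toy genome annotation: one gene per nsaRNA species, an rRNA gene on
    the rDNA pseudo-chromosome, and multi-exon coding genes."""
    sizes = ChromSizes(
        list(config.chroms) + [(config.rdna_chrom, config.rdna_length)]
    )
    main_chroms = [c for c, _ in config.chroms]
    occupied: dict[str, list[tuple[int, int]]] = {}
    genes: list[Gene] = []

    params = config.filter_params
    for i, species in enumerate(params.nsa_species):
        length = NSA_SPECIES_LENGTHS.get(species, 200)
        chrom = main_chroms[i % len(main_chroms)]
        start = _place(rng, occupied, chrom, sizes[chrom], length)
        strand = "+" if rng.random() < 0.5 else "-"
        exon = GenomicInterval(chrom, start, start + length, strand=strand)
        tx = Transcript(f"{species}_tx", chrom, strand, (exon,))
        genes.append(Gene(f"gene_{species}", "nsaRNA", species, (tx,)))

    # 45S-like precursor unit on the rDNA pseudo-chromosome
    rrna_exon = GenomicInterval(config.rdna_chrom, 500, 13_500, strand="+")
    genes.append(
        Gene(
            "gene_rRNA_45S", "rRNA", None,
            (Transcript("rRNA_45S_tx", config.rdna_chrom, "+", (rrna_exon,)),),
        )
    )

    min_intron = max(2 * params.min_intron_overlap, config.read_len + 10)
    for i in range(config.n_coding_genes):
        chrom = main_chroms[i % len(main_chroms)]
        n_exons = int(rng.integers(3, 7))
        exon_lens = rng.integers(150, 301, size=n_exons)
        intron_lens = rng.integers(max(1500, min_intron), 4001, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        start = _place(rng, occupied, chrom, sizes[chrom], span)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append(
                GenomicInterval(chrom, pos, pos + int(exon_lens[j]), strand=strand)
            )
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        tx = Transcript(f"coding{i:03d}_tx", chrom, strand, tuple(exons))
        genes.append(Gene(f"gene_coding{i:03d}", "coding", None, (tx,)))

    return GeneAnnotation(genes), sizes


# ---------------------------------------------------------------------------
# pairs


def _edge_gap(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    # independent re-derivation of the nearest-edge gap used for truth labels
    if a.chrom != b.chrom:
        return None
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def _plant_peaks(
    config: SimulationConfig, sizes: ChromSizes, rng: np.random.Generator
) -> PeakSet:
    if config.scenario == "diffuse" or config.n_planted_peaks == 0:
        return PeakSet("planted_peaks", [])
    lo, hi = config.peak_length_range
    lengths = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=config.n_planted_peaks)
    ).astype(np.int64)
    occupied: dict[str, list[tuple[int, int]]] = {}
    chrom_names = [c for c, _ in config.chroms]
    chrom_lens = np.array([l for _, l in config.chroms], dtype=float)
    intervals = []
    for k, length in enumerate(sorted(lengths, reverse=True)):
        length = int(length)
        for _ in range(1000):
            capacity = np.maximum(chrom_lens - 2 * _EDGE_MARGIN - length, 0.0)
            if capacity.sum() == 0:
                raise RuntimeError("planted peaks do not fit on the genome")
            chrom = chrom_names[
                int(rng.choice(len(chrom_names), p=capacity / capacity.sum()))
            ]
            try:
                start = _place(rng, occupied, chrom, sizes[chrom], length,
                               max_attempts=50)
            except RuntimeError:
                continue
            intervals.append(
                GenomicInterval(chrom, start, start + length, name=f"planted{k}")
            )
            break
        else:
            raise RuntimeError("could not place planted peaks")
    return PeakSet("planted_peaks", intervals)


class _PairSampler:
    """Stateful sampler sharing the annotation, planted peaks and rng."""

    def __init__(self, config, annotation, sizes, peaks, rng):
        self.cfg = config
        self.ann = annotation
        self.sizes = sizes
        self.peaks = peaks
        self.rng = rng
        self.params = config.filter_params
        self.main = [c for c, _ in config.chroms]
        self.main_lens = np.array([l for _, l in config.chroms], dtype=float)
        self.nsa_genes = {g.species: g for g in annotation.by_class("nsaRNA")}
        self.rrna_gene = annotation.by_class("rRNA")[0]
        self.coding = annotation.by_class("coding")
        self.peaks_by_chrom = peaks.by_chrom()
        # all gene spans, for intergenic rejection
        self.gene_spans: dict[str, list[tuple[int, int]]] = {}
        for g in annotation:
            for tx in g.transcripts:
                span = tx.span
                self.gene_spans.setdefault(span.chrom, []).append(
                    (span.start, span.end)
                )

    # ---- RNA ends ----------------------------------------------------

    def _inside(self, exon: GenomicInterval, strand: str) -> GenomicInterval:
        n = min(self.cfg.read_len, exon.length)
        start = int(self.rng.integers(exon.start, exon.end - n + 1))
        return GenomicInterval(exon.chrom, start, start + n, strand=strand)

    def rna_nsarna(self) -> tuple[GenomicInterval, str]:
        species = str(self.rng.choice(list(self.nsa_genes)))
        gene = self.nsa_genes[species]
        tx = gene.transcripts[0]
        return self._inside(tx.exons[0], tx.strand), species

    def rna_rrna(self) -> GenomicInterval:
        tx = self.rrna_gene.transcripts[0]
        return self._inside(tx.exons[0], tx.strand)

    def rna_premrna(self, intron_overlap: Optional[int] = None) -> GenomicInterval:
        """RNA end straddling an exon-intron junction of a coding transcript."""
        for _ in range(100):
            gene = self.coding[int(self.rng.integers(len(self.coding)))]
            tx = gene.transcripts[0]
            introns = tx.introns
            if not introns:
                continue
            i = int(self.rng.integers(len(introns)))
            intron = introns[i]
            max_o = min(intron.length, self.cfg.read_len - 1)
            if intron_overlap is None:
                if max_o < self.params.min_intron_overlap:
                    continue
                o = int(self.rng.integers(self.params.min_intron_overlap, max_o + 1))
            else:
                o = intron_overlap
                if o > max_o:
                    continue
            donor_side = self.rng.random() < 0.5
            exon = tx.exons[i] if donor_side else tx.exons[i + 1]
            e_part = min(self.cfg.read_len - o, exon.length)
            if e_part < 1:
                continue
            if donor_side:
                start, end = intron.start - e_part, intron.start + o
            else:
                start, end = intron.end - o, intron.end + e_part
            return GenomicInterval(tx.chrom, start, end, strand=tx.strand)
        raise RuntimeError("could not construct a junction-straddling RNA end")

    def rna_exonic(self) -> GenomicInterval:
        for _ in range(100):
            gene = self.coding[int(self.rng.integers(len(self.coding)))]
            tx = gene.transcripts[0]
            exons = [e for e in tx.exons if e.length >= 20]
            if not exons:
                continue
            exon = exons[int(self.rng.integers(len(exons)))]
            n = min(self.cfg.read_len, exon.length)
            return self._inside(exon, tx.strand)
        raise RuntimeError("no exon large enough for an exonic read")

    def rna_intergenic(self) -> GenomicInterval:
        n = self.cfg.read_len
        for _ in range(1000):
            ci = int(self.rng.choice(len(self.main), p=self.main_lens / self.main_lens.sum()))
            chrom = self.main[ci]
            start = int(self.rng.integers(0, self.sizes[chrom] - n + 1))
            spans = self.gene_spans.get(chrom, [])
            if not any(s < start + n and start < e for s, e in spans):
                strand = "+" if self.rng.random() < 0.5 else "-"
                return GenomicInterval(chrom, start, start + n, strand=strand)
        raise RuntimeError("could not draw an intergenic RNA end")

    # ---- DNA ends ----------------------------------------------------

    def _in_any_peak(self, chrom: str, midpoint: int) -> bool:
        return any(
            iv.start <= midpoint < iv.end
            for iv in self.peaks_by_chrom.get(chrom, ())
        )

    def dna_nascent(self, rna: GenomicInterval) -> GenomicInterval:
        gap = int(self.rng.integers(0, self.params.nascent_distance + 1))
        n = self.cfg.read_len
        chrom_len = self.sizes[rna.chrom]
        if rna.end + gap + n <= chrom_len:
            start = rna.end + gap
        else:
            start = rna.start - gap - n
        return GenomicInterval(rna.chrom, start, start + n)

    def dna_uniform(
        self,
        rna: GenomicInterval,
        chrom_scope: Sequence[str],
        avoid_peaks: bool,
        avoid_nascent: bool,
    ) -> GenomicInterval:
        n = self.cfg.read_len
        lens = np.array([float(self.sizes[c]) for c in chrom_scope])
        for _ in range(1000):
            chrom = chrom_scope[int(self.rng.choice(len(chrom_scope), p=lens / lens.sum()))]
            start = int(self.rng.integers(0, self.sizes[chrom] - n + 1))
            dna = GenomicInterval(chrom, start, start + n)
            if avoid_peaks and self._in_any_peak(chrom, dna.midpoint):
                continue
            if avoid_nascent:
                gap = _edge_gap(rna, dna)
                if gap is not None and gap <= self.params.nascent_distance:
                    continue
            return dna
        raise RuntimeError("could not draw a background DNA end")

    def dna_in_peak(
        self, rna: GenomicInterval, chrom_scope: Sequence[str]
    ) -> Optional[GenomicInterval]:
        candidates = [
            iv for c in chrom_scope for iv in self.peaks_by_chrom.get(c, ())
        ]
        if not candidates:
            return None
        n = self.cfg.read_len
        weights = np.array([float(iv.length) for iv in candidates])
        for _ in range(1000):
            iv = candidates[
                int(self.rng.choice(len(candidates), p=weights / weights.sum()))
            ]
            start = int(self.rng.integers(iv.start, iv.end - n + 1))
            dna = GenomicInterval(iv.chrom, start, start + n)
            gap = _edge_gap(rna, dna)
            if gap is not None and gap <= self.params.nascent_distance:
                continue
            return dna
        raise RuntimeError("could not draw an in-peak DNA end")

    def dna_end(self, rna: GenomicInterval, rna_class: str) -> GenomicInterval:
        cfg, rng = self.cfg, self.rng
        if rna_class == "rRNA":
            if rng.random() < cfg.rrna_rdna_prob:
                n = cfg.read_len
                start = int(rng.integers(0, cfg.rdna_length - n + 1))
                return GenomicInterval(cfg.rdna_chrom, start, start + n)
            return self.dna_uniform(rna, self.main, avoid_peaks=False,
                                    avoid_nascent=False)
        if rng.random() < cfg.rdna_background_prob:
            n = cfg.read_len
            start = int(rng.integers(0, cfg.rdna_length - n + 1))
            return GenomicInterval(cfg.rdna_chrom, start, start + n)
        if rna_class in ("nsaRNA", "p_pre_mRNA"):
            if rng.random() < cfg.nascent_fraction:
                return self.dna_nascent(rna)
            if rna_class == "p_pre_mRNA":
                if rng.random() < cfg.interchromosomal_prob:
                    scope = [c for c in self.main if c != rna.chrom]
                else:
                    scope = [rna.chrom]
            else:
                scope = self.main
            speckled = cfg.scenario == "speckled"
            if speckled and rng.random() < cfg.in_peak_prob:
                dna = self.dna_in_peak(rna, scope)
                if dna is not None:
                    return dna
            return self.dna_uniform(rna, scope, avoid_peaks=speckled,
                                    avoid_nascent=True)
        # class "other": plain uniform background
        return self.dna_uniform(rna, self.main, avoid_peaks=False,
                                avoid_nascent=False)


def simulate_pairs(
    config: SimulationConfig,
    annotation: GeneAnnotation,
    sizes: ChromSizes,
    rng: np.random.Generator,
) -> tuple[list[PairRecord], TruthSet]:
    """Emit RNA-DNA pairs and their exact truth labels (see module docstring)."""
    peaks = _plant_peaks(config, sizes, rng)
    sampler = _PairSampler(config, annotation, sizes, peaks, rng)
    params = config.filter_params

    pairs: list[PairRecord] = []
    rows: list[dict] = []

    def emit(rna: GenomicInterval, dna: GenomicInterval, rna_class: str,
             species: Optional[str], read_id: str) -> None:
        gap = _edge_gap(rna, dna)
        nascent = gap is not None and gap <= params.nascent_distance
        pairs.append(PairRecord(rna=rna, dna=dna, read_id=read_id))
        rows.append(
            dict(
                read_id=read_id,
                rna_class=rna_class,
                species=species if species is not None else ".",
                nascent=nascent,
                in_peak=sampler._in_any_peak(dna.chrom, dna.midpoint),
            )
        )

    for i in range(config.n_nsarna):
        rna, species = sampler.rna_nsarna()
        emit(rna, sampler.dna_end(rna, "nsaRNA"), "nsaRNA", species,
             f"nsa_{i:06d}")
    for i in range(config.n_rrna):
        rna = sampler.rna_rrna()
        emit(rna, sampler.dna_end(rna, "rRNA"), "rRNA", None, f"rrna_{i:06d}")
    for i in range(config.n_premrna):
        rna = sampler.rna_premrna()
        emit(rna, sampler.dna_end(rna, "p_pre_mRNA"), "p_pre_mRNA", None,
             f"pre_{i:06d}")
    n_exonic = config.n_other // 3
    for i in range(config.n_other):
        rna = sampler.rna_exonic() if i < n_exonic else sampler.rna_intergenic()
        emit(rna, sampler.dna_end(rna, "other"), "other", None, f"oth_{i:06d}")

    if config.include_boundary_probes:
        d = params.nascent_distance
        n = config.read_len
        for j, gap in enumerate((d - 1, d, d + 1)):
            while True:
                rna = sampler.rna_intergenic()
                if rna.end + gap + n <= sizes[rna.chrom]:
                    break
            dna = GenomicInterval(rna.chrom, rna.end + gap, rna.end + gap + n)
            emit(rna, dna, "other", None, f"probe_gap{j}")
        m = params.min_intron_overlap
        for j, o in enumerate((m - 1, m, m + 1)):
            rna = sampler.rna_premrna(intron_overlap=o)
            dna = sampler.dna_uniform(rna, [c for c in sampler.main if c != rna.chrom],
                                      avoid_peaks=True, avoid_nascent=True)
            cls = "p_pre_mRNA" if o >= m else "other"
            emit(rna, dna, cls, None, f"probe_junc{j}")

    labels = pd.DataFrame(
        rows, columns=["read_id", "rna_class", "species", "nascent", "in_peak"]
    )
    return pairs, TruthSet(peaks=peaks, labels=labels)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate annotation + pairs + truth under the config's master seed."""
    rng = np.random.default_rng(config.seed)
    annotation, sizes = simulate_annotation(config, rng)
    pairs, truth = simulate_pairs(config, annotation, sizes, rng)
    return SimulatedDataset(
        config=config, sizes=sizes, annotation=annotation, pairs=pairs, truth=truth
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, str]:
    """Write a dataset's files; returns a name -> path manifest."""
    import os

    from .io_formats import (
        write_annotation, write_bed, write_chrom_sizes, write_pairs,
    )

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "chrom_sizes": os.path.join(out_dir, "chrom.sizes"),
        "annotation": os.path.join(out_dir, "annotation.gtf"),
        "pairs": os.path.join(out_dir, "pairs.tsv"),
        "truth_peaks": os.path.join(out_dir, "truth_peaks.bed"),
        "truth_labels": os.path.join(out_dir, "truth_labels.tsv"),
    }
    write_chrom_sizes(ds.sizes, paths["chrom_sizes"])
    write_annotation(ds.annotation, paths["annotation"])
    write_pairs(ds.pairs, paths["pairs"])
    write_bed(ds.truth.peaks, paths["truth_peaks"])
    ds.truth.labels.to_csv(paths["truth_labels"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# images


def _ellipsoid_mask(shape: tuple[int, int, int], shrink: float = 0.0) -> np.ndarray:
    zz, yy, xx = np.indices(shape, dtype=float)
    center = [(s - 1) / 2 for s in shape]
    semi = [max(0.42 * s - shrink, 1.0) for s in shape]
    d = sum(((g - c) / a) ** 2 for g, c, a in zip((zz, yy, xx), center, semi))
    return d <= 1.0


def _add_blob(
    image: np.ndarray, center: np.ndarray, sigma: float, amplitude: float
) -> None:
    r = int(np.ceil(4 * sigma))
    lo = np.maximum(np.floor(center).astype(int) - r, 0)
    hi = np.minimum(np.floor(center).astype(int) + r + 1, image.shape)
    grids = np.meshgrid(
        *[np.arange(lo[i], hi[i], dtype=float) for i in range(3)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    image[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(
        -d2 / (2 * sigma**2)
    )


def _sample_point(
    rng: np.random.Generator,
    coords: np.ndarray,
    existing: np.ndarray,
    min_dist: float,
    max_attempts: int = 1000,
) -> np.ndarray:
    for _ in range(max_attempts):
        p = coords[int(rng.integers(len(coords)))].astype(float)
        p += rng.uniform(-0.5, 0.5, size=3)
        if len(existing) == 0 or np.linalg.norm(existing - p, axis=1).min() >= min_dist:
            return p
    raise RuntimeError("could not place a point with the required separation")


def simulate_image(
    params: ImagingParams, coloc_prob: float, rng: np.random.Generator
) -> tuple[ImageStack, list[bool]]:
    """One synthetic nucleus; returns the stack and per-spot planted flags."""
    shape = params.shape
    mask = _ellipsoid_mask(shape)
    inner = np.argwhere(_ellipsoid_mask(shape, shrink=2.5))
    sc35 = rng.normal(params.noise_mean, params.noise_sd, size=shape)
    fish = rng.normal(params.noise_mean, params.noise_sd, size=shape)

    n_clusters = int(rng.integers(params.clusters_per_cell[0],
                                  params.clusters_per_cell[1] + 1))
    centers = np.empty((0, 3))
    for _ in range(n_clusters):
        p = _sample_point(rng, inner, centers, params.min_center_separation)
        centers = np.vstack([centers, p])
        _add_blob(sc35, p, params.cluster_sigma, params.cluster_amplitude)

    n_spots = int(rng.integers(params.spots_per_cell[0],
                               params.spots_per_cell[1] + 1))
    planted: list[bool] = []
    spot_centers = np.empty((0, 3))
    for _ in range(n_spots):
        coloc = bool(rng.random() < coloc_prob)
        if coloc:
            for _ in range(1000):
                base = centers[int(rng.integers(len(centers)))]
                p = base + rng.normal(0, 0.5, size=3)
                if (
                    len(spot_centers) == 0
                    or np.linalg.norm(spot_centers - p, axis=1).min()
                    >= params.min_center_separation
                ):
                    break
            else:
                raise RuntimeError("could not place a colocalized spot")
        else:
            exclusion = np.vstack([centers, spot_centers])
            p = _sample_point(rng, inner, exclusion, params.isolation_distance)
        spot_centers = np.vstack([spot_centers, p])
        planted.append(coloc)
        _add_blob(fish, p, params.spot_sigma, params.spot_amplitude)

    stack = ImageStack(fish=fish, sc35=sc35, mask=mask)
    return stack, planted


def simulate_image_group(
    params: ImagingParams,
    n_images: int,
    coloc_prob: float,
    rng: np.random.Generator,
    group: str = "probe",
) -> tuple[list[ImageStack], pd.DataFrame]:
    stacks: list[ImageStack] = []
    rows: list[dict] = []
    for i in range(n_images):
        stack, planted = simulate_image(params, coloc_prob, rng)
        stacks.append(stack)
        for j, flag in enumerate(planted):
            rows.append(dict(group=group, image=i, spot=j, planted_coloc=flag))
    return stacks, pd.DataFrame(rows, columns=["group", "image", "spot", "planted_coloc"])


def simulate_images(
    params: ImagingParams, rng: np.random.Generator
) -> tuple[list[ImageStack], list[ImageStack], pd.DataFrame]:
    """Both probe groups; returns (probe_stacks, control_stacks, truth)."""
    probe, t1 = simulate_image_group(
        params, params.n_images_probe, params.coloc_prob_probe, rng, "probe"
    )
    control, t2 = simulate_image_group(
        params, params.n_images_control, params.coloc_prob_control, rng, "control"
    )
    return probe, control, pd.concat([t1, t2], ignore_index=True)


# ---------------------------------------------------------------------------
# evaluation


def _jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    inter = a.overlap_length(b)
    if inter == 0:
        return 0.0
    return inter / (a.length + b.length - inter)


def evaluate_peaks(
    called: PeakSet, truth: PeakSet, min_jaccard: float = 0.5
) -> tuple[float, float]:
    """Planted-peak recovery: (recall, precision) at a Jaccard threshold.

    A planted peak counts recovered when some called peak reaches Jaccard
    >= ``min_jaccard`` with it; precision is the symmetric statement.  With
    no truth peaks recall is vacuously 1.0; with no calls precision is
    vacuously 1.0.
    """
    def covered(query: PeakSet, reference: PeakSet) -> float:
        if len(query) == 0:
            return 1.0
        n = sum(
            1
            for q in query.intervals
            if any(_jaccard(q, r) >= min_jaccard for r in reference.intervals)
        )
        return n / len(query)

    return covered(truth, called), covered(called, truth)
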