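"""Readers and writers for every file the pipeline touches.

All genomic coordinates are 0-based, half-open ([start, end)) both in memory
and in the BED / pair-file dialects; GTF input is converted from its native
1-based inclusive convention on read.  Ribosomal DNA is modelled as an extra
"chromosome" holding the repeating unit, so a single coordinate frame
(a :class:`ChromSizes`) covers the whole analysis.

Parsers are strict: individually malformed records are dropped and counted,
but more than :data:`MALFORMED_TOLERANCE` (1%) malformed records raises a
:class:`FormatError`, which distinguishes stray bad lines from a
wrong-dialect file.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

log = logging.getLogger(__name__)

#: maximum tolerated fraction of malformed records before a hard error
MALFORMED_TOLERANCE = 0.01

VALID_STRANDS = ("+", "-", ".")

#: RNA classes recognised by the annotation dialect
RNA_CLASSES = ("nsaRNA", "rRNA", "coding", "other")

#: nuclear speckle-associated RNA species (spliceosomal snRNAs, 7SK, Malat1)
DEFAULT_NSA_SPECIES = (
    "U1", "U2", "U4", "U4atac", "U5", "U6", "U6atac", "U11", "U12",
    "7SK", "Malat1",
)


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


class ChromSizes:
    """Ordered map of chromosome name -> length in bp.

    Iteration order is file order and is preserved in all outputs.
    """

    def __init__(self, sizes: Union[Mapping[str, int], Iterable[tuple[str, int]]]):
        items = sizes.items() if hasattr(sizes, "items") else sizes
        self._sizes: dict[str, int] = {}
        for name, length in items:
            name = str(name)
            if name in self._sizes:
                raise FormatError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length < 1:
                raise FormatError(f"non-positive length for {name!r}: {length}")
            self._sizes[name] = length

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChromSizes):
            return NotImplemented
        return list(self.items()) == list(other.items())

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"

    def items(self):
        return self._sizes.items()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._sizes)

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def drop(self, *names: str) -> "ChromSizes":
        """New ChromSizes without the named chromosomes, order preserved."""
        return ChromSizes([(n, l) for n, l in self.items() if n not in names])


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional name/strand."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap(self, other: "GenomicInterval") -> Optional[int]:
        """Nearest-edge gap in bp; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end

    def fits(self, sizes: ChromSizes) -> bool:
        return self.chrom in sizes and self.end <= sizes[self.chrom]


@dataclass(frozen=True)
class PairRecord:
    """One RNA-end/DNA-end interval pair from a chimeric ligation read."""

    rna: GenomicInterval
    dna: GenomicInterval
    read_id: str


class PeakSet:
    """Named set of sorted, non-overlapping genomic intervals.

    Optionally carries a per-peak read count (parallel to ``intervals``).
    Bookended intervals (sharing a boundary) are allowed; overlaps are not.
    """

    def __init__(
        self,
        label: str,
        intervals: Iterable[GenomicInterval],
        read_counts: Optional[Iterable[int]] = None,
    ):
        ivs = list(intervals)
        counts = None if read_counts is None else [int(c) for c in read_counts]
        if counts is not None and len(counts) != len(ivs):
            raise ValueError("read_counts length mismatch")
        order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
        ivs = [ivs[i] for i in order]
        if counts is not None:
            counts = [counts[i] for i in order]
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"overlapping intervals in PeakSet {label!r}: "
                    f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
                )
        self.label = label
        self.intervals: tuple[GenomicInterval, ...] = tuple(ivs)
        self.read_counts: Optional[tuple[int, ...]] = (
            None if counts is None else tuple(counts)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return (
            self.label == other.label
            and self.intervals == other.intervals
            and self.read_counts == other.read_counts
        )

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)


# ---------------------------------------------------------------------------
# gene annotation


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]  # sorted, non-overlapping

    def __post_init__(self):
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return tuple(out)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end,
            strand=self.strand,
        )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    rna_class: str
    species: Optional[str]
    transcripts: tuple[Transcript, ...]


class GeneAnnotation:
    """Genes with transcript exon structure and an RNA-class label each."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise FormatError(f"duplicate gene_id {g.gene_id!r}")
            self.genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def by_class(self, rna_class: str) -> list[Gene]:
        return [g for g in self if g.rna_class == rna_class]


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> ChromSizes:
    """Read a UCSC-style two-column chrom.sizes file (name, length)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from None
            if length < 1:
                raise FormatError(f"{path}:{lineno}: non-positive length {length}")
            rows.append((name, length))
    if not rows:
        log.warning("empty chrom.sizes file: %s", path)
    return ChromSizes(rows)


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# pair files (11-column tab-separated dialect)
#
# rna_chrom rna_start rna_end dna_chrom dna_start dna_end read_id score
# rna_strand dna_strand annotation; '#' lines are comments.

PAIR_COLUMNS = (
    "rna_chrom", "rna_start", "rna_end", "dna_chrom", "dna_start", "dna_end",
    "read_id", "score", "rna_strand", "dna_strand", "annotation",
)


def _parse_pair_row(fields: Sequence[str], sizes: ChromSizes) -> PairRecord:
    if len(fields) < 11:
        raise ValueError("expected 11 columns")
    rna = GenomicInterval(
        fields[0], int(fields[1]), int(fields[2]), strand=fields[8]
    )
    dna = GenomicInterval(
        fields[3], int(fields[4]), int(fields[5]), strand=fields[9]
    )
    if not rna.fits(sizes) or not dna.fits(sizes):
        raise ValueError("interval outside chromosome bounds")
    return PairRecord(rna=rna, dna=dna, read_id=fields[6])


def read_pairs(path, sizes: ChromSizes) -> list[PairRecord]:
    """Read RNA-DNA read pairs, validating both ends against ``sizes``.

    Malformed rows (bad coordinates, unknown chromosome, duplicate read id)
    are dropped and counted; >1% malformed rows raises :class:`FormatError`.
    """
    records: list[PairRecord] = []
    seen_ids: set[str] = set()
    n_rows = 0
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            n_rows += 1
            fields = line.rstrip("\n").split("\t")
            try:
                rec = _parse_pair_row(fields, sizes)
                if rec.read_id in seen_ids:
                    raise ValueError(f"duplicate read_id {rec.read_id!r}")
            except (ValueError, IndexError):
                n_bad += 1
                continue
            seen_ids.add(rec.read_id)
            records.append(rec)
    if n_bad:
        log.warning("%s: dropped %d of %d malformed pair records", path, n_bad, n_rows)
    if n_rows and n_bad / n_rows > MALFORMED_TOLERANCE:
        raise FormatError(
            f"{path}: {n_bad}/{n_rows} malformed records "
            f"(> {MALFORMED_TOLERANCE:.0%}); wrong file dialect?"
        )
    return records


def write_pairs(pairs: Iterable[PairRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.rna.chrom}\t{p.rna.start}\t{p.rna.end}\t"
                f"{p.dna.chrom}\t{p.dna.start}\t{p.dna.end}\t"
                f"{p.read_id}\t0\t{p.rna.strand}\t{p.dna.strand}\t.\n"
            )


# ---------------------------------------------------------------------------
# BED3+


def read_bed(path, sizes: ChromSizes, label: Optional[str] = None) -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet`.

    Column 4 (name) and column 5 (integer score, stored as read count) are
    optional; a literal ``.`` means absent.  Empty (start >= end) or
    out-of-bounds intervals are dropped under the 1% tolerance rule.
    """
    intervals: list[GenomicInterval] = []
    counts: list[Optional[int]] = []
    n_rows = 0
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            n_rows += 1
            fields = line.split("\t")
            try:
                name = None
                if len(fields) >= 4 and fields[3] != ".":
                    name = fields[3]
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name=name)
                if not iv.fits(sizes):
                    raise ValueError("outside chromosome bounds")
                count = None
                if len(fields) >= 5 and fields[4] != ".":
                    count = int(fields[4])
            except (ValueError, IndexError):
                n_bad += 1
                continue
            intervals.append(iv)
            counts.append(count)
    if n_bad:
        log.warning("%s: dropped %d of %d malformed BED records", path, n_bad, n_rows)
    if n_rows and n_bad / n_rows > MALFORMED_TOLERANCE:
        raise FormatError(
            f"{path}: {n_bad}/{n_rows} malformed records; wrong file dialect?"
        )
    read_counts = None
    if any(c is not None for c in counts):
        read_counts = [0 if c is None else c for c in counts]
    import os

    if label is None:
        label = os.path.splitext(os.path.basename(str(path)))[0]
    return PeakSet(label, intervals, read_counts)


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            name = iv.name if iv.name is not None else "."
            score = "." if peaks.read_counts is None else str(peaks.read_counts[i])
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


# ---------------------------------------------------------------------------
# GTF subset (gene + exon features; attributes gene_id, transcript_id,
# rna_class, species)

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_annotation(
    path, species_list: Sequence[str] = DEFAULT_NSA_SPECIES
) -> GeneAnnotation:
    """Read the GTF subset into a :class:`GeneAnnotation`.

    ``gene`` features define gene_id, rna_class and (for nsaRNA genes) a
    species name drawn from ``species_list``; ``exon`` features carry
    gene_id and transcript_id.  Coordinates are converted from 1-based
    inclusive to 0-based half-open.
    """
    gene_meta: dict[str, tuple[str, Optional[str]]] = {}
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    tx_strand: dict[tuple[str, str], tuple[str, str]] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            attrs = _parse_attributes(attrs)
            if feature == "gene":
                gid = attrs.get("gene_id")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without gene_id")
                rna_class = attrs.get("rna_class", "other")
                if rna_class not in RNA_CLASSES:
                    log.warning(
                        "%s:%d: unknown rna_class %r for %s; using 'other'",
                        path, lineno, rna_class, gid,
                    )
                    rna_class = "other"
                species = attrs.get("species")
                if rna_class == "nsaRNA":
                    if species not in species_list:
                        raise FormatError(
                            f"{path}:{lineno}: nsaRNA gene {gid} has species "
                            f"{species!r} not in the configured species list"
                        )
                else:
                    species = None
                gene_meta[gid] = (rna_class, species)
                gene_order.append(gid)
            elif feature == "exon":
                gid = attrs.get("gene_id")
                tid = attrs.get("transcript_id")
                if gid is None or tid is None:
                    raise FormatError(
                        f"{path}:{lineno}: exon missing gene_id/transcript_id"
                    )
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand=strand)
                key = (gid, tid)
                exons.setdefault(key, []).append(iv)
                tx_strand[key] = (chrom, strand)

    genes: list[Gene] = []
    tx_by_gene: dict[str, list[Transcript]] = {}
    for (gid, tid), ivs in exons.items():
        if gid not in gene_meta:
            raise FormatError(f"{path}: exon references unknown gene {gid!r}")
        chrom, strand = tx_strand[(gid, tid)]
        ivs = sorted(ivs, key=lambda iv: iv.start)
        tx_by_gene.setdefault(gid, []).append(
            Transcript(tid, chrom, strand, tuple(ivs))
        )
    for gid in gene_order:
        rna_class, species = gene_meta[gid]
        txs = tuple(
            sorted(tx_by_gene.get(gid, []), key=lambda t: t.transcript_id)
        )
        genes.append(Gene(gid, rna_class, species, txs))
    return GeneAnnotation(genes)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    """Write the GTF subset (inverse of :func:`read_annotation`)."""
    with open(path, "w") as fh:
        for gene in annotation:
            if not gene.transcripts:
                continue
            chrom = gene.transcripts[0].chrom
            strand = gene.transcripts[0].strand
            start = min(t.exons[0].start for t in gene.transcripts)
            end = max(t.exons[-1].end for t in gene.transcripts)
            attrs = f'gene_id "{gene.gene_id}"; rna_class "{gene.rna_class}";'
            if gene.species is not None:
                attrs += f' species "{gene.species}";'
            fh.write(
                f"{chrom}\tnsamap\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )
            for tx in gene.transcripts:
                for exon in tx.exons:
                    ex_attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    fh.write(
                        f"{tx.chrom}\tnsamap\texon\t{exon.start + 1}\t{exon.end}"
                        f"\t.\t{tx.strand}\t.\t{ex_attrs}\n"
                    )
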