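"""Per-pair RNA classification and the nascent / pre-mRNA junction filters.

Three bespoke filters drive the pipeline:

* the *nascent* filter flags a pair when its RNA and DNA ends lie on the
  same chromosome with a nearest-edge gap of at most ``nascent_distance``
  (default 2,000 nt, inclusive) - such pairs plausibly arise from a
  transcript still tethered to its transcription locus and are removed
  before any peak calling;
* the *junction* rule identifies posttranscriptional pre-mRNA reads: the
  RNA end must cover at least 1 nt of an exon and at least
  ``min_intron_overlap`` nt (default 10) of the adjacent intron across one
  exon-intron junction of a coding transcript on the matching strand;
* RNA-class assignment with precedence nsaRNA > rRNA > p_pre_mRNA > other,
  so specific annotations beat generic ones.

Strand handling: nsaRNA/rRNA exon overlap ignores strand (the species loci
are unambiguous); the junction rule is strand-specific because pre-mRNA
identity is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

from intervaltree import IntervalTree

from .assoc_stats import ContingencyTable
from .io_formats import (
    DEFAULT_NSA_SPECIES,
    GeneAnnotation,
    PairRecord,
)

log = logging.getLogger(__name__)

CLASS_PRECEDENCE = ("nsaRNA", "rRNA", "p_pre_mRNA", "other")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the classification filters.

    nascent_distance
        maximum nearest-edge gap (bp, inclusive) between RNA and DNA ends on
        the same chromosome for a pair to be flagged as putatively nascent.
    min_intron_overlap
        minimum intronic coverage (nt) across an exon-intron junction for a
        read to qualify as posttranscriptional pre-mRNA.
    nsa_species
        nsaRNA species whose genes define the nsaRNA class.
    rdna_chrom
        name of the pseudo-chromosome holding the rDNA repeating unit; any
        RNA end mapped there is classified rRNA.
    """

    nascent_distance: int = 2000
    min_intron_overlap: int = 10
    nsa_species: tuple[str, ...] = DEFAULT_NSA_SPECIES
    rdna_chrom: str = "rDNA"

    def __post_init__(self):
        if self.nascent_distance < 0:
            raise ValueError("nascent_distance must be >= 0")
        if self.min_intron_overlap < 1:
            raise ValueError("min_intron_overlap must be >= 1")


@dataclass(frozen=True)
class ClassifiedPair:
    pair: PairRecord
    rna_class: str
    species: Optional[str]
    nascent_flag: bool

    @property
    def read_id(self) -> str:
        return self.pair.read_id


class AnnotationIndex:
    """Interval-tree index over an annotation for fast RNA-end lookups."""

    def __init__(self, annotation: GeneAnnotation, params: FilterParams):
        self.params = params
        # exon trees for nsaRNA and rRNA genes; data = (class, species)
        self._exons: dict[str, IntervalTree] = {}
        # transcript-span trees for coding genes; data = Transcript
        self._coding: dict[str, IntervalTree] = {}
        for gene in annotation:
            for tx in gene.transcripts:
                if gene.rna_class in ("nsaRNA", "rRNA"):
                    tree = self._exons.setdefault(tx.chrom, IntervalTree())
                    for exon in tx.exons:
                        tree.addi(exon.start, exon.end, (gene.rna_class, gene.species))
                elif gene.rna_class == "coding":
                    span = tx.span
                    self._coding.setdefault(tx.chrom, IntervalTree()).addi(
                        span.start, span.end, tx
                    )

    def exon_hits(self, chrom: str, start: int, end: int):
        tree = self._exons.get(chrom)
        return tree.overlap(start, end) if tree is not None else set()

    def coding_transcripts(self, chrom: str, start: int, end: int):
        tree = self._coding.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]


def _as_index(
    annotation: Union[GeneAnnotation, AnnotationIndex], params: FilterParams
) -> AnnotationIndex:
    if isinstance(annotation, AnnotationIndex):
        return annotation
    return AnnotationIndex(annotation, params)


# ---------------------------------------------------------------------------
# nascent filter


def is_nascent(pair: PairRecord, params: FilterParams) -> bool:
    """True iff both ends share a chromosome with gap <= nascent_distance."""
    gap = pair.rna.gap(pair.dna)
    return gap is not None and gap <= params.nascent_distance


def flag_nascent(
    pairs: Sequence[PairRecord], params: FilterParams = FilterParams()
) -> list[bool]:
    """Per-pair nascent flags; order-preserving and idempotent."""
    return [is_nascent(p, params) for p in pairs]


# ---------------------------------------------------------------------------
# junction rule


def is_p_pre_mRNA(
    pair: PairRecord,
    annotation: Union[GeneAnnotation, AnnotationIndex],
    params: FilterParams = FilterParams(),
) -> bool:
    """Junction rule for posttranscriptional pre-mRNA reads.

    True iff, for some coding transcript on the matching strand, the RNA-end
    interval covers >= 1 nt of an exon and >= ``min_intron_overlap`` nt of
    the adjacent intron across a single exon-intron junction.
    """
    index = _as_index(annotation, params)
    rna = pair.rna
    for tx in index.coding_transcripts(rna.chrom, rna.start, rna.end):
        if tx.strand != rna.strand:
            continue
        exons = tx.exons
        introns = tx.introns
        for i, intron in enumerate(introns):
            intron_ov = rna.overlap_length(intron)
            if intron_ov < params.min_intron_overlap:
                continue
            # junction with the upstream (genomically left) exon
            left = exons[i]
            if rna.overlap_length(left) >= 1 and rna.start < intron.start < rna.end:
                return True
            # junction with the downstream (genomically right) exon
            right = exons[i + 1]
            if rna.overlap_length(right) >= 1 and rna.start < intron.end < rna.end:
                return True
    return False


# ---------------------------------------------------------------------------
# class assignment


def assign_rna_class(
    pair: PairRecord,
    annotation: Union[GeneAnnotation, AnnotationIndex],
    params: FilterParams = FilterParams(),
) -> ClassifiedPair:
    """Assign one RNA class to a pair, with precedence nsaRNA > rRNA >
    p_pre_mRNA > other; the nascent flag is set from the distance rule."""
    index = _as_index(annotation, params)
    rna = pair.rna
    hits = index.exon_hits(rna.chrom, rna.start, rna.end)
    species_hits = sorted(
        {data[1] for _, _, data in ((h.begin, h.end, h.data) for h in hits)
         if data[0] == "nsaRNA"},
        key=lambda s: params.nsa_species.index(s) if s in params.nsa_species else 99,
    )
    rrna_hit = any(h.data[0] == "rRNA" for h in hits) or rna.chrom == params.rdna_chrom

    if species_hits:
        if rrna_hit or len(species_hits) > 1:
            log.debug(
                "pair %s overlaps multiple classes/species; nsaRNA precedence",
                pair.read_id,
            )
        rna_class, species = "nsaRNA", species_hits[0]
    elif rrna_hit:
        rna_class, species = "rRNA", None
    elif is_p_pre_mRNA(pair, index, params):
        rna_class, species = "p_pre_mRNA", None
    else:
        rna_class, species = "other", None
    return ClassifiedPair(
        pair=pair,
        rna_class=rna_class,
        species=species,
        nascent_flag=is_nascent(pair, params),
    )


def classify_pairs(
    pairs: Sequence[PairRecord],
    annotation: Union[GeneAnnotation, AnnotationIndex],
    params: FilterParams = FilterParams(),
) -> list[ClassifiedPair]:
    """Classify every pair (class, species, nascent flag), order-preserving."""
    index = _as_index(annotation, params)
    return [assign_rna_class(p, index, params) for p in pairs]


# ---------------------------------------------------------------------------
# summaries


def contingency_by_class(
    pairs: Sequence,
    rna_predicate: Callable,
    dna_predicate: Callable,
) -> ContingencyTable:
    """2x2 counts of pairs by two membership predicates.

    ``a`` = both predicates true, ``b`` = RNA predicate only, ``c`` = DNA
    predicate only, ``d`` = neither; cells sum to the number of pairs.
    """
    if len(pairs) == 0:
        raise ValueError("cannot build a contingency table from zero pairs")
    a = b = c = d = 0
    for p in pairs:
        r, q = bool(rna_predicate(p)), bool(dna_predicate(p))
        if r and q:
            a += 1
        elif r:
            b += 1
        elif q:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def interchromosomal_fraction(pairs: Sequence) -> float:
    """Fraction of pairs whose RNA and DNA ends lie on different chromosomes."""
    if len(pairs) == 0:
        raise ValueError("interchromosomal fraction undefined for zero pairs")
    n = sum(1 for p in pairs if _pair_of(p).rna.chrom != _pair_of(p).dna.chrom)
    return n / len(pairs)


def _pair_of(p) -> PairRecord:
    return p.pair if isinstance(p, ClassifiedPair) else p


# ---------------------------------------------------------------------------
# classified-pair TSV (the 11-column pair dialect + rna_class, species,
# nascent columns)


def write_classified(classified: Iterable[ClassifiedPair], path) -> None:
    from .io_formats import PAIR_COLUMNS

    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PAIR_COLUMNS + ("rna_class", "species", "nascent")) + "\n")
        for cp in classified:
            p = cp.pair
            species = cp.species if cp.species is not None else "."
            fh.write(
                f"{p.rna.chrom}\t{p.rna.start}\t{p.rna.end}\t"
                f"{p.dna.chrom}\t{p.dna.start}\t{p.dna.end}\t"
                f"{p.read_id}\t0\t{p.rna.strand}\t{p.dna.strand}\t.\t"
                f"{cp.rna_class}\t{species}\t{int(cp.nascent_flag)}\n"
            )


def read_classified(path, sizes) -> list[ClassifiedPair]:
    from .io_formats import _parse_pair_row

    out: list[ClassifiedPair] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 14:
                raise ValueError("expected 14 columns in classified pair file")
            pair = _parse_pair_row(fields, sizes)
            species = None if fields[12] == "." else fields[12]
            out.append(
                ClassifiedPair(
                    pair=pair,
                    rna_class=fields[11],
                    species=species,
                    nascent_flag=bool(int(fields[13])),
                )
            )
    return out
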