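import numpy as np
import pytest

from nsamap.io_formats import (
    ChromSizes,
    Gene,
    GeneAnnotation,
    GenomicInterval,
    PairRecord,
    Transcript,
)


@pytest.fixture
def sizes():
    return ChromSizes({"chrA": 1_000_000, "chrB": 500_000, "rDNA": 45_000})


def make_pair(read_id, rna, dna):
    """Pair from (chrom, start, end[, strand]) tuples."""
    def iv(t):
        strand = t[3] if len(t) > 3 else "."
        return GenomicInterval(t[0], t[1], t[2], strand=strand)

    return PairRecord(rna=iv(rna), dna=iv(dna), read_id=read_id)


@pytest.fixture
def toy_annotation():
    """U1 gene, an rRNA gene on rDNA, a coding gene, and a Malat1 exon
    placed inside a second coding gene's intron (for precedence checks)."""
    u1_exon = GenomicInterval("chrA", 10_000, 10_164, strand="+")
    u1 = Gene("gene_U1", "nsaRNA", "U1",
              (Transcript("U1_tx", "chrA", "+", (u1_exon,)),))

    rrna_exon = GenomicInterval("rDNA", 500, 13_500, strand="+")
    rrna = Gene("gene_rRNA", "rRNA", None,
                (Transcript("rRNA_tx", "rDNA", "+", (rrna_exon,)),))

    # coding gene: exons [50000,50200) and [51000,51200), intron [50200,51000)
    ex1 = GenomicInterval("chrA", 50_000, 50_200, strand="+")
    ex2 = GenomicInterval("chrA", 51_000, 51_200, strand="+")
    coding = Gene("gene_cod1", "coding", None,
                  (Transcript("cod1_tx", "chrA", "+", (ex1, ex2)),))

    # second coding gene on chrB with a Malat1 exon inside its intron
    bx1 = GenomicInterval("chrB", 100_000, 100_300, strand="-")
    bx2 = GenomicInterval("chrB", 120_000, 120_300, strand="-")
    coding2 = Gene("gene_cod2", "coding", None,
                   (Transcript("cod2_tx", "chrB", "-", (bx1, bx2)),))
    malat1_exon = GenomicInterval("chrB", 105_000, 113_700, strand="+")
    malat1 = Gene("gene_Malat1", "nsaRNA", "Malat1",
                  (Transcript("Malat1_tx", "chrB", "+", (malat1_exon,)),))

    return GeneAnnotation([u1, rrna, coding, coding2, malat1])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20181)
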