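# Methods

`nsamap` infers the parts of a genome that lie near nuclear speckles from
RNA–DNA proximity-ligation read pairs, and validates the inferred domains
with pre-mRNA proximity, peak-set comparisons, permutation nulls and
single-cell FISH/IF colocalization statistics. This note records the
models, parameter choices and numerical conventions, and what the
synthetic benchmarks do and do not demonstrate.

## Coordinate frame and dialects

All coordinates are 0-based half-open, in memory and on disk (BED
convention); GTF input is converted from 1-based inclusive on read. The
ribosomal DNA repeating unit is carried as an extra "chromosome" in the
chrom.sizes table (default name `rDNA`, 45 kb — the scale of the human
repeating unit), so rRNA→rDNA ligation can be scored in the same frame as
the main genome. Parsers drop individually malformed records but fail hard
above 1% malformed, which separates stray bad lines from a wrong-dialect
file.

## Pair classification

Each read pair carries an RNA-end and a DNA-end interval. Three rules, in
precedence order nsaRNA > rRNA > p-pre-mRNA > other:

* **nsaRNA** — the RNA end overlaps an exon of a gene of a configured
  nuclear speckle-associated species (default U1, U2, U4, U4atac, U5, U6,
  U6atac, U11, U12, 7SK, Malat1). Overlap ignores strand: the species loci
  are unambiguous. A pair counts once toward its species however many gene
  copies it overlaps.
* **rRNA** — the RNA end overlaps an rRNA gene or maps anywhere on the
  rDNA pseudo-chromosome.
* **p-pre-mRNA** (posttranscriptional pre-mRNA) — the junction rule: for
  some coding transcript on the *matching strand*, the RNA end covers at
  least 1 nt of an exon and at least `min_intron_overlap` nt (default 10)
  of the adjacent intron across a single exon–intron junction. Strand
  specificity is required because pre-mRNA identity is strand-specific.

The **nascent filter** flags any pair whose two ends share a chromosome
with a nearest-edge gap of at most `nascent_distance` nt (default 2,000,
inclusive — overlapping ends have gap 0). Such pairs plausibly reflect a
transcript still at its transcription locus rather than a trafficked RNA,
and all downstream domain inference uses only unflagged pairs. The
measuring points (nearest edges) are this package's convention; one
configurable threshold serves both the general pipeline and the pre-mRNA
analysis.

## Broad-domain ("peak") calling

DNA ends are reduced to interval midpoints; at read lengths of tens of bp
against domains of 0.1–13 Mb the approximation is lossless in practice.

Two paths are exposed:

1. **Candidate clusters** — single-linkage clustering of midpoints per
   chromosome (join when consecutive midpoints are ≤ `cluster_max_gap`
   = 100 kb apart), retaining clusters with ≥ 9 reads and midpoint span
   ≥ 500 kb. This is the quadrant-style candidate analysis used to
   contrast cell states.
2. **Broad peaks** — a deterministic windowed enrichment-merge caller:

   * bin each chromosome in `window` = 25 kb tiles and count
     position-deduplicated midpoints per tile (deduplication is the usual
     guard against PCR duplicates and makes calling invariant to read
     duplication);
   * mark tiles whose count exceeds `max(1, enrichment_fold ×
     genome-mean count per tile)` with `enrichment_fold` = 2 — marking is
     deliberately permissive;
   * merge marked tiles within `merge_gap` = 100 kb;
   * trim each merged region to the extent of the reads it contains
     (reported interval) and retain it only if it has ≥ `min_reads` = 9
     reads and its count is significantly above the genome-average
     expectation *over the window span it was selected from* (one-sided
     Poisson at `region_alpha`). Testing at the selection resolution
     matters: testing over the trimmed extent would be anti-conservative,
     because trimming always shrinks the span of a selected fluctuation.

   `region_alpha` defaults to 1e-7 ≈ 0.01 / (7×10³ windows × ~10 merge
   scales) on the default 180-Mb frame — genome-wide family-wise error
   control, so uniform ("sporadic-interaction") data yields essentially no
   peaks. In a null-calibration study (80 uniform simulations at the
   default frame) the false-call rate was 0.087/run at 1e-5, 0.025/run at
   1e-6 and 0/run at 1e-7; the power cost of 1e-7 is confined to ~100-kb
   domains under the most diluted planted configurations.

   The two-stage design (permissive marking + region-level significance)
   is what lets a single parameterization recover domains across the full
   100 kb – 13 Mb size range: per-tile enrichment of a broad, diluted
   domain is individually weak, but its aggregated region count is
   decisive, while the region test simultaneously rejects the tight
   background fluctuations that permissive marking admits. A single high
   fold threshold cannot do both.

   Broad-peak calling is restricted to the main genome: the rDNA
   pseudo-chromosome is a separate control frame whose tiny size makes
   per-bp background noise look enriched. No minimum span is imposed by
   default (`min_peak_span` = 0): reported domains as small as ~100 kb are
   legitimate, and the 500-kb floor belongs to the candidate-cluster path
   only.

   This caller is a documented re-implementation of broad-domain calling
   in the spirit of enrichment-merge tools; exact agreement with any
   specific external peak caller is not promised.

Set operations: peak–peak overlap counts ≥ 1 shared bp; union merges
overlapping or bookended intervals; proximity counts intervals whose
nearest target midpoint is within a distance (inside counts as 0).
**Boundary alignment** against TADs counts a peak boundary as aligned when
within `tolerance` of any TAD boundary on the same chromosome, and a peak
as *tiled* when both boundaries align and consecutive TADs (each adjacent
pair bookended within tolerance) partition it. The default tolerance is
one Hi-C bin (40 kb), the quantization unit of TAD boundaries; no
published tolerance exists for this comparison, so it is configurable.

## Statistics

* Odds ratios are sample cross-product ratios (a·d)/(b·c); a zero
  denominator returns +inf with a warning, and a Haldane–Anscombe +0.5
  correction is available. Note a cross-product ratio can differ in the
  second decimal from conditional-MLE estimators printed elsewhere.
* Chi-square is Pearson's test with 1 df, no continuity correction by
  default (a Yates flag exists); Fisher's exact test is two-sided.
* Density profiles tile the genome in fixed bins (1 Mb default for
  genome-wide concordance; the last bin of a chromosome may be short);
  profile concordance uses Spearman correlation with mid-ranked ties,
  appropriate for heavily tied count data.
* **Permutation null** — each interval is re-placed uniformly at random on
  its own chromosome, preserving its length, re-drawing on overlap with an
  already-placed interval (longest-first within a chromosome keeps
  rejection sampling efficient; 1,000 attempts before error). An optional
  excluded-region BED can mask assembly gaps but is off by default — the
  convention, since no null specification exists for the original
  analyses. Empirical p-values use the add-one estimator
  p = (1 + #{null ≥ obs})/(1 + n_perm), which is valid, never zero, and
  makes "p < 0.001" with 1,000 permutations equivalent to the observed
  statistic exceeding every null draw.
* **Window association** — tile the genome in 1,000-bp windows, classify
  each by ≥ 1 bp overlap with each of two peak sets, and feed the
  resulting 2×2 window-count table to Fisher's test / odds ratio.
* The reads-in-peaks permutation test applied to peaks called from the
  same reads is circular by construction: any called peak is enriched, so
  the test rejects whenever at least one peak exists. It is a check on the
  existence and strength of clustering, not an independent discovery test;
  this is why the caller's genome-wide false-call control matters for the
  sporadic scenario.

## Single-cell imaging

Stacks are 3D (z, y, x) two-channel voxel grids (FISH + SC35 speckle
marker) with a binary nucleus mask. Both channels are binarized by Otsu's
threshold computed over in-mask voxels (fixed-threshold override
available); Otsu on positively rescaled data gives the same binarization,
so segmentation is intensity-scale invariant. Connected components use
26-connectivity in 3D — a generalization of per-slice particle analysis;
components below `min_voxels` = 2 are discarded. Spots touching the mask
border are retained.

Colocalization uses the conservative pixel-overlap rule: a FISH spot is
isolated only if *none* of its voxels is SC35-positive; one positive voxel
makes it colocalized. This upper-bounds any centroid-distance rule at
radius zero. Per-spot and per-image summaries are kept separate — the
pooled per-spot fraction and the mean of per-image fractions are different
statistics and are reported as such. Center-to-center distances are
Euclidean in voxel units, treating voxels as isotropic (anisotropy is
carried as metadata only); distance histograms bin (d−1, d] for d = 1..10
with an overflow count so totals are conserved (an exact 0 falls in bin
1). Group comparisons use Welch's t-test on per-image fractions (errors on
two zero-variance groups) and the two-sample Kolmogorov–Smirnov test on
pooled distances.

## Synthetic data generator

The generator emulates the study conditions rather than the raw assay: a
toy genome of four autosome stand-ins (60/50/40/30 Mb — large enough for
Mb-scale domains, small enough for sub-minute runs) plus the 45-kb rDNA
unit; one single-exon gene per nsaRNA species at realistic mature lengths;
a 13-kb precursor-style rRNA gene; 30 multi-exon coding genes with introns
comfortably larger than the junction-rule threshold.

Scenario `speckled` plants `n_planted_peaks` = 10 non-overlapping domains
with lengths log-uniform over [100 kb, 13 Mb] (the reported size range of
speckle-proximal domains) and draws non-nascent nsaRNA / pre-mRNA DNA ends
inside them with probability `in_peak_prob` = 0.72 (the in-domain read
share of the real data), choosing domains in proportion to length so
density is uniform across domains. Scenario `diffuse` plants nothing and
draws uniformly. Background draws are rejected out of planted domains and
out of the nascent window, so truth labels are exact and the realized
in-domain fraction matches the configured probability to binomial error.
Pre-mRNA DNA ends are interchromosomal with probability 0.93; rRNA DNA
ends hit the rDNA unit with probability 0.80 against a 0.001 background
rate for other classes (a planted odds ratio of ~4×10³, emulating the
several-hundred-fold enrichment of the nucleolar control); a configurable
`nascent_fraction` (default 0.10) of nsaRNA/pre-mRNA pairs is drawn with
the DNA end within the nascent distance of the RNA end. Boundary probes
(gaps of exactly 1,999/2,000/2,001 nt; junction intron overlaps of 9/10/11
nt) are emitted by default so both filter thresholds are exercised
end-to-end.

Synthetic nuclei are ellipsoids (default 14×56×56 voxels) with 20–35
Gaussian SC35 clusters (σ 1.2, centers ≥ 4 voxels apart) and 1–3 FISH
spots (σ 1.0); a spot planted as colocalized is centered on a cluster with
sub-voxel jitter, otherwise it is kept ≥ 5 voxels from every cluster
center. Group sizes and colocalization probabilities default to 82 vs 100
cells at 0.84 vs 0.57.

Everything is deterministic under the master seed, byte-for-byte.

**What passing synthetic benchmarks shows — and does not.** The generator
produces clean, well-separated signal: uniform background, uniform-density
rectangular domains, exact annotations, high-SNR Gaussian blobs, isotropic
voxels. Passing demonstrates that the algorithms are correct and correctly
calibrated under their stated models. It does not demonstrate robustness
to mappability and GC structure, copy-number variation, chromatin-state
confounding of the background rate, partially spliced annotation
ambiguity, optical aberrations or anisotropic point-spread functions —
none of which are modelled. One concrete consequence: with a uniform
background, off-domain density bins are exchangeable Poisson noise, so the
genome-wide Spearman concordance of two profiles sharing the same planted
domains plateaus around 0.4–0.7 (1–5 Mb bins, default depths) rather than
approaching 1 — real assays correlate in the background too, through
shared mappability and chromatin covariates.

## Problem sizes used in tests and the acceptance script

The shipped checks run at the generator's native conditions (15,000 nsaRNA
pairs per dataset, 10 planted domains, 1,000 permutations, 82+100 nuclei),
with 20 seeds per scenario in the test suite and 5 in the acceptance
script, 200 datasets × 200 permutations for null calibration, and reduced
pair counts only where a check is about bookkeeping rather than power
(e.g. byte-determinism). These sizes were chosen to keep a full run at
desk scale while leaving binomial error well inside the asserted margins.

## Known limitations

* The broad-peak caller assumes a globally uniform background rate; a
  locally varying background (e.g. per-chromosome rates) would require a
  local-lambda extension.
* The permutation null preserves interval lengths and chromosome
  assignment but not inter-interval spacing or exclusion of unmappable
  regions (an optional mask hook exists).
* The junction rule needs transcript annotation on the correct strand;
  unstranded libraries would need a relaxed mode.
* Imaging analysis assumes the nucleus mask is given; no nucleus
  segmentation from a DNA channel is provided.
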