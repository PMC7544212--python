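# Methods

## Overview

`tifseq2` reconstructs transcript isoform boundaries (TIFs) from sequencing
libraries in which each read pair reports the exact 5′ end (transcription
start site, TSS) and 3′ end (polyadenylation site, PAS) of one RNA molecule.
The pipeline runs six stages in order:

1. **Boundary extraction** — each aligned mate pair collapses to two
   single-nucleotide boundary positions.
2. **UMI deduplication** — PCR copies collapse into unique molecules.
3. **Internal-priming filtering** — artifactual 3′ ends at genomic A-rich
   tracts are removed.
4. **Normalization and clustering** — per-sample tag counts are mapped onto
   a common reference power law, then clustered into per-sample and
   cross-sample consensus TSS/PAS clusters.
5. **TIF calling** — TSS and PAS clusters are linked through their
   supporting read pairs and quantified per sample.
6. **Annotation and overlap analysis** — TIFs are assigned to transcript
   models, classified, and screened for tandem overlap and read-through
   (putative transcriptional fusion) arrangements.

A synthetic-data module generates genomes, annotations and libraries with
known ground truth so that every stage has a quantitative test surface.

## Coordinate conventions

All internal coordinates are 0-based half-open; GTF/GFF I/O converts at the
boundary and BED is written natively. A boundary *position* is the 0-based
index of the transcript's first or last transcribed base. On the plus strand
the TSS is the 5′-mate's leftmost base and the PAS the 3′-mate's rightmost
base; mirrored on the minus strand. Pairs whose mates map to different
chromosomes or strands are rejected, as are pairs whose implied boundary
ordering contradicts the strand (these arise from circularization chimeras).

## UMI deduplication

Molecules carry 8-mer UMIs. Two tags are linkable when they share the
chromosome, strand and PAS position, their TSS positions differ by at most
1 bp (sequencing/alignment slippage at the 5′ end), their UMIs differ by at
most 1 mismatch, and — under the default *directional* method — the larger
count is at least twice the smaller minus one (the adjacency rule that
distinguishes PCR/sequencing-error UMI neighbours from genuine co-occurring
molecules). Connected components of this linkage graph collapse to single
tags positioned at the highest-count member; ties break toward the smaller
coordinate and then the lexicographically smallest UMI, making output
independent of input order. A plain single-linkage variant (`cluster`) is
available by flag. The PAS is held exact by default (`pas_shift = 0`):
poly(A)-slippage trimming upstream of alignment already stabilizes the 3′
coordinate; a tolerance can be enabled where that assumption fails.

Deduplication conserves mass (output counts sum to the number of input
tags) and is idempotent and permutation-invariant on the inputs exercised
by the test suite; the implementation is checked against an independent
brute-force connected-components oracle.

## Chimera estimation

Intermolecular circularization joins the 5′ end of one cDNA to the 3′ end of
another. Because samples are pooled with distinct barcodes before
circularization, a chimera between molecules of different samples is
directly observable as a barcode mismatch. With k equally pooled samples a
chimera is cross-sample with probability (k−1)/k, so the corrected rate is
`observed_fraction * k/(k-1)`, capped at 1. The estimate is computed on all
input pairs *before* mapping-based rejection, since rejected pairs
(cross-chromosome, discordant) are enriched for chimeras. Barcode-mismatched
pairs are then discarded; same-sample chimeras are invisible and remain as a
low-level background, which the ≥ 4-pair support threshold keeps out of TIF
calls under realistic rates.

## Internal-priming filter

Oligo-dT primers can anneal to genomic A-rich stretches, creating false 3′
ends. A PAS tag is flagged when the 10 genomic bases immediately downstream
of the PAS base (on the transcript strand; the PAS base itself excluded)
contain ≥ 7 adenines. N bases never count; windows truncate at contig edges.
Flagged tags are excluded from all downstream clustering. The hexamer QC
reports, for kept versus flagged tags, the frequency of the poly(A)-signal
motif A[AT]TAAA at each upstream offset and summarizes the fraction of tags
with a motif starting 15–30 nt upstream — genuine cleavage sites are
motif-enriched there, internal-priming sites are not. The QC is diagnostic
only and never filters.

## Power-law normalization and clustering

Boundary-tag count distributions are heavy-tailed; to compare samples the
reverse-cumulative distribution R(x) (number of positions with ≥ x tags) is
fitted by OLS in log10–log10 space over counts in `fit_range` (default
[10, 1000]), using the distinct observed count values as fit points. Each
raw count x then maps to the count x′ at which a reference law
R_ref(x′) = T·x′^(−α_ref) attains the fitted R(x):

    x′ = 10^((a + b·log10 x − log10 T) / (−α_ref))

Defaults α_ref = 1.25, T = 10⁶ follow the lineage of the tag-normalization
method this reproduces; all three are configurable. Normalized counts are
real-valued and never re-rounded. Degenerate inputs (flat distributions,
fewer than 3 fit points in range, non-negative slopes) raise errors rather
than producing silent garbage. By construction, re-fitting the normalized
counts over the image of the fit range returns slope −α_ref exactly (the
log-space map is affine).

Positions with normalized count < 1 in more than one sample are excluded
(low coverage). Remaining positions are chained single-linkage per sample:
neighbours ≤ 10 bp apart join one cluster; singleton clusters survive only
with normalized count strictly above 1. Per-sample clusters of one kind then
merge across samples into consensus clusters whenever intervals overlap or
gap ≤ 10 bp, so consensus intervals of one kind/strand are pairwise
separated by more than the window. Cluster "dominant" positions (maximum
normalized count, ties toward smaller coordinates) serve as the best
single-nucleotide boundary estimates.

## TIF calling and quantification

Pairs with inclusive base span |pas − tss| + 1 below 300 bp or above 2 Mb
are dropped (too short to be a credible molecule; too long to be a credible
template). The span filter is applied after deduplication and before
linking. A pair supports a (TSS cluster, PAS cluster) combination when both
its boundaries fall inside the respective consensus intervals on one strand.
A combination becomes a TIF when its support summed across all samples is
≥ 4 unique molecular events (per-sample thresholding available by flag);
the per-sample support counts form the expression matrix (rows = TIFs,
columns = samples), ready for external differential-expression tooling.

## Annotation and classification

A TIF is compared with same-strand transcripts overlapping its span:
d1 = |TIF TSS − transcript 5′ end|, d2 = |TIF PAS − transcript 3′ end|,
measured from cluster dominant positions (cluster edges by option). The TIF
is assigned to the transcript minimizing d1 + d2 (ties: smaller d1, then
smallest transcript id) and inherits its gene. With tolerance 200 bp
(inclusive) the five categories are: *annotated* (both within), *new_tss*,
*new_pas*, *new_boundaries*, and *intergenic* (no same-strand overlap).
Intergenic TIFs whose spans overlap merge into unannotated transcribed
regions ("unannotated genes"); a merged region overlapping an annotated
same-strand gene would contradict the classification and is asserted
against. Antisense overlap never creates an assignment, consistent with the
same-strand scope of the overlap analyses.

## Overlap typology and read-through detection

For same-strand TIF pairs whose TSSs lie within 10 kb, the pipeline records
overlap width (or gap when disjoint, reported as a signed offset), the
overlapped fraction of each TIF's genomic span (single-exon view — the assay
observes boundaries, not splicing), and the TSS–TSS distance. Patterns:
both fractions > 0.9 → *high_overlap* (alternative isoforms of one unit);
exactly one > 0.9 → *truncated* (a long isoform and its intronic-TSS/PAS
short form); both < 0.2 with nonzero overlap → *low_tandem*; zero overlap →
*disjoint*; otherwise *other*. The tandem-PAS statistic is the fraction of
overlapping pairs whose upstream PAS falls within 2 kb downstream of the
downstream TIF's TSS — the window within which termination of an upstream
unit inside a downstream unit is typically observed.

A read-through call requires the TIF's TSS inside (or within 200 bp of) one
gene and its PAS inside (or within 200 bp of) a distinct, same-strand,
strand-aware-downstream gene. Genes overlapping another same-strand gene are
excluded as ambiguous anchors, and by default a third same-strand gene lying
wholly inside the TIF span disqualifies the call
(`--allow-skipped-genes` relaxes this, since real read-throughs can step
across small intervening features).

## Synthetic data generator

The generator emulates the library the pipeline consumes; its defaults are
the package's reference study conditions: 20 genes over two 120-kb
chromosomes (8 isolated, 3 two-isoform genes, 2 tandem-overlap pairs with
designed overlap fractions, 2 read-through pairs each contributing an
unannotated fusion isoform, 1 unannotated gene), 4 samples, depth 50
(mean molecules per sample at unit abundance), boundary jitter sd 1 bp,
PCR duplicate rate 0.3, internal-priming rate 0.05, chimera rate 0.02,
8-mer UMIs.

Isoform abundances follow a discrete Pareto law (α = 1.25) capped at 10.
The cap bounds the library size and fixes the abundance dynamic range at
one order of magnitude; with the heavy tail uncapped, same-barcode chimeras
between the two most abundant isoforms concentrate enough support to exceed
the 4-pair calling threshold, which would make spurious calls a property of
the abundance draw rather than of the pipeline. The chosen range keeps the
expected chimeric support for any isoform pair well below threshold while
preserving a realistic expression spread for the normalization fit.

Reference construction plants, at every true PAS: an A[AT]TAAA hexamer
starting 16–28 nt upstream, and an A-poor window (at most 2 adenines across
the last 6 transcribed and first 20 downstream bases) so that no jittered
true PAS within ±5 bp can reach the 7-A priming threshold. Artifact sites
carry 25 adenines centred on the site, so every priming event is flagged
regardless of neighbouring positions. Priming replaces a molecule's PAS
with its isoform's artifact site exactly (the primer anneals at the tract,
so the artifact position carries no jitter); chimeras swap a molecule's 3′
side — coordinates and sample barcode — with a partner molecule drawn
uniformly across all samples; duplicates re-emit an exact copy with the
configured probability. All randomness flows from two integer-seeded
streams (reference and library), so outputs are byte-identical across runs
and platforms.

What the generator does *not* emulate: splicing (molecules are boundary
pairs, not read sequences), sequencing errors in bases or UMIs beyond the
modelled 1-bp boundary jitter, mapping ambiguity, unequal sample pooling,
and chromatin- or expression-dependent cluster-width structure. Passing
recovery tests therefore demonstrate the correctness of the boundary
calculus, not robustness to alignment artifacts.

## Problem sizes and numerical choices

The default simulation produces roughly 15,000–25,000 read pairs from 25
isoforms; the test suite and the acceptance script run the full pipeline on
libraries of this size, which completes in seconds. The power-law recovery
checks use 10⁵ Pareto draws. Recovery criteria follow the generator's
sampling noise: rate estimators are compared within 3 binomial standard
errors; the Pareto exponent within ±0.05, the empirical spread of the OLS
fit at this sample size.

Ties everywhere break deterministically (smaller coordinate, then smaller
identifier), cluster and TIF ids are assigned after a global sort, and
per-chromosome work is scheduled order-independently, so reruns and
different worker counts produce byte-identical outputs.

## Known limitations

- The overlap fractions treat TIF spans as single exons; for spliced
  transcripts the genomic overlap overstates the transcribed overlap.
- The chimera correction assumes equal-mass pooling; unequal pooling would
  need per-sample weights.
- Whether the low-coverage rule should count samples or sample pairs is
  ambiguous in the method's prose; the literal count-of-samples reading is
  implemented and the threshold (`max_low_samples`) is configurable.
- The singleton normalized-count rule is applied per sample before
  consensus building; applying it to aggregated counts is a defensible
  alternative that would retain slightly more singleton clusters.
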