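# Methods

## Scope and model

`dosagelens` re-implements, as a tested library, the computational
analysis of facultative dosage compensation: how the MSL complex — which
normally doubles transcription of the single male X chromosome in
*Drosophila* via H4K16 acetylation — also binds a class of autosomal
promoters, and whether the mouse 1:1 orthologues of those bound genes
are coherently dosage-sensitive to knockout of the nucleating factor
MSL2. The pipeline has four analytical layers:

1. **Fragment-size-resolved MNase ChIP profiling.** Mapped fragments are
   split at 140 bp: fragments ≤ 140 bp trace the direct DNA footprint of
   a bound protein, fragments > 140 bp trace crosslinked or flanking
   nucleosomes. Coverage is binned (2 bp default) as mean per-base depth
   and normalised as log2(ChIP/input), input subtraction, or 1× genome
   coverage. Depth scaling always excludes the X chromosome, so that the
   hallmark of male X monosomy — an X:autosome input coverage ratio of
   0.5 — survives normalisation.
2. **Meta-profiles and peak classification.** Two matrix geometries:
   a fixed ±800 bp window around a reference point (site center,
   strand-aware), and a meta-gene layout with ±500 bp unscaled around
   the TSS and the remaining gene body linearly rescaled to 1000 bp.
   Autosomal peaks are clustered by k-means (k = 3) on concatenated,
   per-track-standardised signal; peaks are assigned to genes whose TSS
   lies within a closed ±200 bp window; X overrepresentation is tested
   with Fisher's exact test.
3. **FLASH crosslink quantification.** Read pairs merge on an exact
   overlap ≥ 30 nt; merged reads are demultiplexed on a leading barcode
   (assigned iff exactly one whitelist entry lies within Hamming
   distance 2); tags with mapping quality ≤ 10 are dropped (note the
   deliberate asymmetry with ChIP, which drops quality < 10 — both rules
   follow their respective upstream conventions); PCR duplicates
   collapse on (position key, strand, random tag); unique events are
   counted per gene and compared between samples as M/A values.
4. **Cross-species dosage-sensitivity statistics.** Gene sets (bound-gene
   clusters, HAS-overlapping genes, HAS-proximal genes within 2344 bp)
   are translated through 1:1 orthology, and the mean knockout log2FC of
   each set is compared against B = 10,000 random same-size gene samples
   from the expression universe, with Benjamini–Hochberg correction
   across the sets tested. Supporting statistics: the two-clone
   FDR < 0.05 DE consensus filter, Welch's t-test, H4K16ac gain/loss
   classification, and efficiency-corrected qPCR relative
   quantification against the geometric mean of reference genes.

## Key parameters

All thresholds live on `AnalysisParams` with these defaults (units bp
unless noted): footprint boundary 140 (inclusive small); ChIP MAPQ ≥ 10
kept; FLASH MAPQ > 10 kept; coverage binsize 2; peak merge gap 10
(bedtools `-d` semantics — bookended intervals always merge); TSS
assignment window ±200 (closed); mouse TSS peak window ±1000;
reference-point flank ±800; meta-gene unscaled flank 500 and scaled body
1000; pair-merge overlap 10 nt (ChIP) / 30 nt (FLASH); barcode Hamming
≤ 2; DE FDR 0.05; bootstrap B = 10,000; HAS-proximal distance ≤ 2344
(inclusive); k-means k = 3; log2 pseudocount 1.0. The matrix column
width (10 bp) is not dictated by the analysis design and is
configurable; the underlying track stays at binsize 2.

## Numerical and design choices

- **Coordinates** are 0-based half-open everywhere; GTF (1-based closed)
  converts at the I/O boundary. The TSS of a minus-strand gene is
  `end − 1`: half-open ends are not covered bases.
- **Bin values** are mean per-base depth; the last bin of a chromosome
  is zero-padded to full width so that Σ(bin × binsize) equals the
  summed (clipped) fragment lengths exactly — the mass-conservation
  invariant the tests assert at 1e-9.
- **Depth equalisation** for ratio/subtraction modes scales both tracks
  to the smaller total on non-excluded chromosomes (read-count style);
  log2 ratios use a pseudocount of 1.0.
- **Region center** is floor((start+end)/2). Out-of-bounds matrix cells
  are NaN-masked, never zero-filled, and are excluded from column means.
  Meta-gene rows drop (and report) genes whose body is not longer than
  the unscaled flank.
- **Dyad profiles.** For peak-location tests the package uses
  fragment-midpoint density rather than base coverage: every
  nucleosome-scale fragment (> 141 bp) spans its own center, so base
  coverage is flat across roughly ±70 bp around a positioned nucleosome
  and cannot localise it to one 10 bp column, while midpoint density is
  sharply peaked. This is the standard positioning estimate in the
  MNase literature.
- **Cluster labelling.** k-means (k-means++, 10 restarts, fixed seed) is
  followed by deterministic relabelling: clusters are numbered 1..k by
  descending mean intensity of the first supplied track, and rows sort
  within clusters by descending first-track row mean. "Cluster 1" is
  therefore reproducible across runs; any other numbering is arbitrary.
- **Fisher's exact test** conditions on the margins (hypergeometric);
  two-sided sums tables with probability ≤ observed (with a 1e-9
  relative tolerance to guard ties against floating-point rounding).
  A zero margin yields p = 1 with a warning.
- **Bootstrap test.** Default null sampling is without replacement
  ("random gene set of the same size"); a with-replacement mode exists.
  The empirical p uses the add-one correction (1 + #extreme)/(B + 1),
  so p is never 0 and the test is exactly calibrated on the lattice.
  `bootstrap_set_test` defaults to two-sided; `conservation_test`
  defaults to "less" because the scientific hypothesis is coherent
  *down*-regulation on knockout, and a one-sided test is also robust to
  the small contamination of the universe mean by the shifted set.
- **DE consensus filter** requires FDR < α in *every* clone and, by
  default, agreement of the log2FC sign across clones (disable with
  `require_sign_agreement=False` for the literal FDR-only rule);
  consensus log2FC is the across-clone mean.
- **qPCR.** Efficiency is E = 10^(−1/slope) from the least-squares fit
  of Ct against log10(dilution); quantities are Q = E^(−Ct); relative
  expression divides the target quantity by the geometric mean of the
  reference-gene quantities.
- **Degenerate inputs** fail loudly: empty intervals, start ≥ end,
  unknown chromosomes (line-numbered parse errors), zero-variance
  clustering input, zero total coverage, efficiencies outside (1, 2],
  sets smaller than 2 or larger than the universe.

## The synthetic-data generator

The generator is first-class, tested code; its defaults define the
study conditions every recovery test runs under.

- **Genome**: one X plus 2 autosomes of 300 kb (default), 60
  non-overlapping genes per chromosome, bodies 1.5–2.5 kb, intergenic
  gaps ≥ 3 kb laid out one gene per slot. Gaps this large make planted
  site–gene relationships unambiguous by construction.
- **Sites**: HAS on the X only, either inside a gene body (the
  direct-overlap gene set) or intergenic at 50–2344 bp from one gene
  (the proximal set; gap sizing keeps every other gene outside the
  window). Cluster-1/2/3 sites are centered within ±100 bp of distinct
  autosomal TSSs so the ±200 bp assignment rule recovers the planted
  links exactly.
- **ChIP fragments**: per bound site, Poisson(200) footprint fragments
  (truncated normal length, mean 90, sd 15, on [40, 140]) centered on
  the site with 10 bp jitter, plus Poisson(100) nucleosomal fragments
  (mean 165, sd 12, on [141, 250]) at each phased offset (±200 bp).
  Uniform background of 0.01 fragments/bp *per chromosome copy*, so the
  male X (one copy) has half the female coverage. 5% of fragments get
  MAPQ 5 and 5% are duplicated exactly, giving the filters real work.
  The antibody label selects which planted classes emit (MSL2tg-like:
  all; MLE-like: HAS only; untagged: none).
- **FLASH**: each gene gets a unique 30 nt insert (the exact-lookup
  stand-in for alignment, consistent with the no-aligner scope); each
  molecule is barcode + 7 nt random tag + insert, sequenced
  1 + Poisson(3) times as an overlapping 40+40 nt pair. Random tags are
  drawn without replacement within a gene, so an error-free library
  round-trips through deduplication to the truth counts *exactly*;
  real libraries would show rare tag collisions.
- **DE tables**: per-gene log2FC = planted shift + N(0, 0.3) per clone;
  p-values from the one-sample z-model at the known sd, BH-adjusted
  within each clone. The planted effect is −0.5 on the cluster-1
  orthologues only.
- **Conservation scenario**: a larger layout (700 genes/chromosome,
  6 kb gaps) sized so the gene sets reach the published counts —
  clusters of 66/269/346 bound genes, 432 HAS-overlapping and 231
  HAS-proximal genes — against a 3000-gene expression universe with
  fully 1:1 orthology. These sizes keep the statistical geometry of the
  real experiment while everything else stays desk-scale.
- **qPCR**: Ct = base − log_E(level) + N(0, 0.15), references at level
  1, plus a 4-point 1:10 dilution series per primer (Ct step log2(10)
  at E = 2).
- **Determinism**: one global seed split into fixed named substreams
  (genome, sites, chip, flash, de, qpcr, orthology); regenerating one
  component never perturbs another.

**What passing tests do and do not show.** The generator has no
sequencing errors, no mappability or GC structure, no overdispersion in
the DE noise, no correlated genes, and orthology is planted rather than
inferred. Recovery therefore certifies the *arithmetic* of the pipeline
(boundaries, geometry, deduplication, calibration, power under the
planted effect), not robustness to the failure modes of real libraries.

## Problem sizes used in the test suite

Unit tests run on ≤ 10 kb chromosomes against literal per-base oracles.
The end-to-end checks use the 300 kb default genome (≈ 35,000 ChIP
fragments per library), a 1 Mb genome for mass conservation, all ≈ 246k
2×2 tables with row margins ≤ 30 for Fisher exactness, 200 replicate
sets at B = 2000 for bootstrap calibration, and 100 seeded runs of the
conservation scenario at B = 10,000 for the power check, which is the
longest single test (a few minutes on one CPU).

## Known limitations

- Peak calling, read alignment, DE model fitting, motif discovery and
  GO analysis are upstream/downstream of this package and out of scope;
  the pipeline consumes their outputs (BED, fragment tables, DE TSVs).
- `merge_pairs` requires an exact overlap match; real merger tools
  tolerate mismatches.
- The FLASH transcriptome mode identifies genes by exact insert lookup;
  coordinate mode exists on `MappedTag` but no aligner is bundled.
- bedGraph is the only coverage export (no bigWig); fragment tables
  replace BAM.
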