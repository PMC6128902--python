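# dosagelens

Analysis toolkit for studying facultative dosage compensation: how the
*Drosophila* MSL complex — the machinery that doubles transcription of
the single male X chromosome through H4K16 acetylation — also occupies a
class of autosomal promoters, and whether the mouse orthologues of those
bound genes are dosage-sensitive to loss of the nucleating factor MSL2.

The package is aimed at computational epigenomics work on MNase
ChIP-seq, CLIP-type RNA-crosslink data and cross-species expression
comparisons. It provides:

- **Fragment-size-resolved ChIP profiling** — partition of MNase
  fragments at 140 bp into protein footprints (≤ 140 bp) and
  nucleosome-scale fragments (> 140 bp); binned coverage with
  log2-ratio, subtraction and 1×-coverage normalisation, always
  excluding the X from depth scaling so male X monosomy stays visible;
  reference-point (±0.8 kb) and meta-gene (±0.5 kb unscaled + 1 kb
  scaled body) signal matrices; fragment-midpoint (dyad) density for
  positioning analyses.
- **Peak post-processing** — replicate merging (10 bp gap), closed
  ±200 bp TSS assignment, Fisher's exact test for X overrepresentation,
  and deterministic k-means classification (k = 3) of multi-track peak
  signal.
- **FLASH quantification** — exact-overlap pair merging (≥ 30 nt),
  unique-within-Hamming-2 barcode demultiplexing, random-tag PCR
  deduplication (MAPQ > 10), gene-level crosslink counts and MA values.
- **Dosage-sensitivity statistics** — the orthologue-set bootstrap test:
  for a gene set S with knockout log2 fold changes, the observed mean
  log2FC is compared against B = 10,000 random same-size gene samples
  from the expression universe,

  p = (1 + #{null means as or more extreme}) / (B + 1),

  Benjamini–Hochberg-corrected across the sets tested; plus the
  two-clone FDR < 0.05 DE consensus filter, 1:1 orthologue translation,
  HAS-proximal gene sets (≤ 2344 bp), Welch's t-test, H4K16ac gain/loss
  classification and efficiency-corrected qPCR relative quantification.
- **A synthetic-data generator** that plants recoverable ground truth
  for every stage (bound sites with phased nucleosomes, X monosomy,
  PCR-duplicated barcoded libraries, shifted orthologue clusters, qPCR
  plates with known efficiencies), so the whole pipeline is testable
  without any external download.

## Worked example

Run the end-to-end synthetic conservation experiment — plant a −0.5
log2FC shift on the 66 cluster-1 orthologues, leave the other four gene
sets null, and test all five against 10,000 random same-size samples:

```bash
dosage-lens conserve-demo --seed 1 --B 10000 --out report.json
```

which prints:

```
cluster1        n=66    mean log2FC=-0.514      p=9.999e-05     p_adj=0.0005
cluster2        n=269   mean log2FC=+0.012      p=0.9491        p_adj=0.9491
cluster3        n=346   mean log2FC=-0.006      p=0.638         p_adj=0.9491
HAS             n=432   mean log2FC=-0.010      p=0.4831        p_adj=0.9491
HAS_proximal    n=231   mean log2FC=+0.006      p=0.8632        p_adj=0.9491
```

Only the set carrying the planted shift is significant after
Benjamini–Hochberg correction: its observed mean log2FC (−0.514)
recovers the planted −0.5, and the empirical p is at the resolution
floor 1/(B+1) of the bootstrap. The four control sets (the other two
autosomal clusters, genes overlapping a high-affinity site, and genes
within 2344 bp of one) sit near zero with adjusted p ≈ 0.95 — the
coherent-downregulation signature is specific to the bound cluster.

A ChIP-side example from the library:

```python
from dosagelens import *

cfg = SimConfig(seed=1)
genome, genes = make_genome(cfg)
sites, truth = plant_sites(genome, genes, cfg)
chip, inp = simulate_chip_experiment(genome, sites, cfg, sex="male")

small, large = partition_fragments(filter_fragments(chip))
track = normalize_tracks(coverage_track(filter_fragments(inp), genome, 2),
                         None, "one_x")
print(track.mean_per_base(["chrX"]))   # 0.493 — the single male X
```

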