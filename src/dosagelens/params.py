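"""Shared analysis parameters.

Every tunable threshold used by the pipeline lives here, with the value
the analysis was designed around.  The fragment-size boundary separates
sub-nucleosomal protein footprints from nucleosome-scale fragments in
MNase ChIP-seq; the remaining fields are distance windows, quality
cut-offs and resampling sizes used by the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AnalysisParams:
    """Pipeline-wide constants.

    Attributes
    ----------
    footprint_max_len:
        Fragments of this length or shorter (bp) are classed as protein
        footprints; longer fragments as nucleosomal.
    min_mapq:
        ChIP fragments with mapping quality strictly below this are dropped.
    coverage_binsize:
        Bin width (bp) of genome coverage tracks.
    peak_merge_gap:
        Peaks separated by at most this many bp are merged.
    tss_assign_dist:
        Half-width (bp) of the TSS window used to assign peaks to genes.
    tss_peak_dist_mouse:
        TSS window half-width (bp) used for the mouse peak-gene sets.
    ref_point_flank:
        Half-width (bp) of reference-point signal matrices.
    unscaled_flank:
        Unscaled flank (bp) on each side of the TSS in scaled-region
        matrices.
    scaled_body:
        Length (bp) the remainder of the gene body is rescaled to.
    pair_min_overlap_chip / pair_min_overlap_flash:
        Minimum exact read-pair overlap (nt) for merging, per assay.
    max_barcode_hamming:
        Maximum Hamming distance for barcode assignment.
    flash_min_mapq:
        FLASH tags must have mapping quality strictly greater than this.
    de_fdr:
        FDR threshold for calling a gene differentially expressed.
    bootstrap_B:
        Number of resampled null sets in the gene-set bootstrap test.
    has_proximal_max_dist:
        Maximum gene-to-site distance (bp) for the HAS-proximal gene set.
    kmeans_k:
        Number of k-means clusters for autosomal peak classification.
    log2_pseudocount:
        Pseudocount used in log2 ratios.
    matrix_binwidth:
        Column width (bp) of signal matrices (coverage tracks stay at
        ``coverage_binsize``).
    """

    footprint_max_len: int = 140
    min_mapq: int = 10
    coverage_binsize: int = 2
    peak_merge_gap: int = 10
    tss_assign_dist: int = 200
    tss_peak_dist_mouse: int = 1000
    ref_point_flank: int = 800
    unscaled_flank: int = 500
    scaled_body: int = 1000
    pair_min_overlap_chip: int = 10
    pair_min_overlap_flash: int = 30
    max_barcode_hamming: int = 2
    flash_min_mapq: int = 10
    de_fdr: float = 0.05
    bootstrap_B: int = 10_000
    has_proximal_max_dist: int = 2344
    kmeans_k: int = 3
    log2_pseudocount: float = 1.0
    matrix_binwidth: int = 10

    def __post_init__(self) -> None:
        for name in (
            "footprint_max_len", "coverage_binsize", "ref_point_flank",
            "unscaled_flank", "scaled_body", "pair_min_overlap_chip",
            "pair_min_overlap_flash", "bootstrap_B", "kmeans_k",
            "matrix_binwidth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.de_fdr < 1.0:
            raise ValueError("de_fdr must be in (0, 1)")


DEFAULT_PARAMS = AnalysisParams()
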