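"""Peak post-processing: replicate merging, TSS assignment, chromosome
overrepresentation and k-means clustering of multi-track peak signal.

Peak calling itself is upstream; this module consumes interval sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from sklearn.cluster import KMeans

from .coverage_profiles import SignalMatrix
from .genomics_io import GeneAnnotation, GenomeModel, GenomicInterval, merge_intervals
from .params import DEFAULT_PARAMS


@dataclass
class PeakSet:
    """Sorted peak intervals with a source label."""

    intervals: list[GenomicInterval]
    source: str = ""

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def counts_by_chrom(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for iv in self.intervals:
            out[iv.chrom] = out.get(iv.chrom, 0) + 1
        return out


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = factor, columns = X vs autosome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class ClusterResult:
    """Cluster labels (1..k) per row with within-cluster intensity ranks."""

    row_ids: list[str]
    labels: np.ndarray            # cluster label per row, 1-based
    order: np.ndarray             # row indices: cluster-major, intensity-sorted
    cluster_profiles: dict[int, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rank = np.empty(len(self.row_ids), dtype=int)
        rank[self.order] = np.arange(len(self.row_ids))
        return pd.DataFrame(
            {"row_id": self.row_ids, "cluster": self.labels, "sort_rank": rank}
        )


def merge_replicate_peaks(
    peaksets: list[PeakSet], max_gap: int = DEFAULT_PARAMS.peak_merge_gap
) -> PeakSet:
    """Concatenate replicate peak sets, sort and merge within *max_gap* bp."""
    pooled = [iv for ps in peaksets for iv in ps.intervals]
    merged = merge_intervals(pooled, max_gap)
    merged = [
        GenomicInterval(iv.chrom, iv.start, iv.end, id=f"peak_{i}")
        for i, iv in enumerate(merged)
    ]
    source = "+".join(dict.fromkeys(ps.source for ps in peaksets if ps.source))
    return PeakSet(merged, source=source)


def assign_peaks_to_tss(
    peaks: PeakSet,
    annotation: GeneAnnotation,
    dist: int = DEFAULT_PARAMS.tss_assign_dist,
) -> tuple[pd.DataFrame, int]:
    """Assign peaks to genes whose TSS window [TSS-dist, TSS+dist] (closed,
    clipped at the chromosome start) intersects the peak.

    Returns the (gene_id, peak_id) link table and the number of peaks with
    at least one assignment.  Many-to-many links are kept.
    """
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(peaks.intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, iv.id or f"peak_{i}"
        )
    links = []
    assigned_peaks: set[str] = set()
    for r in annotation.df.itertuples():
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        lo = max(0, r.tss - dist)
        hi = r.tss + dist + 1  # closed window -> half-open query
        for hit in tree.overlap(lo, hi):
            links.append({"gene_id": r.gene_id, "peak_id": hit.data})
            assigned_peaks.add(hit.data)
    df = pd.DataFrame(links, columns=["gene_id", "peak_id"])
    return df, len(assigned_peaks)


def genes_with_tss_peak(
    peaks: PeakSet,
    annotation: GeneAnnotation,
    dist: int = DEFAULT_PARAMS.tss_peak_dist_mouse,
) -> set[str]:
    """Genes carrying a peak within *dist* bp of the TSS."""
    table, _ = assign_peaks_to_tss(peaks, annotation, dist)
    return set(table["gene_id"])


def fisher_exact(table: ContingencyTable2x2, alternative: str = "greater") -> float:
    """Fisher's exact test p-value on a 2x2 table.

    Conditions on the margins; p is the hypergeometric tail probability.
    ``two_sided`` sums all tables whose probability does not exceed the
    observed one.  A zero margin means the table carries no information:
    p = 1 with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    r1, c1 = a + b, a + c
    if 0 in (r1, c1, c + d, b + d):
        warnings.warn("degenerate 2x2 table (zero margin): p = 1")
        return 1.0
    rv = hypergeom(n, c1, r1)  # a | margins ~ Hypergeom(N=n, K=a+c, n=a+b)
    if alternative == "greater":
        return float(rv.sf(a - 1))
    if alternative == "less":
        return float(rv.cdf(a))
    if alternative == "two_sided":
        support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
        pmf = rv.pmf(support)
        # tolerance guards against ties lost to floating-point rounding
        return float(min(1.0, pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum()))
    raise ValueError(f"unknown alternative {alternative!r}")


def chromosome_overrepresentation(
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    genome: GenomeModel,
    alternative: str = "greater",
    mode: str = "versus_set",
) -> tuple[ContingencyTable2x2, float]:
    """Test whether X-linked peaks are overrepresented in set A.

    ``versus_set`` (default) contrasts X/autosome counts of A against B;
    ``versus_length`` contrasts A against the expectation from X vs
    autosomal chromosome lengths (expressed as per-kb pseudo-counts).
    """
    if not len(peaks_a) or (mode == "versus_set" and not len(peaks_b)):
        raise ValueError("peak sets must be nonempty")

    def split(ps: PeakSet) -> tuple[int, int]:
        x = sum(iv.chrom == genome.x_chrom for iv in ps.intervals)
        return x, len(ps) - x

    ax, aa = split(peaks_a)
    if mode == "versus_set":
        bx, ba = split(peaks_b)
    elif mode == "versus_length":
        bx = genome.lengths[genome.x_chrom] // 1000
        ba = sum(genome.lengths[c] for c in genome.autosomes) // 1000
    else:
        raise ValueError(f"unknown mode {mode!r}")
    table = ContingencyTable2x2(ax, aa, bx, ba)
    return table, fisher_exact(table, alternative=alternative)


def cluster_peaks(
    matrices: list[SignalMatrix], k: int = DEFAULT_PARAMS.kmeans_k, seed: int = 0
) -> ClusterResult:
    """k-means clustering of peaks on concatenated multi-track signal.

    Each track is standardised to zero mean / unit variance over all its
    cells (NaN cells imputed at the track mean, i.e. 0 after scaling).
    Clusters are relabelled 1..k by descending mean intensity on the first
    track, and rows are sorted within each cluster by descending first-track
    row mean, so "cluster 1" and the heatmap row order are reproducible.
    """
    if not matrices:
        raise ValueError("need at least one signal matrix")
    row_ids = matrices[0].row_ids
    for m in matrices[1:]:
        if m.row_ids != row_ids:
            raise ValueError("matrices must share row ids in the same order")
    if len(row_ids) < k:
        raise ValueError(f"{len(row_ids)} rows < k={k}")

    blocks = []
    for m in matrices:
        mu = np.nanmean(m.values)
        sd = np.nanstd(m.values)
        if sd == 0:
            raise ValueError("constant signal matrix (zero variance)")
        z = (m.values - mu) / sd
        blocks.append(np.nan_to_num(z, nan=0.0))
    features = np.hstack(blocks)

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(features)

    first_means = np.nan_to_num(matrices[0].row_means(), nan=0.0)
    cluster_intensity = {lab: first_means[raw == lab].mean() for lab in range(k)}
    by_intensity = sorted(cluster_intensity, key=cluster_intensity.get, reverse=True)
    relabel = {old: new + 1 for new, old in enumerate(by_intensity)}
    labels = np.array([relabel[lab] for lab in raw])

    order = np.lexsort((-first_means, labels))
    profiles = {
        lab: np.hstack([np.nanmean(m.values[labels == lab], axis=0) for m in matrices])
        for lab in range(1, k + 1)
    }
    return ClusterResult(row_ids=row_ids, labels=labels, order=order,
                         cluster_profiles=profiles)
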