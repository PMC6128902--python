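"""Fragment-size partitioning, binned coverage and meta-profile matrices.

MNase ChIP fragments are split at a size boundary (default 140 bp):
short fragments trace the direct DNA footprint of a bound protein,
longer ones trace flanking or crosslinked nucleosomes.  Coverage tracks
are fixed-bin per-base mean depths with three normalisation modes
(log2 ratio over input, input subtraction, 1x genome coverage), with the
X chromosome excludable from depth scaling so that monosomy of the male
X remains visible.  Signal matrices come in the two standard meta-profile
geometries: a fixed flank around a reference point, and an
unscaled-flank / scaled-gene-body layout from TSS to TES.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomics_io import GenomeModel, GenomicInterval, GeneAnnotation
from .params import DEFAULT_PARAMS

FRAGMENT_COLUMNS = ["chrom", "start", "end", "mapq", "dup_flag"]


@dataclass
class FragmentSet:
    """Mapped fragments (chrom, start, end, mapq, dup_flag) with provenance."""

    df: pd.DataFrame
    sample: str = ""
    antibody: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")
        if len(self.df) and ((self.df["end"] <= self.df["start"]).any()
                             or (self.df["mapq"] < 0).any()):
            raise ValueError("fragments require end > start and mapq >= 0")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def _with(self, df: pd.DataFrame) -> "FragmentSet":
        return FragmentSet(df.reset_index(drop=True), self.sample, self.antibody, self.sex)

    def to_tsv(self, path) -> None:
        self.df[FRAGMENT_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **provenance) -> "FragmentSet":
        return cls(pd.read_csv(path, sep="\t"), **provenance)


@dataclass
class CoverageTrack:
    """Fixed-bin genome signal.

    Bin values are mean per-base depth within the bin (the last bin of a
    chromosome is zero-padded to full width, so bin*binsize sums conserve
    fragment mass exactly).
    """

    genome: GenomeModel
    binsize: int
    data: dict[str, np.ndarray]
    normalization: str = "raw"
    scaling_excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for chrom in self.genome.names:
            expect = -(-self.genome.lengths[chrom] // self.binsize)
            if len(self.data[chrom]) != expect:
                raise ValueError(f"{chrom}: expected {expect} bins")

    def total(self, chroms=None) -> float:
        """Sum of bin value * binsize (== per-base mass) over *chroms*."""
        chroms = self.genome.names if chroms is None else chroms
        return float(sum(self.data[c].sum() * self.binsize for c in chroms))

    def mean_per_base(self, chroms=None) -> float:
        chroms = self.genome.names if chroms is None else chroms
        nbases = sum(self.genome.lengths[c] for c in chroms)
        return self.total(chroms) / nbases

    def per_base(self, chrom: str) -> np.ndarray:
        """Expand bins to a per-base array clipped to the chromosome length."""
        vals = np.repeat(self.data[chrom], self.binsize)
        return vals[: self.genome.lengths[chrom]]


@dataclass
class SignalMatrix:
    """Regions x bins matrix; NaN cells mark out-of-bounds positions."""

    mode: str  # "reference_point" | "scaled_region"
    row_ids: list[str]
    binwidth: int
    values: np.ndarray
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_ids):
            raise ValueError("values must be 2-D with one row per region id")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def mean_profile(self) -> np.ndarray:
        """Column means ignoring masked (NaN) cells."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)

    def row_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mode={self.mode} binwidth={self.binwidth}\n")
            for key, val in sorted(self.geometry.items()):
                fh.write(f"# {key}={val}\n")
            pd.DataFrame(self.values, index=self.row_ids).to_csv(
                fh, sep="\t", header=False, na_rep="nan"
            )


# ---------------------------------------------------------------------------
# fragment-level operations
# ---------------------------------------------------------------------------

def partition_fragments(
    frags: FragmentSet, threshold: int = DEFAULT_PARAMS.footprint_max_len
) -> tuple[FragmentSet, FragmentSet]:
    """Split fragments at the footprint/nucleosome size boundary.

    The boundary is inclusive on the small side: a fragment of exactly
    *threshold* bp is a footprint.
    """
    small_mask = (frags.df["end"] - frags.df["start"]) <= threshold
    return frags._with(frags.df[small_mask]), frags._with(frags.df[~small_mask])


def filter_fragments(
    frags: FragmentSet, min_mapq: int = DEFAULT_PARAMS.min_mapq
) -> FragmentSet:
    """Drop fragments with mapping quality < *min_mapq* and collapse exact
    (chrom, start, end) duplicates to a single representative."""
    kept = frags.df[frags.df["mapq"] >= min_mapq]
    kept = kept.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
    return frags._with(kept)


def _base_depth(frags: FragmentSet, chrom: str, length: int) -> np.ndarray:
    """Per-base fragment depth on one chromosome (fragments clipped)."""
    depth = np.zeros(length + 1)
    sub = frags.df[frags.df["chrom"] == chrom]
    if len(sub):
        starts = np.clip(sub["start"].to_numpy(), 0, length)
        ends = np.clip(sub["end"].to_numpy(), 0, length)
        np.add.at(depth, starts, 1.0)
        np.add.at(depth, ends, -1.0)
    return np.cumsum(depth)[:length]


def coverage_track(
    frags: FragmentSet,
    genome: GenomeModel,
    binsize: int = DEFAULT_PARAMS.coverage_binsize,
) -> CoverageTrack:
    """Raw binned coverage: bin value = mean per-base depth over the bin."""
    bad = ~frags.df["chrom"].isin(genome.names)
    if bad.any():
        raise ValueError(f"fragments on unknown chromosome {frags.df.loc[bad, 'chrom'].iloc[0]!r}")
    for chrom, clen in genome.lengths.items():
        sub = frags.df[frags.df["chrom"] == chrom]
        if len(sub) and (sub["end"].max() > clen or sub["start"].min() < 0):
            raise ValueError(f"fragment beyond bounds of {chrom}")
    data = {}
    for chrom in genome.names:
        clen = genome.lengths[chrom]
        nbins = -(-clen // binsize)
        depth = np.zeros(nbins * binsize)
        depth[:clen] = _base_depth(frags, chrom, clen)
        data[chrom] = depth.reshape(nbins, binsize).mean(axis=1)
    return CoverageTrack(genome=genome, binsize=binsize, data=data, normalization="raw")


def dyad_track(
    frags: FragmentSet,
    genome: GenomeModel,
    binsize: int = DEFAULT_PARAMS.coverage_binsize,
) -> CoverageTrack:
    """Fragment-midpoint (dyad) density per bin, in events per bp.

    For positioning analyses the fragment midpoint is the sharp estimate
    of the protected center (the nucleosome dyad for nucleosome-scale
    fragments, the bound-protein footprint center for small ones), so
    midpoint density localises planted positions far better than base
    coverage, whose top is flat across the span of every fragment.
    """
    data = {}
    for chrom in genome.names:
        clen = genome.lengths[chrom]
        nbins = -(-clen // binsize)
        sub = frags.df[frags.df["chrom"] == chrom]
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        counts = np.bincount(np.clip(mids // binsize, 0, nbins - 1), minlength=nbins)
        data[chrom] = counts / binsize
    return CoverageTrack(genome=genome, binsize=binsize, data=data,
                         normalization="raw")


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize_tracks(
    chip: CoverageTrack,
    control: CoverageTrack | None,
    mode: str,
    pseudocount: float = DEFAULT_PARAMS.log2_pseudocount,
    exclude_scaling: tuple[str, ...] | None = None,
) -> CoverageTrack:
    """Normalise a ChIP track against its control.

    Modes
    -----
    ``log2_ratio``
        log2((chip + pc) / (control + pc)) per bin after equalising both
        tracks to the smaller total depth on non-excluded chromosomes.
    ``subtract``
        depth-equalised chip - control.
    ``one_x``
        chip alone scaled so mean per-base coverage over non-excluded
        chromosomes is exactly 1 (control ignored).

    ``exclude_scaling`` defaults to the genome's X chromosome: scaling on
    autosomes only keeps the X:autosome coverage ratio interpretable
    (0.5 expected for a male input, 1.0 for a female).
    """
    if mode not in ("log2_ratio", "subtract", "one_x"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    excl = (chip.genome.x_chrom,) if exclude_scaling is None else tuple(exclude_scaling)
    scale_chroms = [c for c in chip.genome.names if c not in excl]
    if not scale_chroms:
        raise ValueError("all chromosomes excluded from scaling")

    if mode == "one_x":
        mean = chip.mean_per_base(scale_chroms)
        if mean <= 0:
            raise ValueError("zero total coverage")
        data = {c: chip.data[c] / mean for c in chip.genome.names}
        return CoverageTrack(chip.genome, chip.binsize, data, "one_x", excl)

    if control is None:
        raise ValueError(f"mode {mode!r} requires a control track")
    if control.binsize != chip.binsize or control.genome.names != chip.genome.names:
        raise ValueError("chip and control tracks must share genome and binsize")

    t_chip = chip.total(scale_chroms)
    t_ctrl = control.total(scale_chroms)
    if t_chip <= 0 or t_ctrl <= 0:
        raise ValueError("zero total coverage")
    target = min(t_chip, t_ctrl)
    f_chip, f_ctrl = target / t_chip, target / t_ctrl

    data = {}
    for c in chip.genome.names:
        a = chip.data[c] * f_chip
        b = control.data[c] * f_ctrl
        if mode == "log2_ratio":
            data[c] = np.log2((a + pseudocount) / (b + pseudocount))
        else:
            data[c] = a - b
    return CoverageTrack(chip.genome, chip.binsize, data, mode, excl)


# ---------------------------------------------------------------------------
# signal matrices
# ---------------------------------------------------------------------------

def _window_values(track: CoverageTrack, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Track value at each genomic base position; NaN outside bounds."""
    clen = track.genome.lengths[chrom]
    out = np.full(positions.shape, np.nan)
    ok = (positions >= 0) & (positions < clen)
    bins = track.data[chrom]
    out[ok] = bins[positions[ok] // track.binsize]
    return out


def _pool(per_base: np.ndarray, binwidth: int) -> np.ndarray:
    """Mean-pool a per-base row into matrix bins; all-NaN bins stay NaN."""
    cells = per_base.reshape(-1, binwidth)
    n_ok = (~np.isnan(cells)).sum(axis=1)
    total = np.nansum(cells, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_ok > 0, total / n_ok, np.nan)


def matrix_reference_point(
    track: CoverageTrack,
    regions: list[GenomicInterval],
    flank: int = DEFAULT_PARAMS.ref_point_flank,
    binwidth: int = DEFAULT_PARAMS.matrix_binwidth,
) -> SignalMatrix:
    """Signal in [center-flank, center+flank) around each region center.

    The center is floor((start+end)/2).  Rows of minus-strand regions are
    column-reversed so the matrix reads 5'->3'.  Positions beyond the
    chromosome are NaN-masked.
    """
    if flank % binwidth:
        raise ValueError("flank must be a multiple of the matrix binwidth")
    ncols = 2 * flank // binwidth
    values = np.empty((len(regions), ncols))
    row_ids = []
    for i, region in enumerate(regions):
        center = region.center
        positions = np.arange(center - flank, center + flank)
        row = _pool(_window_values(track, region.chrom, positions), binwidth)
        if region.strand == "-":
            row = row[::-1]
        values[i] = row
        row_ids.append(region.id or f"region_{i}")
    return SignalMatrix(
        mode="reference_point", row_ids=row_ids, binwidth=binwidth,
        values=values, geometry={"flank_bp": flank},
    )


def matrix_scaled_region(
    track: CoverageTrack,
    genes: GeneAnnotation,
    unscaled: int = DEFAULT_PARAMS.unscaled_flank,
    body_bp: int = DEFAULT_PARAMS.scaled_body,
    binwidth: int = DEFAULT_PARAMS.matrix_binwidth,
) -> tuple[SignalMatrix, list[str]]:
    """Meta-gene matrix: [TSS-unscaled, TSS+unscaled) kept at native scale,
    the remaining gene body to the TES linearly resampled to *body_bp*.

    Genes are traversed in their own 5'->3' orientation.  Genes whose body
    is not longer than the unscaled flank are dropped; their ids are
    returned alongside the matrix.
    """
    if (2 * unscaled + body_bp) % binwidth:
        raise ValueError("row width must be a multiple of the matrix binwidth")
    rows, row_ids, dropped = [], [], []
    # virtual gene-oriented offsets from the TSS for every output base
    flank_t = np.arange(-unscaled, unscaled)
    for r in genes.df.itertuples():
        body_len = r.end - r.start
        if body_len <= unscaled:
            dropped.append(r.gene_id)
            continue
        remainder = body_len - unscaled
        body_t = unscaled + (np.arange(body_bp) * remainder) // body_bp
        t = np.concatenate([flank_t, body_t])
        direction = 1 if r.strand == "+" else -1
        positions = r.tss + direction * t
        rows.append(_pool(_window_values(track, r.chrom, positions), binwidth))
        row_ids.append(r.gene_id)
    values = np.array(rows) if rows else np.empty((0, (2 * unscaled + body_bp) // binwidth))
    matrix = SignalMatrix(
        mode="scaled_region", row_ids=row_ids, binwidth=binwidth, values=values,
        geometry={"unscaled_bp": unscaled, "body_bp": body_bp},
    )
    return matrix, dropped


def region_score(track: CoverageTrack, intervals: list[GenomicInterval]) -> pd.Series:
    """Mean track value over each interval (per-base, i.e. bins weighted by
    their overlap with the interval)."""
    scores = {}
    for i, iv in enumerate(intervals):
        per_base = track.per_base(iv.chrom)[iv.start : iv.end]
        scores[iv.id or f"region_{i}"] = float(per_base.mean())
    return pd.Series(scores, dtype=float)
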