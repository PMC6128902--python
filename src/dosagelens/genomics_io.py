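"""Genome model, interval algebra and plain-text format I/O.

All internal coordinates are 0-based half-open (BED convention).  GTF is
1-based closed and converted at the boundary.  The X chromosome is
designated explicitly on the :class:`GenomeModel` because several
normalisation steps must exclude it from depth scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised for malformed input records; carries the offending line number."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names with lengths and an explicit X designation."""

    names: tuple[str, ...]
    lengths: dict[str, int]
    x_chrom: str

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if self.x_chrom not in self.names:
            raise ValueError(f"x_chrom {self.x_chrom!r} not in genome")
        for name in self.names:
            if self.lengths.get(name, 0) <= 0:
                raise ValueError(f"chromosome {name!r} must have positive length")

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n != self.x_chrom)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with optional strand, id and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class GeneAnnotation:
    """Gene-level annotation backed by a DataFrame.

    The TSS is the first transcribed base (``start`` on + genes, ``end-1``
    on - genes: half-open ends are not covered bases), the TES the last.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be '+' or '-'")
        if (df["start"] >= df["end"]).any() or (df["start"] < 0).any():
            raise ValueError("gene intervals must satisfy 0 <= start < end")
        df = df.reset_index(drop=True).copy()
        plus = df["strand"] == "+"
        df["tss"] = np.where(plus, df["start"], df["end"] - 1)
        df["tes"] = np.where(plus, df["end"] - 1, df["start"])
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.df["gene_id"])

    @property
    def gene_ids(self) -> list[str]:
        return self.df["gene_id"].tolist()

    def subset(self, gene_ids: Iterable[str]) -> "GeneAnnotation":
        wanted = set(gene_ids)
        return GeneAnnotation(
            self.df[self.df["gene_id"].isin(wanted)].drop(columns=["tss", "tes"])
        )

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.gene_id)
            for r in self.df.itertuples()
        ]

    def gene(self, gene_id: str) -> GenomicInterval:
        row = self.df.loc[self.df["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, gene_id)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, genome: GenomeModel | None = None) -> list[GenomicInterval]:
    """Read BED3+ into intervals; validates coordinates (and chromosome
    membership when *genome* is given), reporting the 1-based line number
    on failure."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if genome is not None:
                if chrom not in genome.lengths:
                    raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > genome.lengths[chrom]:
                    raise ParseError(f"{path}:{lineno}: interval beyond chromosome end")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.id is not None or iv.score is not None or iv.strand != ".":
                fields += [
                    iv.id if iv.id is not None else ".",
                    f"{iv.score:g}" if iv.score is not None else "0",
                    iv.strand,
                ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> GeneAnnotation:
    """Read gene-level GTF records into a :class:`GeneAnnotation`.

    Coordinates convert from 1-based closed to 0-based half-open, so a
    GTF gene at 1..100 becomes interval [0, 100).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ParseError(f"gene {feat.id!r}: missing or invalid strand")
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            raise ParseError(f"gene record at {feat.seqid}:{feat.start} lacks gene_id")
        rows.append(
            dict(gene_id=gene_ids[0], chrom=feat.seqid,
                 start=feat.start - 1, end=feat.end, strand=feat.strand)
        )
    if not rows:
        raise ParseError(f"{path}: no gene records")
    df = pd.DataFrame(rows)
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene_id")
    return GeneAnnotation(df)


def write_gtf(annotation: GeneAnnotation, path: str | Path, source: str = "dosagelens") -> None:
    """Write gene records as GTF (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        for r in annotation.df.itertuples():
            attrs = f'gene_id "{r.gene_id}";'
            fh.write(
                "\t".join([
                    r.chrom, source, "gene", str(r.start + 1), str(r.end),
                    ".", r.strand, ".", attrs,
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= *max_gap* (bedtools ``merge -d``
    semantics: bookended and overlapping intervals always merge).

    Output is sorted by (chrom, start); idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def interval_point_distance(interval: GenomicInterval, chrom: str, point: int) -> float:
    """Distance (bp) from a point to an interval: 0 inside, +inf on a
    different chromosome, otherwise distance to the nearest covered base."""
    if chrom != interval.chrom:
        return math.inf
    if interval.start <= point < interval.end:
        return 0.0
    return float(min(abs(point - interval.start), abs(point - (interval.end - 1))))


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track, path: str | Path, allow_nan: bool = False) -> None:
    """Write a coverage track as bedGraph, run-length merging equal
    adjacent bins.  NaN bins are an error unless *allow_nan*, which masks
    them as 0."""
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            values = np.asarray(track.data[chrom], dtype=float)
            if np.isnan(values).any():
                if not allow_nan:
                    raise ValueError(f"NaN bins on {chrom}")
                values = np.nan_to_num(values, nan=0.0)
            clen = track.genome.lengths[chrom]
            bs = track.binsize
            # run-length encode
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{s * bs}\t{min(e * bs, clen)}\t{values[s]:.10g}\n"
                )


def read_bedgraph(path: str | Path, genome: GenomeModel, binsize: int):
    """Read a bedGraph written by :func:`write_bedgraph` back into a
    raw-normalisation coverage track.  Record boundaries must align to
    *binsize* (the final record may end at the chromosome end)."""
    from .coverage_profiles import CoverageTrack  # local import avoids a cycle

    data = {
        c: np.zeros(-(-genome.lengths[c] // binsize)) for c in genome.names
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            s, e = int(s), int(e)
            if chrom not in data:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if s % binsize or (e % binsize and e != genome.lengths[chrom]):
                raise ParseError(f"{path}:{lineno}: record not aligned to binsize")
            data[chrom][s // binsize : -(-e // binsize)] = float(v)
    return CoverageTrack(genome=genome, binsize=binsize, data=data, normalization="raw")
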