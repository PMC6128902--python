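"""FLASH (RNA crosslink) read processing.

The custom library layout places a sample barcode followed by a random
tag (UMI) at the start of the merged read; the remainder is the insert.
Processing is: merge read pairs on an exact overlap of at least 30 nt,
demultiplex on barcodes allowing a unique match within Hamming distance
2, keep tags with mapping quality strictly greater than 10, collapse PCR
duplicates on (position key, strand, UMI) and count unique crosslink
events per gene.

Note the two mapping-quality conventions in this pipeline: ChIP
fragments drop quality < 10 (10 kept), FLASH tags keep quality > 10
(10 dropped).  Each stage applies its own rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .genomics_io import GeneAnnotation
from .params import DEFAULT_PARAMS

_VALID_BASES = frozenset("ACGTN")


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: |sequence| != |quality|")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MappedTag:
    """A demultiplexed, located crosslink tag.

    The position key is a gene id in transcriptome mode, or
    (chrom, position, strand) when genomic coordinates are available; the
    duplicate key is always (position key, strand, UMI).
    """

    read_id: str
    gene_id: str | None
    umi: str
    sample: str
    mapq: int
    chrom: str | None = None
    position: int | None = None
    strand: str = "."

    @property
    def position_key(self):
        if self.chrom is not None and self.position is not None:
            return (self.chrom, self.position, self.strand)
        return self.gene_id


@dataclass
class GeneCounts:
    """Unique crosslink events per gene for one sample."""

    sample: str
    counts: pd.Series  # gene_id -> int
    unassigned: int = 0

    def to_tsv(self, path) -> None:
        df = self.counts.rename("count").rename_axis("gene_id").reset_index()
        df.to_csv(path, sep="\t", index=False)


def read_fastq(path) -> list[ReadRecord]:
    return [
        ReadRecord(
            rec.id, str(rec.seq),
            "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# pair merging
# ---------------------------------------------------------------------------

def merge_pairs(
    fwd: ReadRecord,
    rev: ReadRecord,
    min_overlap: int = DEFAULT_PARAMS.pair_min_overlap_flash,
) -> ReadRecord | None:
    """Merge a read pair on the longest exact forward/reverse-complement
    overlap of at least *min_overlap* nt; ``None`` when no overlap
    qualifies.

    The merged sequence has length |fwd| + |rev| - overlap.  In the
    overlap the forward base is kept (reads are error-free by assumption
    upstream; qualities are carried from whichever read contributes the
    base).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    for read in (fwd, rev):
        if not set(read.sequence) <= _VALID_BASES:
            raise ValueError(f"read {read.id}: non-ACGTN characters")
    rc = str(Seq(rev.sequence).reverse_complement())
    rc_qual = rev.quality[::-1]
    max_o = min(len(fwd), len(rc))
    for overlap in range(max_o, min_overlap - 1, -1):
        if fwd.sequence[len(fwd) - overlap:] == rc[:overlap]:
            seq = fwd.sequence + rc[overlap:]
            qual = fwd.quality + rc_qual[overlap:]
            return ReadRecord(fwd.id, seq, qual)
    return None


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class DemuxedRead:
    read: ReadRecord   # barcode and UMI stripped
    sample: str
    umi: str


def demultiplex(
    reads: list[ReadRecord],
    whitelist: dict[str, str],
    umi_len: int,
    max_hamming: int = DEFAULT_PARAMS.max_barcode_hamming,
) -> tuple[list[DemuxedRead], pd.DataFrame]:
    """Assign reads to samples by their leading barcode.

    A read is assigned iff exactly one whitelist barcode lies within
    *max_hamming*; ambiguous or unmatched reads are discarded with a
    reason code.  The barcode and the following *umi_len* random-tag
    bases are stripped; the UMI is retained on the record.

    *whitelist* maps barcode sequence -> sample label.  Returns the
    assigned reads and a discard log (read_id, reason).
    """
    barcodes = list(whitelist)
    if len({len(b) for b in barcodes}) != 1:
        raise ValueError("whitelist barcodes must share one length")
    bc_len = len(barcodes[0])
    assigned: list[DemuxedRead] = []
    discards = []
    for read in reads:
        if len(read) < bc_len + umi_len + 1:
            discards.append({"read_id": read.id, "reason": "too_short"})
            continue
        observed = read.sequence[:bc_len]
        hits = [b for b in barcodes if _hamming(observed, b) <= max_hamming]
        if len(hits) != 1:
            reason = "no_barcode_match" if not hits else "ambiguous_barcode"
            discards.append({"read_id": read.id, "reason": reason})
            continue
        umi = read.sequence[bc_len : bc_len + umi_len]
        trimmed = ReadRecord(
            read.id,
            read.sequence[bc_len + umi_len:],
            read.quality[bc_len + umi_len:],
        )
        assigned.append(DemuxedRead(read=trimmed, sample=whitelist[hits[0]], umi=umi))
    log = pd.DataFrame(discards, columns=["read_id", "reason"])
    return assigned, log


# ---------------------------------------------------------------------------
# locating, deduplication, counting
# ---------------------------------------------------------------------------

def locate_reads(
    demuxed: list[DemuxedRead],
    insert_index: dict[str, str],
    mapq_by_read: dict[str, int] | None = None,
    default_mapq: int = 30,
) -> list[MappedTag]:
    """Transcriptome-mode stand-in for alignment: look the insert up in a
    gene -> insert-sequence index (exact match).  Reads whose insert is
    absent from the index get gene_id None (they fall into the unassigned
    bucket downstream)."""
    by_insert = {seq: gene for gene, seq in insert_index.items()}
    tags = []
    for d in demuxed:
        gene = by_insert.get(d.read.sequence)
        mapq = (mapq_by_read or {}).get(d.read.id, default_mapq)
        tags.append(MappedTag(d.read.id, gene, d.umi, d.sample, mapq))
    return tags


def dedup_tags(
    tags: list[MappedTag], min_mapq: int = DEFAULT_PARAMS.flash_min_mapq
) -> list[MappedTag]:
    """PCR-duplicate removal on the random tags.

    Tags with mapping quality <= *min_mapq* are dropped (strictly greater
    kept).  One representative survives per (position key, strand, UMI);
    idempotent.
    """
    seen = set()
    out = []
    for tag in tags:
        if tag.mapq <= min_mapq:
            continue
        key = (tag.sample, tag.position_key, tag.strand, tag.umi)
        if key in seen:
            continue
        seen.add(key)
        out.append(tag)
    return out


def count_by_gene(tags: list[MappedTag], annotation: GeneAnnotation) -> GeneCounts:
    """Count deduplicated tags per gene.

    Tags carrying a gene id are counted directly; coordinate-bearing tags
    are assigned to the gene whose interval contains the position on the
    matching strand.  Tags matching no gene are tallied as unassigned.
    """
    counts = pd.Series(0, index=pd.Index(annotation.gene_ids, name="gene_id"))
    unassigned = 0
    sample = tags[0].sample if tags else ""
    coord_lookup = None
    for tag in tags:
        gene = tag.gene_id
        if gene is None and tag.chrom is not None:
            if coord_lookup is None:
                coord_lookup = _build_coord_lookup(annotation)
            gene = coord_lookup(tag.chrom, tag.position, tag.strand)
        if gene is None or gene not in counts.index:
            unassigned += 1
        else:
            counts[gene] += 1
    return GeneCounts(sample=sample, counts=counts, unassigned=unassigned)


def _build_coord_lookup(annotation: GeneAnnotation):
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for r in annotation.df.itertuples():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, (r.gene_id, r.strand))

    def lookup(chrom: str, pos: int, strand: str) -> str | None:
        tree = trees.get(chrom)
        if tree is None:
            return None
        for hit in tree.at(pos):
            gene_id, gene_strand = hit.data
            if strand == "." or strand == gene_strand:
                return gene_id
        return None

    return lookup


def ma_values(
    counts_a: GeneCounts, counts_b: GeneCounts, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene MA statistics between two samples:
    M = log2((a+pc)/(b+pc)), A = mean of the two log2 counts."""
    a, b = counts_a.counts.align(counts_b.counts, join="outer", fill_value=0)
    la = np.log2(a.to_numpy(dtype=float) + pseudocount)
    lb = np.log2(b.to_numpy(dtype=float) + pseudocount)
    return pd.DataFrame({"M": la - lb, "A": 0.5 * (la + lb)}, index=a.index)
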