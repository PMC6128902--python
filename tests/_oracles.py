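"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive quantities by the most literal possible
route (per-base loops, full enumeration) so they share no code with the
implementation they check.
"""

from math import comb

import numpy as np


def per_base_signal(track, chrom):
    """Literal per-base expansion of a binned track."""
    clen = track.genome.lengths[chrom]
    out = np.empty(clen)
    for pos in range(clen):
        out[pos] = track.data[chrom][pos // track.binsize]
    return out


def brute_reference_point_row(track, region, flank, binwidth):
    """Per-base resample of one reference-point matrix row."""
    clen = track.genome.lengths[region.chrom]
    base = per_base_signal(track, region.chrom)
    center = (region.start + region.end) // 2
    row = []
    for col_start in range(center - flank, center + flank, binwidth):
        vals = [
            base[p]
            for p in range(col_start, col_start + binwidth)
            if 0 <= p < clen
        ]
        row.append(np.mean(vals) if vals else np.nan)
    row = np.array(row)
    return row[::-1] if region.strand == "-" else row


def brute_scaled_region_row(track, gene_row, unscaled, body_bp, binwidth):
    """Per-base resample of one scaled-region (meta-gene) matrix row."""
    clen = track.genome.lengths[gene_row.chrom]
    base = per_base_signal(track, gene_row.chrom)
    body_len = gene_row.end - gene_row.start
    direction = 1 if gene_row.strand == "+" else -1
    positions = []
    for t in range(-unscaled, unscaled):
        positions.append(gene_row.tss + direction * t)
    remainder = body_len - unscaled
    for j in range(body_bp):
        t = unscaled + (j * remainder) // body_bp
        positions.append(gene_row.tss + direction * t)
    row = []
    for i in range(0, len(positions), binwidth):
        vals = [base[p] for p in positions[i : i + binwidth] if 0 <= p < clen]
        row.append(np.mean(vals) if vals else np.nan)
    return np.array(row)


def fisher_enumeration(a, b, c, d, alternative="greater"):
    """Fisher's exact p by full enumeration of tables with fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {x: comb(r1, x) * comb(n - r1, c1 - x) / denom for x in range(lo, hi + 1)}
    obs = probs[a]
    if alternative == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    if alternative == "less":
        return sum(p for x, p in probs.items() if x <= a)
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-9)))


def bh_step_up(pvals):
    """Literal Benjamini-Hochberg step-up from the textbook definition."""
    m = len(pvals)
    indexed = sorted(enumerate(pvals), key=lambda t: t[1])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx, p = indexed[rank - 1]
        running = min(running, p * m / rank)
        adjusted[idx] = running
    return adjusted
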