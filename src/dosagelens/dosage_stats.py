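"""Statistics for cross-species dosage-sensitivity analysis.

The central question: do the mouse 1:1 orthologues of fly genes bound by
the dosage-compensation machinery respond coherently to knockout of the
nucleating factor?  The test compares the mean knockout log2 fold change
of a candidate orthologue set against a null of equally sized random
gene sets drawn from the expression universe, with Benjamini-Hochberg
correction across the sets tested.  Supporting pieces: the two-clone DE
consensus filter, 1:1 orthologue translation, site-proximal gene-set
construction, Welch's t-test, acetylation gain/loss classification and
efficiency-corrected qPCR relative quantification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_io import GeneAnnotation, GenomicInterval, interval_point_distance
from .params import DEFAULT_PARAMS


@dataclass
class DETable:
    """Per-gene log2FC (knockout vs parental), p-value and FDR for one clone."""

    clone: str
    df: pd.DataFrame  # columns: gene_id, log2fc, pvalue, fdr

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "pvalue", "fdr"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"DE table needs columns {sorted(required)}")
        if ((self.df["fdr"] < 0) | (self.df["fdr"] > 1)).any():
            raise ValueError("FDR must be in [0, 1]")
        if not np.isfinite(self.df["log2fc"]).all():
            raise ValueError("log2FC must be finite")
        self.df = self.df.set_index("gene_id", drop=False)

    def to_tsv(self, path) -> None:
        self.df[["gene_id", "log2fc", "pvalue", "fdr"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, clone: str) -> "DETable":
        return cls(clone, pd.read_csv(path, sep="\t"))


@dataclass
class OrthologyMap:
    """Fly gene -> set of mouse genes; an entry is 1:1 iff the fly gene has
    exactly one partner and that partner has no other fly gene."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        partner_count: dict[str, int] = {}
        for partners in self.mapping.values():
            for m in partners:
                partner_count[m] = partner_count.get(m, 0) + 1
        self._one2one = {
            fly: len(partners) == 1 and partner_count[next(iter(partners))] == 1
            for fly, partners in self.mapping.items()
        }

    def is_one2one(self, fly_gene: str) -> bool:
        return self._one2one.get(fly_gene, False)

    def to_tsv(self, path) -> None:
        rows = [
            {"fly_gene": fly, "mouse_gene": m, "one2one": self.is_one2one(fly)}
            for fly, partners in sorted(self.mapping.items())
            for m in sorted(partners)
        ]
        pd.DataFrame(rows, columns=["fly_gene", "mouse_gene", "one2one"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "OrthologyMap":
        df = pd.read_csv(path, sep="\t")
        mapping: dict[str, set[str]] = {}
        for r in df.itertuples():
            mapping.setdefault(r.fly_gene, set()).add(r.mouse_gene)
        return cls({k: frozenset(v) for k, v in mapping.items()})


@dataclass
class GeneSet:
    label: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class BootstrapResult:
    label: str
    n: int
    observed: float
    null: np.ndarray
    p: float
    alternative: str
    mode: str
    seed: int
    p_adj: float | None = None

    def summary(self) -> dict:
        return {
            "label": self.label, "n": self.n, "observed": self.observed,
            "p": self.p, "p_adj": self.p_adj, "B": len(self.null),
            "alternative": self.alternative, "mode": self.mode, "seed": self.seed,
        }


@dataclass
class QpcrPlate:
    """Ct measurements with primer efficiencies and reference genes.

    ``ct`` maps (gene, sample) -> Ct; ``efficiencies`` maps gene -> E in
    (1, 2]; ``dilution_series`` optionally maps gene -> (dilution, Ct)
    table for efficiency estimation.
    """

    ct: dict[tuple[str, str], float]
    efficiencies: dict[str, float]
    reference_genes: list[str]
    dilution_series: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, e in self.efficiencies.items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency of {gene!r} must be in (1, 2]")


# ---------------------------------------------------------------------------
# DE filtering and set construction
# ---------------------------------------------------------------------------

def filter_de(
    tables: list[DETable],
    alpha: float = DEFAULT_PARAMS.de_fdr,
    require_sign_agreement: bool = True,
) -> pd.DataFrame:
    """Genes differentially expressed in every clone.

    A gene is retained iff FDR < *alpha* in all clones and (by default)
    the log2FC sign agrees across clones.  Returns gene_id with the
    consensus (mean) log2FC.  Clone universes that differ are restricted
    to their intersection with a warning.
    """
    if len(tables) < 2:
        raise ValueError("need at least two clone tables")
    universes = [set(t.df["gene_id"]) for t in tables]
    shared = set.intersection(*universes)
    if any(len(u) != len(shared) for u in universes):
        warnings.warn("clone gene universes differ; using their intersection")
    genes = sorted(shared)
    fc = np.column_stack([t.df.loc[genes, "log2fc"].to_numpy() for t in tables])
    fdr = np.column_stack([t.df.loc[genes, "fdr"].to_numpy() for t in tables])
    keep = (fdr < alpha).all(axis=1)
    if require_sign_agreement:
        signs = np.sign(fc)
        keep &= (signs == signs[:, [0]]).all(axis=1)
    return pd.DataFrame(
        {"gene_id": np.asarray(genes)[keep], "log2fc": fc[keep].mean(axis=1)}
    )


def orthologue_set(fly_set: GeneSet, omap: OrthologyMap) -> tuple[GeneSet, dict]:
    """Translate a fly gene set through 1:1 orthology.

    Only 1:1 entries are translated; the report counts input genes,
    translated genes and dropped genes."""
    translated = set()
    n_one2one = 0
    for fly in fly_set.members:
        if omap.is_one2one(fly):
            n_one2one += 1
            translated.add(next(iter(omap.mapping[fly])))
    report = {
        "n_input": len(fly_set), "n_one2one": n_one2one,
        "n_dropped": len(fly_set) - n_one2one,
    }
    return GeneSet(fly_set.label, frozenset(translated)), report


def _nearest_center_distance(annotation: GeneAnnotation, has_sites) -> pd.Series:
    """Distance from each gene interval to the nearest site center
    (0 = a center inside the gene; inf = no site on the chromosome)."""
    centers: dict[str, list[int]] = {}
    for s in has_sites:
        centers.setdefault(s.chrom, []).append(s.center)
    dist = pd.Series(np.inf, index=pd.Index(annotation.df["gene_id"]))
    for chrom, pts in centers.items():
        c = np.sort(np.asarray(pts))
        sub = annotation.df[annotation.df["chrom"] == chrom]
        if sub.empty:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        i = np.searchsorted(c, s)
        j = np.searchsorted(c, e)
        left = np.where(i > 0, s - c[np.maximum(i - 1, 0)], np.inf)
        right = np.where(i < len(c), c[np.minimum(i, len(c) - 1)] - (e - 1), np.inf)
        d = np.where(j > i, 0.0, np.minimum(left, right))
        dist.loc[sub["gene_id"]] = np.minimum(dist.loc[sub["gene_id"]].to_numpy(), d)
    return dist


def has_proximal_genes(
    annotation: GeneAnnotation,
    has_sites: list[GenomicInterval],
    max_dist: int = DEFAULT_PARAMS.has_proximal_max_dist,
) -> GeneSet:
    """Genes near, but not overlapping, a high-affinity site.

    A gene qualifies iff the distance from its interval to the nearest
    site center is <= *max_dist* (boundary inclusive) and no site center
    falls inside the gene (those genes belong to the direct-overlap set).
    """
    dist = _nearest_center_distance(annotation, has_sites)
    members = dist.index[(dist > 0) & (dist <= max_dist)]
    return GeneSet("HAS_proximal", frozenset(members))


def has_overlapping_genes(
    annotation: GeneAnnotation, has_sites: list[GenomicInterval]
) -> GeneSet:
    """Genes whose interval directly contains a site center."""
    dist = _nearest_center_distance(annotation, has_sites)
    return GeneSet("HAS", frozenset(dist.index[dist == 0]))


# ---------------------------------------------------------------------------
# bootstrap set test
# ---------------------------------------------------------------------------

def bootstrap_set_test(
    gene_set: GeneSet,
    universe_log2fc: pd.Series,
    B: int = DEFAULT_PARAMS.bootstrap_B,
    alternative: str = "two_sided",
    seed: int = 0,
    mode: str = "without_replacement",
    statistic: str = "mean",
) -> BootstrapResult:
    """Empirical test of a gene set's log2FC against random sets.

    The observed statistic (mean log2FC by default, median via
    ``statistic="median"``) is compared with *B* statistics of random
    same-size gene samples from the universe — without replacement by
    default, with replacement in ``mode="with_replacement"``.  The
    empirical p uses the add-one correction
    p = (1 + #{null as or more extreme}) / (B + 1), so it is never 0.
    """
    members = [g for g in gene_set.members if g in universe_log2fc.index]
    n = len(members)
    if n < 2:
        raise ValueError("gene set must have >= 2 members in the universe")
    if B < 1:
        raise ValueError("B must be >= 1")
    values = universe_log2fc.to_numpy(dtype=float)
    N = len(values)
    if mode == "without_replacement" and n > N:
        raise ValueError("set larger than universe in without-replacement mode")
    stat = np.mean if statistic == "mean" else np.median
    observed = float(stat(universe_log2fc.loc[members].to_numpy()))

    rng = np.random.default_rng(seed)
    null = np.empty(B)
    chunk = max(1, min(B, int(4e6 // max(N, 1)) or 1))
    done = 0
    while done < B:
        m = min(chunk, B - done)
        if mode == "with_replacement":
            idx = rng.integers(0, N, size=(m, n))
        elif mode == "without_replacement":
            # m independent size-n draws without replacement via random keys
            keys = rng.random((m, N))
            idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        sampled = values[idx]
        null[done : done + m] = (
            sampled.mean(axis=1) if statistic == "mean" else np.median(sampled, axis=1)
        )
        done += m

    if alternative == "less":
        extreme = int((null <= observed).sum())
    elif alternative == "greater":
        extreme = int((null >= observed).sum())
    elif alternative == "two_sided":
        center = float(np.mean(null))
        extreme = int((np.abs(null - center) >= abs(observed - center)).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + extreme) / (B + 1)
    return BootstrapResult(
        label=gene_set.label, n=n, observed=observed, null=null, p=p,
        alternative=alternative, mode=mode, seed=seed,
    )


def conservation_test(
    sets: list[GeneSet],
    universe_log2fc: pd.Series,
    B: int = DEFAULT_PARAMS.bootstrap_B,
    alternative: str = "less",
    seed: int = 0,
    mode: str = "without_replacement",
) -> list[BootstrapResult]:
    """Run the bootstrap set test on several gene sets and BH-adjust the
    p-values across them.  The default alternative "less" tests coherent
    downregulation on knockout."""
    results = [
        bootstrap_set_test(
            s, universe_log2fc, B=B, alternative=alternative,
            seed=seed + i, mode=mode,
        )
        for i, s in enumerate(sets)
    ]
    adjusted = bh_adjust(np.array([r.p for r in results]))
    for r, q in zip(results, adjusted):
        r.p_adj = float(q)
    return results


def write_bootstrap_report(results: list[BootstrapResult], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.summary() for r in results], fh, indent=2)


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def welch_t_test(a, b, alternative: str = "two_sided") -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        df = float(na + nb - 2)
        diff = a.mean() - b.mean()
        if diff == 0:
            return 0.0, df, 1.0 if alternative == "two_sided" else 0.5
        t = np.inf if diff > 0 else -np.inf
        if alternative == "two_sided":
            return float(t), df, 0.0
        hit = (alternative == "greater") == (diff > 0)
        return float(t), df, 0.0 if hit else 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if alternative == "two_sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), float(df), float(p)


def one_tailed_t_test(a, b, alternative: str = "greater") -> float:
    """One-tailed Welch test p-value (qPCR group comparisons)."""
    _, _, p = welch_t_test(a, b, alternative=alternative)
    return p


# ---------------------------------------------------------------------------
# acetylation gain/loss classification
# ---------------------------------------------------------------------------

def classify_h4k16(
    score_wt: pd.Series, score_mut: pd.Series, de_log2fc: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Classify each gene's acetylation change between genotypes.

    A gene below the wt = mut diagonal (mut < wt) loses the mark, above
    gains it; exact ties are "unchanged".  Concordance is the fraction of
    DE genes whose expression change matches the mark change
    (down <-> loss, up <-> gain); genes missing a paired score are
    skipped with a warning.
    """
    genes = score_wt.index.intersection(score_mut.index).intersection(de_log2fc.index)
    skipped = len(de_log2fc.index.union(score_wt.index).union(score_mut.index)) - len(genes)
    if skipped:
        warnings.warn(f"{skipped} unpaired genes skipped")
    wt = score_wt.loc[genes]
    mut = score_mut.loc[genes]
    label = np.where(mut < wt, "loss", np.where(mut > wt, "gain", "unchanged"))
    fc = de_log2fc.loc[genes]
    concordant = ((fc < 0) & (label == "loss")) | ((fc > 0) & (label == "gain"))
    relevant = fc != 0
    concordance = float(concordant[relevant].mean()) if relevant.any() else float("nan")
    table = pd.DataFrame(
        {"score_wt": wt, "score_mut": mut, "log2fc": fc, "label": label}, index=genes
    )
    return table, concordance


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def qpcr_efficiency(dilution_series: pd.DataFrame) -> float:
    """Amplification efficiency from a serial dilution: least-squares slope
    of Ct against log10(dilution), E = 10^(-1/slope).

    *dilution_series* needs columns ``dilution`` (relative template
    amount, e.g. 1, 0.1, 0.01) and ``ct``.
    """
    if len(dilution_series) < 3:
        raise ValueError("need >= 3 dilution points")
    x = np.log10(dilution_series["dilution"].to_numpy(dtype=float))
    y = dilution_series["ct"].to_numpy(dtype=float)
    slope, _ = np.polyfit(x, y, 1)
    if slope >= 0:
        warnings.warn("non-negative Ct-vs-dilution slope: check the series")
    order = np.argsort(-x)  # decreasing template -> Ct should increase
    if np.any(np.diff(y[order]) < -0.5):
        warnings.warn("non-monotone Ct versus dilution beyond noise tolerance")
    return float(10 ** (-1 / slope))


def qpcr_relative(plate: QpcrPlate, target: str, sample: str) -> float:
    """Expression of *target* relative to the geometric mean of the
    reference genes, with per-primer efficiency correction:
    Q_g = E_g^(-Ct_g), result = Q_target / geomean(Q_ref)."""

    def quantity(gene: str) -> float:
        key = (gene, sample)
        if key not in plate.ct:
            raise KeyError(f"missing Ct for {gene!r} in sample {sample!r}")
        return plate.efficiencies[gene] ** (-plate.ct[key])

    q_target = quantity(target)
    q_refs = np.array([quantity(g) for g in plate.reference_genes])
    return float(q_target / stats.gmean(q_refs))
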