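"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design at desk scale: a small genome
with one X chromosome and a configurable number of autosomes; X-linked
high-affinity sites (HAS) and three classes of autosomal promoter sites
bound by the dosage-compensation factor; MNase ChIP fragments where
bound sites emit short protected footprints flanked by phased
nucleosome-scale fragments over a uniform background; male X monosomy
visible in input coverage; FLASH libraries with sample barcodes, random
tags and PCR duplication; two-clone knockout DE tables with a planted
negative shift on one orthologue cluster; and qPCR plates with known
amplification efficiencies.

Every generator is a pure function of (config, seed): a shared seed is
split into named substreams per component, so regenerating one data type
never perturbs another.  Truth records carry the planted parameters so
downstream recovery can be tested without re-deriving them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .coverage_profiles import FragmentSet
from .dosage_stats import DETable, OrthologyMap, QpcrPlate, bh_adjust
from .flash_quant import ReadRecord
from .genomics_io import GeneAnnotation, GenomeModel, GenomicInterval
from .peak_analysis import PeakSet

_BASES = np.array(list("ACGT"))

# substream indices: one fixed lane per component so streams never collide
_COMPONENTS = {
    "genome": 0, "sites": 1, "chip": 2, "flash": 3,
    "de": 4, "qpcr": 5, "orthology": 6,
}


def component_rng(seed: int, component: str, *extra: int) -> np.random.Generator:
    """Named substream of the global seed for one generator component."""
    return np.random.default_rng([seed, _COMPONENTS[component], *extra])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Fragment-length defaults keep the planted classes on the 140 bp
    partition boundary by construction: footprints are truncated normal
    on [40, 140] (mean 90, sd 15), nucleosomal fragments truncated normal
    on [141, 250] (mean 165, sd 12).  Flanking nucleosomes sit at
    +-200 bp of the site center.  Background is uniform per chromosome
    copy, so the male X (one copy) has half the female input coverage.
    """

    n_autosomes: int = 2
    chrom_length_bp: int = 300_000
    n_genes_per_chrom: int = 60
    min_gene_len: int = 1500
    max_gene_len: int = 2500
    min_intergenic_bp: int = 3000
    n_has: int = 30
    has_genic_frac: float = 0.6
    n_auto_sites_per_cluster: tuple[int, int, int] = (12, 10, 8)
    site_halfwidth: int = 100
    footprint_len_mean: float = 90.0
    footprint_len_sd: float = 15.0
    nucleosomal_len_mean: float = 165.0
    nucleosomal_len_sd: float = 12.0
    phased_offsets_bp: tuple[int, ...] = (-200, 200)
    background_rate: float = 0.01       # fragments per bp per chromosome copy
    site_emission_rate: float = 200.0   # footprint fragments per bound site
    low_mapq_frac: float = 0.05
    dup_frac: float = 0.05
    male_x_ploidy: int = 1
    female_x_ploidy: int = 2
    flash_barcodes: tuple[str, ...] = ("AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT")
    umi_len: int = 7
    insert_len: int = 30
    flash_read_len: int = 40
    flash_depth: float = 1.0            # molecules per unit enrichment rate
    pcr_dup_mean: float = 3.0
    de_effect_cluster1: float = -0.5
    de_noise_sd: float = 0.3
    one2one_frac: float = 0.8
    qpcr_sigma_ct: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chrom_length_bp, self.n_genes_per_chrom, self.min_gene_len) <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.footprint_len_mean > 140 or self.nucleosomal_len_mean <= 140:
            raise ValueError(
                "footprint mean must be <= 140 bp and nucleosomal mean > 140 bp "
                "so planted classes land on the size partition"
            )
        if len({len(b) for b in self.flash_barcodes}) != 1:
            raise ValueError("barcodes must share one length")
        for i, x in enumerate(self.flash_barcodes):
            for y in self.flash_barcodes[i + 1:]:
                if sum(a != b for a, b in zip(x, y)) < 5:
                    raise ValueError(
                        f"barcodes {x}/{y} closer than Hamming 5: "
                        "distance-2 demultiplexing would be ambiguous"
                    )
        if self.pcr_dup_mean < 0 or self.background_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class TruthRecord:
    """Planted ground truth accompanying one generated dataset."""

    sites: pd.DataFrame | None = None        # site_id, class, chrom, start, end, gene_id
    gene_effects: dict[str, float] = field(default_factory=dict)
    molecule_counts: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        if self.sites is not None:
            self.sites.to_csv(path, sep="\t", index=False)


class SizingError(ValueError):
    """Requested annotation does not fit on the chromosomes."""


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def make_genome(cfg: SimConfig, prefix: str = "fly") -> tuple[GenomeModel, GeneAnnotation]:
    """A genome of one X plus ``cfg.n_autosomes`` autosomes with
    non-overlapping genes of body length >= ``cfg.min_gene_len``.

    Genes are laid out one per equal-width slot with at least
    ``cfg.min_intergenic_bp`` between neighbours, so site planting can
    reason about neighbour distances.  Deterministic given the seed.
    """
    names = ["chrX"] + [f"chr{i + 2}" for i in range(cfg.n_autosomes)]
    lengths = {c: cfg.chrom_length_bp for c in names}
    slot = cfg.chrom_length_bp // cfg.n_genes_per_chrom
    usable = slot - cfg.min_intergenic_bp
    if usable < cfg.min_gene_len:
        raise SizingError(
            f"chromosome of {cfg.chrom_length_bp} bp cannot host "
            f"{cfg.n_genes_per_chrom} genes of >= {cfg.min_gene_len} bp "
            f"with {cfg.min_intergenic_bp} bp gaps"
        )
    rng = component_rng(cfg.seed, "genome", 0 if prefix == "fly" else 1)
    rows = []
    max_len = min(cfg.max_gene_len, usable)
    for chrom in names:
        gene_lens = rng.integers(cfg.min_gene_len, max_len + 1, cfg.n_genes_per_chrom)
        offsets = rng.integers(0, usable - gene_lens + 1)
        starts = (np.arange(cfg.n_genes_per_chrom) * slot
                  + cfg.min_intergenic_bp // 2 + offsets)
        strands = rng.choice(["+", "-"], cfg.n_genes_per_chrom)
        for i in range(cfg.n_genes_per_chrom):
            rows.append(dict(
                gene_id=f"{prefix}_{chrom}_g{i:04d}", chrom=chrom,
                start=int(starts[i]), end=int(starts[i] + gene_lens[i]),
                strand=str(strands[i]),
            ))
    genome = GenomeModel(names=tuple(names), lengths=lengths, x_chrom="chrX")
    return genome, GeneAnnotation(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------

def plant_sites(
    genome: GenomeModel,
    annotation: GeneAnnotation,
    cfg: SimConfig,
    n_has_genic: int | None = None,
    n_has_proximal: int | None = None,
) -> tuple[dict[str, list[GenomicInterval]], TruthRecord]:
    """Plant HAS on the X and cluster-labelled sites at autosomal promoters.

    HAS come in two placements: inside a gene body (the direct-overlap
    gene set) and intergenic within the proximity window of one gene
    (the HAS-proximal set); gap sizing guarantees no other gene falls in
    the window.  Cluster-1/2/3 sites are centered within 200 bp of
    distinct autosomal TSSs so the assignment stage can recover the
    planted gene links exactly.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    if n_has_genic is None:
        n_has_genic = round(cfg.n_has * cfg.has_genic_frac)
    if n_has_proximal is None:
        n_has_proximal = cfg.n_has - n_has_genic
    rng = component_rng(cfg.seed, "sites")
    df = annotation.df
    x_genes = df[df["chrom"] == genome.x_chrom]
    auto_genes = df[df["chrom"] != genome.x_chrom]
    n_clusters = sum(cfg.n_auto_sites_per_cluster)
    if n_has_genic + n_has_proximal > len(x_genes):
        raise ValueError("more HAS requested than X-linked genes")
    if n_clusters > len(auto_genes):
        raise ValueError("more autosomal sites requested than autosomal genes")
    # proximal placement must keep the neighbouring gene outside the window
    prox_max = cfg.min_intergenic_bp // 2 - cfg.site_halfwidth - 1
    prox_hi = min(2344, prox_max)
    if n_has_proximal and prox_hi < 50:
        raise ValueError("intergenic gaps too small for proximal HAS placement")

    hw = cfg.site_halfwidth
    records, sites = [], {"HAS": [], "cluster1": [], "cluster2": [], "cluster3": []}

    x_pick = rng.permutation(x_genes.index.to_numpy())
    for j, idx in enumerate(x_pick[:n_has_genic]):
        g = df.loc[idx]
        center = (g.start + g.end) // 2
        iv = GenomicInterval(g.chrom, center - hw, center + hw, id=f"HAS_{j:04d}")
        sites["HAS"].append(iv)
        records.append(dict(site_id=iv.id, cls="HAS", chrom=iv.chrom,
                            start=iv.start, end=iv.end, gene_id=g.gene_id,
                            placement="genic"))
    for j, idx in enumerate(x_pick[n_has_genic : n_has_genic + n_has_proximal]):
        g = df.loc[idx]
        d = int(rng.integers(50, prox_hi + 1))
        center = g.end - 1 + d  # distance d downstream of the last gene base
        iv = GenomicInterval(g.chrom, center - hw, center + hw,
                             id=f"HAS_{n_has_genic + j:04d}")
        sites["HAS"].append(iv)
        records.append(dict(site_id=iv.id, cls="HAS", chrom=iv.chrom,
                            start=iv.start, end=iv.end, gene_id=g.gene_id,
                            placement="proximal"))

    auto_pick = rng.permutation(auto_genes.index.to_numpy())
    offset = 0
    for ci, n_sites in enumerate(cfg.n_auto_sites_per_cluster, start=1):
        for j, idx in enumerate(auto_pick[offset : offset + n_sites]):
            g = df.loc[idx]
            center = int(g.tss + rng.integers(-100, 101))
            iv = GenomicInterval(g.chrom, max(0, center - hw), center + hw,
                                 id=f"c{ci}_{j:04d}")
            sites[f"cluster{ci}"].append(iv)
            records.append(dict(site_id=iv.id, cls=f"cluster{ci}", chrom=iv.chrom,
                                start=iv.start, end=iv.end, gene_id=g.gene_id,
                                placement="promoter"))
        offset += n_sites

    truth = TruthRecord(sites=pd.DataFrame(
        records, columns=["site_id", "cls", "chrom", "start", "end",
                          "gene_id", "placement"]))
    return sites, truth


# ---------------------------------------------------------------------------
# ChIP fragment simulation
# ---------------------------------------------------------------------------

_ANTIBODY_TARGETS = {
    "MSL2tg": ("HAS", "cluster1", "cluster2", "cluster3"),
    "MLE": ("HAS",),
    "untagged": (),
}


def _truncnorm_lengths(rng, n, mean, sd, lo, hi) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(draws).astype(int), int(np.ceil(lo)), int(hi))


def simulate_chip_experiment(
    genome: GenomeModel,
    sites: dict[str, list[GenomicInterval]],
    cfg: SimConfig,
    sex: str = "male",
    antibody: str = "MSL2tg",
) -> tuple[FragmentSet, FragmentSet]:
    """Simulate one MNase ChIP experiment and its matched input.

    Each site bound by the chosen antibody emits footprint-length
    fragments centered on the site plus nucleosome-length fragments at
    the phased flanking offsets; everywhere else both libraries see
    uniform background proportional to chromosome copy number (the male
    X carries one copy).  A configurable fraction of fragments gets a
    sub-threshold mapping quality, and exact duplicates are injected so
    the filtering stage has work to do.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    if antibody not in _ANTIBODY_TARGETS:
        raise ValueError(f"unknown antibody {antibody!r}")
    x_ploidy = cfg.male_x_ploidy if sex == "male" else cfg.female_x_ploidy
    rng = component_rng(cfg.seed, "chip", {"male": 0, "female": 1}[sex],
                        list(_ANTIBODY_TARGETS).index(antibody))

    def background() -> pd.DataFrame:
        frames = []
        for chrom in genome.names:
            clen = genome.lengths[chrom]
            ploidy = x_ploidy if chrom == genome.x_chrom else 2
            n = rng.poisson(cfg.background_rate * clen * ploidy)
            lengths = rng.integers(60, 251, n)
            starts = rng.integers(0, np.maximum(clen - lengths, 1))
            frames.append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + lengths}))
        return pd.concat(frames, ignore_index=True)

    def site_fragments() -> pd.DataFrame:
        frames = []
        for cls in _ANTIBODY_TARGETS[antibody]:
            for site in sites.get(cls, []):
                clen = genome.lengths[site.chrom]
                n_fp = rng.poisson(cfg.site_emission_rate)
                fp_len = _truncnorm_lengths(rng, n_fp, cfg.footprint_len_mean,
                                            cfg.footprint_len_sd, 40, 140)
                fp_center = site.center + np.rint(rng.normal(0, 10, n_fp)).astype(int)
                parts = [(fp_center, fp_len)]
                for off in cfg.phased_offsets_bp:
                    n_nu = rng.poisson(cfg.site_emission_rate / 2)
                    nu_len = _truncnorm_lengths(rng, n_nu, cfg.nucleosomal_len_mean,
                                                cfg.nucleosomal_len_sd, 141, 250)
                    nu_center = (site.center + off
                                 + np.rint(rng.normal(0, 10, n_nu)).astype(int))
                    parts.append((nu_center, nu_len))
                for centers, lens in parts:
                    starts = np.clip(centers - lens // 2, 0, None)
                    starts = np.minimum(starts, clen - lens)
                    frames.append(pd.DataFrame(
                        {"chrom": site.chrom, "start": starts, "end": starts + lens}))
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(frames, ignore_index=True)

    def finalize(df: pd.DataFrame, sample: str) -> FragmentSet:
        n = len(df)
        mapq = np.where(rng.random(n) < cfg.low_mapq_frac, 5, 30)
        df = df.assign(mapq=mapq, dup_flag=0)
        dup = df.sample(frac=cfg.dup_frac, random_state=int(rng.integers(2**31)))
        dup = dup.assign(dup_flag=1)
        out = pd.concat([df, dup], ignore_index=True)
        return FragmentSet(out, sample=sample, antibody=antibody, sex=sex)

    chip = finalize(pd.concat([background(), site_fragments()], ignore_index=True),
                    f"{antibody}_{sex}_chip")
    inp = finalize(background(), f"{antibody}_{sex}_input")
    return chip, inp


# ---------------------------------------------------------------------------
# FLASH library simulation
# ---------------------------------------------------------------------------

def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, length))


def simulate_flash_library(
    annotation: GeneAnnotation,
    enrichment_map: dict[str, float],
    cfg: SimConfig,
    sample: str = "sample1",
    barcode_index: int = 0,
) -> tuple[list[ReadRecord], list[ReadRecord], dict[str, str], TruthRecord]:
    """Simulate a FLASH library as overlapping read pairs.

    Each crosslinked molecule yields a template
    ``barcode + random tag + gene insert``; molecule counts per gene are
    Poisson in the enrichment rate, random tags are drawn without
    replacement within a gene (error-free libraries then round-trip
    exactly through deduplication), and every molecule is sequenced
    1 + Poisson(pcr_dup_mean) times.  Returns forward reads, reverse
    reads, the gene -> insert index standing in for an aligner, and the
    truth with unique molecule counts.
    """
    unknown = [g for g in enrichment_map if g not in annotation]
    if unknown:
        raise ValueError(f"enrichment for unknown genes: {unknown[:3]}")
    rng = component_rng(cfg.seed, "flash", barcode_index)
    barcode = cfg.flash_barcodes[barcode_index]
    umi_space = 4 ** cfg.umi_len

    insert_index: dict[str, str] = {}
    seen_inserts: set[str] = set()
    for gene in annotation.gene_ids:
        seq = _random_seq(rng, cfg.insert_len)
        while seq in seen_inserts:
            seq = _random_seq(rng, cfg.insert_len)
        insert_index[gene] = seq
        seen_inserts.add(seq)

    fwd, rev, counts = [], [], {}
    read_len = cfg.flash_read_len
    for gene in annotation.gene_ids:
        rate = enrichment_map.get(gene, 0.0)
        n_mol = rng.poisson(rate * cfg.flash_depth) if rate > 0 else 0
        if n_mol == 0:
            counts[gene] = 0
            continue
        n_mol = min(n_mol, umi_space)
        counts[gene] = n_mol
        umi_codes = rng.choice(umi_space, size=n_mol, replace=False)
        for m, code in enumerate(umi_codes):
            umi = "".join(_BASES[(code // 4**k) % 4] for k in range(cfg.umi_len))
            template = barcode + umi + insert_index[gene]
            copies = 1 + rng.poisson(cfg.pcr_dup_mean)
            for c in range(copies):
                rid = f"{sample}_{gene}_m{m}_c{c}"
                f_seq = template[:read_len]
                r_tmpl = template[-read_len:]
                r_seq = r_tmpl.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                fwd.append(ReadRecord(rid, f_seq, "I" * len(f_seq)))
                rev.append(ReadRecord(rid, r_seq, "I" * len(r_seq)))
    truth = TruthRecord(molecule_counts=counts)
    return fwd, rev, insert_index, truth


# ---------------------------------------------------------------------------
# DE tables, orthology, qPCR
# ---------------------------------------------------------------------------

def simulate_de_tables(
    annotation: GeneAnnotation,
    planted_shifts: dict[str, float],
    cfg: SimConfig,
    clones: tuple[str, str] = ("A2", "D12"),
) -> tuple[DETable, DETable, TruthRecord]:
    """Two-clone knockout DE tables with planted per-gene shifts.

    log2FC = shift + Normal(0, de_noise_sd) independently per clone;
    p-values come from a one-sample z-model at the known noise sd and are
    BH-adjusted within each clone to give the FDR column, so strongly
    shifted genes pass 0.05 and null genes pass at about the nominal
    false rate.
    """
    unknown = [g for g in planted_shifts if g not in annotation]
    if unknown:
        raise ValueError(f"planted shift for unknown genes: {unknown[:3]}")
    genes = annotation.gene_ids
    shift = np.array([planted_shifts.get(g, 0.0) for g in genes])
    tables = []
    for ci, clone in enumerate(clones):
        rng = component_rng(cfg.seed, "de", ci)
        log2fc = shift + rng.normal(0, cfg.de_noise_sd, len(genes))
        z = log2fc / cfg.de_noise_sd
        pvals = 2 * stats.norm.sf(np.abs(z))
        tables.append(DETable(clone, pd.DataFrame({
            "gene_id": genes, "log2fc": log2fc,
            "pvalue": pvals, "fdr": bh_adjust(pvals),
        })))
    truth = TruthRecord(gene_effects={g: s for g, s in zip(genes, shift) if s != 0})
    return tables[0], tables[1], truth


def make_orthology(
    annotation_fly: GeneAnnotation,
    annotation_mouse: GeneAnnotation,
    cfg: SimConfig,
    one2one_frac: float | None = None,
) -> OrthologyMap:
    """Synthetic orthology: a deterministic rounded fraction of fly genes
    get exactly one mouse partner; the remainder alternate between no
    partner and two partners."""
    if not len(annotation_fly) or not len(annotation_mouse):
        raise ValueError("both annotations must be nonempty")
    frac = cfg.one2one_frac if one2one_frac is None else one2one_frac
    fly = annotation_fly.gene_ids
    mouse = annotation_mouse.gene_ids
    n11 = round(frac * len(fly))
    rng = component_rng(cfg.seed, "orthology")
    mouse_pool = list(rng.permutation(mouse))
    mapping: dict[str, frozenset[str]] = {}
    for fly_gene in fly[:n11]:
        mapping[fly_gene] = frozenset([mouse_pool.pop()])
    rest = fly[n11:]
    for i, fly_gene in enumerate(rest):
        if i % 2 == 0 or len(mouse_pool) < 2:
            mapping[fly_gene] = frozenset()
        else:
            mapping[fly_gene] = frozenset([mouse_pool.pop(), mouse_pool.pop()])
    return OrthologyMap(mapping)


def simulate_qpcr_plate(
    genes: list[str],
    true_rel_levels: dict[str, dict[str, float]],
    efficiencies: dict[str, float],
    cfg: SimConfig,
    reference_genes: list[str] = ("RpL32", "Pfk", "U6"),
    base_ct: float = 20.0,
    n_dilutions: int = 4,
    dilution_step: float = 10.0,
) -> QpcrPlate:
    """qPCR plate whose Ct values encode known relative levels.

    *true_rel_levels* maps sample -> gene -> level relative to the
    geometric mean of the reference genes (references are level 1).  Ct
    is -log_E(level) + base plus Normal(0, qpcr_sigma_ct) noise; a serial
    dilution series (fold *dilution_step*) is included per primer for
    efficiency estimation.
    """
    for gene, e in efficiencies.items():
        if e <= 1.0:
            raise ValueError(f"efficiency of {gene!r} must be > 1")
    rng = component_rng(cfg.seed, "qpcr")
    ct: dict[tuple[str, str], float] = {}
    all_genes = list(dict.fromkeys(list(genes) + list(reference_genes)))
    for sample, levels in true_rel_levels.items():
        for gene in all_genes:
            level = levels.get(gene, 1.0)
            e = efficiencies[gene]
            ct[(gene, sample)] = (base_ct - np.log(level) / np.log(e)
                                  + rng.normal(0, cfg.qpcr_sigma_ct))
    series = {}
    for gene in all_genes:
        e = efficiencies[gene]
        dil = dilution_step ** -np.arange(n_dilutions)
        cts = (base_ct - np.log(dil) / np.log(e)
               + rng.normal(0, cfg.qpcr_sigma_ct, n_dilutions))
        series[gene] = pd.DataFrame({"dilution": dil, "ct": cts})
    return QpcrPlate(ct=ct, efficiencies=dict(efficiencies),
                     reference_genes=list(reference_genes),
                     dilution_series=series)


# ---------------------------------------------------------------------------
# end-to-end conservation scenario
# ---------------------------------------------------------------------------

CONSERVATION_CONFIG = SimConfig(
    n_autosomes=2,
    chrom_length_bp=5_600_000,
    n_genes_per_chrom=700,
    min_intergenic_bp=6000,
    max_gene_len=2000,
    n_has=663,
    n_auto_sites_per_cluster=(66, 269, 346),
    one2one_frac=1.0,
)
# Gene-set sizes mirror the published orthologue clusters (66/269/346
# bound-gene clusters, 432 HAS-overlapping and 231 HAS-proximal genes);
# only cluster 1 carries a planted expression shift.
CONSERVATION_HAS_GENIC = 432
CONSERVATION_HAS_PROXIMAL = 231


def simulate_conservation_scenario(seed: int, cfg: SimConfig | None = None) -> dict:
    """Build the full cross-species experiment with planted truth.

    Fly side: genome, planted HAS and autosomal cluster sites.  Mouse
    side: an expression universe, 1:1 orthology and two-clone DE tables
    in which the cluster-1 orthologues carry the planted downshift.
    Returns the pieces the conservation test consumes, plus the truth.
    """
    from .dosage_stats import GeneSet, has_overlapping_genes, has_proximal_genes, orthologue_set
    from .peak_analysis import PeakSet, assign_peaks_to_tss

    cfg = replace(cfg or CONSERVATION_CONFIG, seed=seed)
    fly_genome, fly_genes = make_genome(cfg, prefix="fly")
    sites, site_truth = plant_sites(
        fly_genome, fly_genes, cfg,
        n_has_genic=min(CONSERVATION_HAS_GENIC, cfg.n_has),
        n_has_proximal=min(CONSERVATION_HAS_PROXIMAL,
                           max(cfg.n_has - CONSERVATION_HAS_GENIC, 0)),
    )
    mouse_cfg = replace(cfg, n_autosomes=2, chrom_length_bp=8_000_000,
                        n_genes_per_chrom=1000, min_intergenic_bp=6000)
    mouse_genome, mouse_genes = make_genome(mouse_cfg, prefix="mouse")
    omap = make_orthology(fly_genes, mouse_genes, cfg, one2one_frac=cfg.one2one_frac)

    # fly gene sets recovered through the assignment/overlap machinery
    fly_sets = []
    for ci in (1, 2, 3):
        peaks = PeakSet(sites[f"cluster{ci}"], source=f"cluster{ci}")
        links, _ = assign_peaks_to_tss(peaks, fly_genes)
        fly_sets.append(GeneSet(f"cluster{ci}", frozenset(links["gene_id"])))
    fly_sets.append(GeneSet("HAS", has_overlapping_genes(fly_genes, sites["HAS"]).members))
    fly_sets.append(GeneSet("HAS_proximal",
                            has_proximal_genes(fly_genes, sites["HAS"]).members))

    mouse_sets, reports = [], {}
    for s in fly_sets:
        translated, report = orthologue_set(s, omap)
        mouse_sets.append(translated)
        reports[s.label] = report

    cluster1_mouse = next(s for s in mouse_sets if s.label == "cluster1")
    shifts = {g: cfg.de_effect_cluster1 for g in cluster1_mouse.members}
    de_a, de_b, de_truth = simulate_de_tables(mouse_genes, shifts, cfg)
    universe = pd.Series(
        0.5 * (de_a.df["log2fc"].to_numpy() + de_b.df["log2fc"].to_numpy()),
        index=pd.Index(de_a.df["gene_id"], name="gene_id"),
    )
    return {
        "config": cfg,
        "fly_genome": fly_genome, "fly_genes": fly_genes, "sites": sites,
        "mouse_genes": mouse_genes, "orthology": omap,
        "fly_sets": fly_sets, "mouse_sets": mouse_sets, "set_reports": reports,
        "de_tables": (de_a, de_b), "universe_log2fc": universe,
        "truth": {"sites": site_truth, "de": de_truth},
    }
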