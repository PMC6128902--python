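"""Generator determinism, planted-truth geometry and recovery bounds."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dosagelens import (
    SimConfig, SizingError, coverage_track, filter_fragments, make_genome,
    make_orthology, normalize_tracks, partition_fragments, plant_sites,
    simulate_chip_experiment, simulate_conservation_scenario, simulate_de_tables,
    simulate_flash_library, simulate_qpcr_plate,
)
from dosagelens.dosage_stats import qpcr_relative
from dosagelens.synthetic_data import TruthRecord


class TestConfigValidation:
    def test_classes_must_straddle_partition_boundary(self):
        with pytest.raises(ValueError, match="140"):
            SimConfig(footprint_len_mean=150)
        with pytest.raises(ValueError, match="140"):
            SimConfig(nucleosomal_len_mean=120)

    def test_close_barcodes_rejected(self):
        with pytest.raises(ValueError, match="Hamming"):
            SimConfig(flash_barcodes=("AAAAAA", "AAAATT"))


class TestMakeGenome:
    def test_counts_forced_by_config(self, small_cfg):
        genome, genes = make_genome(small_cfg)
        assert len(genome) == small_cfg.n_autosomes + 1
        assert len(genes) == (small_cfg.n_autosomes + 1) * small_cfg.n_genes_per_chrom
        assert genome.x_chrom == "chrX"

    def test_deterministic_given_seed(self, small_cfg):
        _, a = make_genome(small_cfg)
        _, b = make_genome(small_cfg)
        assert a.df.equals(b.df)
        _, c = make_genome(replace(small_cfg, seed=small_cfg.seed + 1))
        assert not a.df.equals(c.df)

    def test_genes_non_overlapping_with_min_length(self, small_cfg):
        _, genes = make_genome(small_cfg)
        assert ((genes.df["end"] - genes.df["start"]) >= 1500).all()
        for _, sub in genes.df.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_sizing_error_when_genes_do_not_fit(self):
        with pytest.raises(SizingError):
            make_genome(SimConfig(chrom_length_bp=10_000, n_genes_per_chrom=100))


class TestPlantSites:
    def test_has_on_x_only_with_requested_count(self, small_cfg):
        genome, genes = make_genome(small_cfg)
        sites, truth = plant_sites(genome, genes, small_cfg)
        assert len(sites["HAS"]) == small_cfg.n_has
        assert all(iv.chrom == "chrX" for iv in sites["HAS"])

    def test_cluster_sites_within_200bp_of_a_tss(self, small_cfg):
        genome, genes = make_genome(small_cfg)
        sites, truth = plant_sites(genome, genes, small_cfg)
        tss = genes.df.set_index("gene_id")["tss"]
        planted = truth.sites.set_index("site_id")
        for ci in (1, 2, 3):
            for iv in sites[f"cluster{ci}"]:
                gene = planted.loc[iv.id, "gene_id"]
                assert abs(iv.center - tss[gene]) <= 200
                assert iv.chrom != "chrX"

    def test_zero_sites_of_a_class_is_fine(self, small_cfg):
        genome, genes = make_genome(small_cfg)
        cfg = replace(small_cfg, n_auto_sites_per_cluster=(0, 0, 0))
        sites, _ = plant_sites(genome, genes, cfg)
        assert sites["cluster1"] == []

    def test_more_sites_than_genes_rejected(self, small_cfg):
        genome, genes = make_genome(small_cfg)
        with pytest.raises(ValueError, match="HAS"):
            plant_sites(genome, genes, replace(small_cfg, n_has=10_000))


class TestChipSimulation:
    @pytest.fixture(scope="class")
    @staticmethod
    def setup():
        cfg = SimConfig(chrom_length_bp=100_000, n_genes_per_chrom=20,
                        n_has=10, n_auto_sites_per_cluster=(4, 3, 3), seed=7)
        genome, genes = make_genome(cfg)
        sites, _ = plant_sites(genome, genes, cfg)
        return cfg, genome, sites

    def test_unknown_labels_rejected(self, setup):
        cfg, genome, sites = setup
        with pytest.raises(ValueError, match="sex"):
            simulate_chip_experiment(genome, sites, cfg, sex="other")
        with pytest.raises(ValueError, match="antibody"):
            simulate_chip_experiment(genome, sites, cfg, antibody="unknown")

    def test_deterministic(self, setup):
        cfg, genome, sites = setup
        a, _ = simulate_chip_experiment(genome, sites, cfg)
        b, _ = simulate_chip_experiment(genome, sites, cfg)
        assert a.df.equals(b.df)

    @pytest.mark.parametrize("sex,expected", [("male", 0.5), ("female", 1.0)])
    def test_input_x_to_autosome_ratio(self, setup, sex, expected):
        cfg, genome, sites = setup
        _, inp = simulate_chip_experiment(genome, sites, cfg, sex=sex)
        track = normalize_tracks(
            coverage_track(filter_fragments(inp), genome, 10), None, "one_x"
        )
        assert track.mean_per_base(genome.autosomes) == pytest.approx(1.0, abs=1e-9)
        assert track.mean_per_base(["chrX"]) == pytest.approx(expected, rel=0.10)

    def test_zero_emission_chip_matches_input_statistically(self, setup):
        cfg, genome, sites = setup
        cfg0 = replace(cfg, site_emission_rate=0.0)
        chip, inp = simulate_chip_experiment(genome, sites, cfg0)
        # same background model: totals agree within Poisson error
        assert len(chip) == pytest.approx(len(inp), rel=0.1)

    def test_site_fragments_fall_in_footprint_class(self, setup):
        cfg, genome, sites = setup
        chip, inp = simulate_chip_experiment(genome, sites, cfg, antibody="MSL2tg")
        # fragments within 50 bp of a HAS center are dominated by planted
        # footprints; with mean 90 sd 15 truncated at 140, >99% are small
        centers = {iv.center for iv in sites["HAS"]}
        mids = ((chip.df["start"] + chip.df["end"]) // 2).to_numpy()
        on_x = chip.df["chrom"] == "chrX"
        near = np.zeros(len(chip.df), dtype=bool)
        for c in centers:
            near |= on_x.to_numpy() & (np.abs(mids - c) <= 30)
        lengths = (chip.df["end"] - chip.df["start"]).to_numpy()[near]
        assert (lengths <= 140).mean() > 0.9

    def test_untagged_antibody_emits_no_site_signal(self, setup):
        cfg, genome, sites = setup
        chip, inp = simulate_chip_experiment(genome, sites, cfg, antibody="untagged")
        assert len(chip) == pytest.approx(len(inp), rel=0.1)


class TestFlashSimulation:
    def test_no_pcr_duplication_means_reads_equal_molecules(self, small_cfg):
        _, genes = make_genome(small_cfg)
        cfg = replace(small_cfg, pcr_dup_mean=0.0)
        enrich = {g: 2.0 for g in genes.gene_ids[:10]}
        fwd, rev, _, truth = simulate_flash_library(genes, enrich, cfg)
        assert len(fwd) == sum(truth.molecule_counts.values())

    def test_zero_rate_gene_has_zero_molecules(self, small_cfg):
        _, genes = make_genome(small_cfg)
        enrich = {genes.gene_ids[0]: 0.0, genes.gene_ids[1]: 50.0}
        _, _, _, truth = simulate_flash_library(genes, enrich, small_cfg)
        assert truth.molecule_counts[genes.gene_ids[0]] == 0
        assert truth.molecule_counts[genes.gene_ids[1]] > 0

    def test_unknown_gene_rejected(self, small_cfg):
        _, genes = make_genome(small_cfg)
        with pytest.raises(ValueError, match="unknown"):
            simulate_flash_library(genes, {"nope": 1.0}, small_cfg)

    def test_reads_begin_with_barcode_then_umi(self, small_cfg):
        _, genes = make_genome(small_cfg)
        fwd, _, index, _ = simulate_flash_library(
            genes, {genes.gene_ids[0]: 30.0}, small_cfg, barcode_index=1
        )
        bc = small_cfg.flash_barcodes[1]
        assert all(r.sequence.startswith(bc) for r in fwd)


class TestDeSimulation:
    def test_null_set_mean_near_zero(self, small_cfg):
        _, genes = make_genome(small_cfg)
        a, b, truth = simulate_de_tables(genes, {}, small_cfg)
        n = len(genes)
        bound = 3 * small_cfg.de_noise_sd / np.sqrt(n)
        assert abs(a.df["log2fc"].mean()) < bound

    def test_planted_shift_recovered_within_clt_bound(self, small_cfg):
        _, genes = make_genome(small_cfg)
        members = genes.gene_ids[:66]
        shifts = {g: -0.5 for g in members}
        a, b, truth = simulate_de_tables(genes, shifts, small_cfg)
        bound = 3 * small_cfg.de_noise_sd / np.sqrt(66)
        for t in (a, b):
            assert t.df.loc[members, "log2fc"].mean() == pytest.approx(-0.5, abs=bound)
        assert truth.gene_effects == shifts

    def test_clones_share_shift_but_not_noise(self, small_cfg):
        _, genes = make_genome(small_cfg)
        a, b, _ = simulate_de_tables(genes, {genes.gene_ids[0]: -2.0}, small_cfg)
        assert not a.df["log2fc"].equals(b.df["log2fc"])
        # the planted gene is strongly down in both clones
        g = genes.gene_ids[0]
        assert a.df.loc[g, "log2fc"] < -1 and b.df.loc[g, "log2fc"] < -1

    def test_strong_shifts_pass_fdr_nulls_mostly_do_not(self, small_cfg):
        _, genes = make_genome(small_cfg)
        members = genes.gene_ids[:5]
        a, _, _ = simulate_de_tables(genes, {g: -3.0 for g in members}, small_cfg)
        assert (a.df.loc[members, "fdr"] < 0.05).all()
        null_fdr = a.df.drop(index=members)["fdr"]
        assert (null_fdr < 0.05).mean() < 0.10

    def test_unknown_gene_rejected(self, small_cfg):
        _, genes = make_genome(small_cfg)
        with pytest.raises(ValueError, match="unknown"):
            simulate_de_tables(genes, {"nope": 1.0}, small_cfg)


class TestOrthology:
    def test_full_one2one(self, small_cfg):
        _, fly = make_genome(small_cfg, prefix="fly")
        _, mouse = make_genome(small_cfg, prefix="mouse")
        omap = make_orthology(fly, mouse, small_cfg, one2one_frac=1.0)
        assert all(omap.is_one2one(g) for g in fly.gene_ids)

    def test_deterministic_rounding_of_fraction(self, small_cfg):
        _, fly = make_genome(small_cfg, prefix="fly")
        _, mouse = make_genome(small_cfg, prefix="mouse")
        omap = make_orthology(fly, mouse, small_cfg, one2one_frac=0.5)
        n11 = sum(omap.is_one2one(g) for g in fly.gene_ids)
        assert n11 == round(0.5 * len(fly.gene_ids))

    def test_non_one2one_have_zero_or_two_partners(self, small_cfg):
        _, fly = make_genome(small_cfg, prefix="fly")
        _, mouse = make_genome(small_cfg, prefix="mouse")
        omap = make_orthology(fly, mouse, small_cfg, one2one_frac=0.5)
        for g in fly.gene_ids:
            if not omap.is_one2one(g):
                assert len(omap.mapping[g]) in (0, 2)


class TestQpcrSimulation:
    def test_noise_free_plate_reproduces_ratios_exactly(self, small_cfg):
        cfg = replace(small_cfg, qpcr_sigma_ct=0.0)
        eff = {g: 2.0 for g in ("roX1", "RpL32", "Pfk", "U6")}
        plate = simulate_qpcr_plate(
            ["roX1"], {"male": {"roX1": 2.0}}, eff, cfg,
            reference_genes=["RpL32", "Pfk", "U6"],
        )
        assert qpcr_relative(plate, "roX1", "male") == pytest.approx(2.0, rel=1e-12)
        # Ct difference of exactly one cycle encodes the twofold level
        assert (plate.ct[("RpL32", "male")] - plate.ct[("roX1", "male")]
                ) == pytest.approx(1.0, abs=1e-12)

    def test_dilution_series_step_encodes_efficiency(self, small_cfg):
        from dosagelens import qpcr_efficiency
        cfg = replace(small_cfg, qpcr_sigma_ct=0.0)
        plate = simulate_qpcr_plate([], {"s": {}}, {"RpL32": 2.0, "Pfk": 2.0, "U6": 2.0},
                                    cfg)
        series = plate.dilution_series["RpL32"]
        steps = np.diff(series["ct"])
        np.testing.assert_allclose(steps, np.log2(10), rtol=1e-12)
        assert qpcr_efficiency(series) == pytest.approx(2.0, rel=1e-9)

    def test_bad_efficiency_rejected(self, small_cfg):
        with pytest.raises(ValueError):
            simulate_qpcr_plate([], {"s": {}}, {"RpL32": 0.9, "Pfk": 2.0, "U6": 2.0},
                                small_cfg)


class TestConservationScenario:
    def test_paper_scale_set_sizes_and_planted_truth(self):
        scen = simulate_conservation_scenario(11)
        sizes = {s.label: len(s) for s in scen["mouse_sets"]}
        assert sizes == {"cluster1": 66, "cluster2": 269, "cluster3": 346,
                         "HAS": 432, "HAS_proximal": 231}
        cluster1 = next(s for s in scen["mouse_sets"] if s.label == "cluster1")
        effects = scen["truth"]["de"].gene_effects
        assert set(effects) == set(cluster1.members)
        assert all(v == scen["config"].de_effect_cluster1 for v in effects.values())

    def test_deterministic_in_seed(self):
        a = simulate_conservation_scenario(3)
        b = simulate_conservation_scenario(3)
        pd.testing.assert_series_equal(a["universe_log2fc"], b["universe_log2fc"])
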