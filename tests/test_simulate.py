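"""Cohort generator: design enumeration, determinism, closure, calibration."""

import dataclasses

import numpy as np
import pytest

import skinmwas.io as sio
from skinmwas.errors import AlignmentError, ConfigError
from skinmwas.simulate import (default_config, null_config,
                               simulate_cohort, simulate_gene_tables,
                               simulate_taxon_profiles, single_site_config)
from skinmwas.stats import spearman
from skinmwas.taxa import clade_string


class TestCohortDesign:
    def test_default_design_enumerates_180_samples(self):
        meta, _ = simulate_cohort(default_config())
        assert len(meta) == 180
        assert meta["sample_id"].is_unique
        # 30 subjects x 3 sites x 2 timepoints, sexes 8F/7M per group
        assert meta["subject_id"].nunique() == 30
        counts = meta.drop_duplicates("subject_id").groupby(["age_group", "sex"]).size()
        assert counts.loc[("children", "F")] == 8
        assert counts.loc[("teens", "M")] == 7

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigError, match="n_children"):
            default_config(n_children=0, n_teens=0,
                           sex_split={"children": (0, 0), "teens": (0, 0)}).validate()

    def test_invalid_fields_named_in_errors(self):
        with pytest.raises(ConfigError, match="timepoints"):
            default_config(timepoints=("1h",)).validate()
        with pytest.raises(ConfigError, match="sigma_odor_noise"):
            default_config(sigma_odor_noise=-1.0).validate()
        with pytest.raises(ConfigError, match="sex_split"):
            default_config(sex_split={"children": (9, 9), "teens": (8, 7)}).validate()
        with pytest.raises(ConfigError, match="target_spearman"):
            single_site_config(target_spearman=0.99).validate()

    def test_same_seed_reproduces_byte_identical_tables(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            cfg = default_config(seed=42)
            meta, truth = simulate_cohort(cfg)
            taxa = simulate_taxon_profiles(meta, truth, cfg)
            genes, pw = simulate_gene_tables(taxa, cfg)
            d = tmp_path / run
            d.mkdir()
            sio.write_metadata(meta, d / "meta.tsv")
            sio.write_taxon_table(taxa, d / "taxa.tsv")
            sio.write_stratified_gene_table(genes, d / "genes.tsv")
            sio.write_pathway_tables(pw, d / "pa.tsv", d / "pc.tsv")
            paths.append(d)
        for name in ("meta.tsv", "taxa.tsv", "genes.tsv", "pa.tsv", "pc.tsv"):
            assert (paths[0] / name).read_bytes() == (paths[1] / name).read_bytes()

    def test_odor_rises_after_exercise_in_underarm(self):
        meta, _ = simulate_cohort(default_config(seed=3))
        ua = meta[meta["site"] == "underarm"]
        by_tp = ua.groupby("timepoint")["odor_intensity"].mean()
        assert by_tp["8h"] > by_tp["1h"]

    def test_ground_truth_partitions_features(self):
        cfg = default_config()
        _, truth = simulate_cohort(cfg)
        planted = [r.effect.taxon for r in truth.planted]
        assert set(planted).isdisjoint(truth.null_taxa)
        assert sorted(planted + truth.null_taxa) == sorted(cfg.taxa)
        assert len(planted) + len(truth.null_taxa) == cfg.n_taxa


class TestTaxonProfiles:
    def test_composition_closes_to_100(self, default_cohort):
        sums = default_cohort["taxa"].sum(axis=0)
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_mismatched_metadata_rejected(self, default_cohort):
        cfg = default_cohort["config"]
        meta = default_cohort["meta"].iloc[:-2]
        with pytest.raises(AlignmentError):
            simulate_taxon_profiles(meta, default_cohort["truth"], cfg)

    def test_planted_copula_hits_target_rank_correlation(self):
        """Realized Spearman lands within 0.2 of the 0.8 target in >= 90% of
        200 replicate 30-sample cohorts (copula calibration check)."""
        clade = clade_string("Staphylococcus_epidermidis")
        within = 0
        for seed in range(200):
            cfg = single_site_config(target_spearman=0.8, seed=seed)
            meta, truth = simulate_cohort(cfg)
            taxa = simulate_taxon_profiles(meta, truth, cfg)
            sub = meta[meta["age_group"] == "children"]
            rho, _ = spearman(taxa.loc[clade, sub["sample_id"]].to_numpy(),
                              sub["odor_intensity"].to_numpy())
            within += abs(rho - 0.8) <= 0.2
        assert within >= 0.9 * 200

    def test_null_taxa_match_spearman_null_critical_value(self):
        """|rho| of a null taxon vs odor exceeds the n=30 alpha=0.05 critical
        value (0.36) in roughly 5% of replicates, never systematically."""
        exceed = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = null_config(n_taxa=5, seed=seed)
            meta, truth = simulate_cohort(cfg)
            taxa = simulate_taxon_profiles(meta, truth, cfg)
            sub = meta[meta["age_group"] == "children"]
            rho, _ = spearman(taxa.iloc[0][sub["sample_id"]].to_numpy(),
                              sub["odor_intensity"].to_numpy())
            exceed += abs(rho) > 0.36
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert exceed / n_rep <= bound

    def test_mean_realized_correlation_tracks_targets(self):
        """Over 100 default-cohort replicates, each planted effect's mean
        realized Spearman is within 0.1 of its target."""
        cfg0 = default_config()
        effects = [(r.taxon, r.site,
                    "youth" if r.stratum == "both" else r.stratum,
                    r.target_spearman)
                   for r in cfg0.planted_taxa]
        sums = {e[0]: 0.0 for e in effects}
        n_rep = 100
        for seed in range(n_rep):
            cfg = dataclasses.replace(cfg0, seed=seed)
            meta, truth = simulate_cohort(cfg)
            taxa = simulate_taxon_profiles(meta, truth, cfg)
            for taxon, site, stratum, _ in effects:
                sub = meta[meta["site"] == site]
                if stratum != "youth":
                    sub = sub[sub["age_group"] == stratum]
                rho, _ = spearman(taxa.loc[clade_string(taxon), sub["sample_id"]],
                                  sub["odor_intensity"].to_numpy())
                sums[taxon] += rho
        for taxon, _, _, target in effects:
            assert abs(sums[taxon] / n_rep - target) <= 0.1, taxon


class TestGeneTables:
    def test_total_rows_equal_sum_of_strata(self, default_cohort):
        genes = default_cohort["genes"]
        totals = genes.xs("TOTAL", level="stratum")
        strata = genes[genes.index.get_level_values("stratum") != "TOTAL"]
        recon = strata.groupby("gene_family").sum().reindex(totals.index).fillna(0.0)
        assert np.allclose(totals.to_numpy(), recon.to_numpy(),
                           rtol=1e-9, atol=1e-9)

    def test_absent_taxon_has_zero_strata(self):
        # a coarse detection floor guarantees zero abundances somewhere
        cfg = single_site_config(detection_floor=1.0, seed=5)
        meta, truth = simulate_cohort(cfg)
        taxa = simulate_taxon_profiles(meta, truth, cfg)
        genes, _ = simulate_gene_tables(taxa, cfg)
        zero = np.argwhere(taxa.to_numpy() == 0.0)
        assert len(zero) > 0
        from skinmwas.taxa import species_from_clade, stratum_token
        for i, j in zero[:20]:
            token = stratum_token(species_from_clade(taxa.index[i]))
            sample = taxa.columns[j]
            strata = genes[genes.index.get_level_values("stratum") == token]
            assert (strata[sample] == 0.0).all()

    def test_no_carriage_means_zero_coverage(self):
        cfg = single_site_config(ko_carry_prob=0.0)
        planted = (dataclasses.replace(cfg.planted_taxa[0], linked_kos=()),)
        cfg = dataclasses.replace(cfg, planted_taxa=planted)
        meta, truth = simulate_cohort(cfg)
        taxa = simulate_taxon_profiles(meta, truth, cfg)
        _, pw = simulate_gene_tables(taxa, cfg)
        assert (pw.coverage.to_numpy() == 0.0).all()

    def test_unknown_linked_ko_rejected(self):
        cfg = single_site_config()
        planted = (dataclasses.replace(cfg.planted_taxa[0],
                                       linked_kos=("K99999",)),)
        cfg = dataclasses.replace(cfg, planted_taxa=planted)
        meta, truth = simulate_cohort(cfg)
        taxa = simulate_taxon_profiles(meta, truth, cfg)
        with pytest.raises(ConfigError, match="K99999"):
            simulate_gene_tables(taxa, cfg)

    def test_coverage_bounded_and_unclassified_fraction(self, default_cohort):
        pw = default_cohort["pathways"]
        cov = pw.coverage.to_numpy()
        assert ((cov >= 0) & (cov <= 1)).all()
        genes = default_cohort["genes"]
        uncl = genes.xs("unclassified", level="stratum")
        totals = genes.xs("TOTAL", level="stratum").reindex(uncl.index)
        nz = totals.to_numpy() > 0
        frac = uncl.to_numpy()[nz] / totals.to_numpy()[nz]
        assert np.allclose(frac, default_cohort["config"].unclassified_fraction)
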