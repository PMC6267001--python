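"""KO aggregation modes, the candidate-pathway rule, and per-species counts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from skinmwas.associate import associate_features
from skinmwas.errors import IncompleteDesignError, MappingError
from skinmwas.functional import (BAG_OF_GENES, BAG_OF_GENOMES, KoCatalog,
                                 KoMap, aggregate_to_ko,
                                 count_significant_kos, default_catalog,
                                 marginalize_strata, pathway_candidate_rule,
                                 pathway_sign_consistency)
from skinmwas.io import filter_gene_families
from skinmwas.pipeline import _flatten_ko_index
from skinmwas.simulate import (simulate_cohort, simulate_gene_tables,
                               simulate_taxon_profiles, single_site_config)


def _tiny_genes():
    """Two families of one KO split across two taxa, plus an unmapped one."""
    idx = pd.MultiIndex.from_tuples([
        ("FAM_1", "TOTAL"), ("FAM_1", "g__A.s__A_x"),
        ("FAM_2", "TOTAL"), ("FAM_2", "g__B.s__B_y"),
        ("FAM_9", "TOTAL"), ("FAM_9", "g__A.s__A_x"),
    ], names=["gene_family", "stratum"])
    genes = pd.DataFrame([[10.0, 20.0], [10.0, 20.0],
                          [1.0, 2.0], [1.0, 2.0],
                          [5.0, 5.0], [5.0, 5.0]], index=idx,
                         columns=["s1", "s2"])
    catalog = KoCatalog({"PW": ("K1",)})
    komap = KoMap({"FAM_1": "K1", "FAM_2": "K1", "FAM_9": None}, catalog)
    return genes, komap


class TestAggregateToKo:
    def test_single_family_single_taxon_modes_agree(self):
        genes, komap = _tiny_genes()
        one = genes.loc[[("FAM_1", "TOTAL"), ("FAM_1", "g__A.s__A_x")]]
        pooled = aggregate_to_ko(one, komap, BAG_OF_GENES)
        strat = aggregate_to_ko(one, komap, BAG_OF_GENOMES)
        assert np.allclose(pooled.loc["K1"], strat.sum(axis=0))

    def test_split_ko_preserved_by_strata(self):
        genes, komap = _tiny_genes()
        pooled = aggregate_to_ko(genes, komap, BAG_OF_GENES)
        strat = aggregate_to_ko(genes, komap, BAG_OF_GENOMES)
        assert list(pooled.index) == ["K1"]
        assert np.allclose(pooled.loc["K1"], [11.0, 22.0])
        assert len(strat) == 2  # one row per contributing taxon
        assert np.allclose(strat.loc[("K1", "g__A.s__A_x")], [10.0, 20.0])

    def test_unmapped_families_dropped(self):
        genes, komap = _tiny_genes()
        pooled = aggregate_to_ko(genes, komap, BAG_OF_GENES)
        assert "FAM_9" not in pooled.index

    def test_pooled_equals_marginalized_strata_on_simulated_fixture(
            self, default_cohort):
        genes, komap = default_cohort["genes"], default_cohort["komap"]
        pooled = aggregate_to_ko(genes, komap, BAG_OF_GENES)
        strat = aggregate_to_ko(genes, komap, BAG_OF_GENOMES)
        recon = marginalize_strata(strat).reindex(pooled.index)
        assert np.allclose(pooled.to_numpy(), recon.to_numpy(),
                           rtol=1e-9, atol=1e-6)

    def test_empty_mapping_rejected(self):
        genes, _ = _tiny_genes()
        with pytest.raises(MappingError):
            aggregate_to_ko(genes, KoMap({}, default_catalog()), BAG_OF_GENES)


class TestCandidateRule:
    def _qtable(self, rows):
        cols = [f"q_{s}_{t}" for s in ("youth", "children", "teens")
                for t in ("spearman", "wilcoxon")]
        return pd.DataFrame(rows, columns=cols,
                            index=[f"pw{i}" for i in range(len(rows))])

    def test_two_of_six_boundary(self):
        out = pathway_candidate_rule(self._qtable([
            [0.01] * 6,                                # all hits
            [0.01, 0.5, 0.5, 0.5, 0.5, 0.5],           # one hit
            [0.01, 0.09, 0.5, 0.5, 0.5, 0.5],          # exactly two
        ]))
        assert out["candidate"].tolist() == [True, False, True]
        assert out["n_hits"].tolist() == [6, 1, 2]

    def test_nan_cells_never_count(self):
        out = pathway_candidate_rule(self._qtable(
            [[0.01, np.nan, np.nan, np.nan, np.nan, np.nan]]))
        assert not out["candidate"].iloc[0]

    def test_missing_comparison_rejected(self):
        bad = self._qtable([[0.01] * 6]).iloc[:, :5]
        with pytest.raises(IncompleteDesignError):
            pathway_candidate_rule(bad)

    def test_monotone_in_q(self):
        rng = np.random.default_rng(7)
        q = self._qtable(rng.uniform(0, 1, (10, 6)))
        base = pathway_candidate_rule(q)["candidate"]
        for i in range(10):
            lowered = q.copy()
            lowered.iloc[i, rng.integers(0, 6)] = 0.0
            after = pathway_candidate_rule(lowered)["candidate"]
            assert (after | ~base).all()  # candidacy never lost


class TestSpeciesKoCounts:
    def test_absent_species_counts_zero(self, default_cohort):
        genes, komap = default_cohort["genes"], default_cohort["komap"]
        strat = aggregate_to_ko(genes, komap, BAG_OF_GENOMES)
        assoc = pd.DataFrame({"feature": [], "rho": [], "q_spearman": []})
        n_present, n_sig = count_significant_kos(
            "PW_PYRUVATE", "No_such_species", strat, assoc, komap.catalog)
        assert (n_present, n_sig) == (0, 0)

    def test_unknown_pathway_rejected(self, default_cohort):
        genes, komap = default_cohort["genes"], default_cohort["komap"]
        strat = aggregate_to_ko(genes, komap, BAG_OF_GENOMES)
        with pytest.raises(MappingError):
            count_significant_kos("PW_NOPE", "x", strat,
                                  pd.DataFrame({"feature": []}), komap.catalog)

    def test_three_of_five_planted_kos_recovered(self):
        """A species carrying 3 of a pathway's 5 KOs with a strong positive
        effect yields (present, significant) = (3, 3) in most replicates."""
        members = default_catalog().pathways["PW_PYRUVATE"]
        linked = tuple(members[:3])
        hits = 0
        for seed in range(15):
            cfg = single_site_config(target_spearman=0.8, seed=seed,
                                     exclusive_repertoires=True)
            cfg = dataclasses.replace(cfg, planted_taxa=(
                dataclasses.replace(cfg.planted_taxa[0], linked_kos=linked),))
            meta, truth = simulate_cohort(cfg)
            taxa = simulate_taxon_profiles(meta, truth, cfg)
            genes, _ = simulate_gene_tables(taxa, cfg)
            komap = KoMap(genes.attrs["family_to_ko"], cfg.catalog())
            kept = filter_gene_families(genes, meta, 10.0, "underarm")
            strat = aggregate_to_ko(kept, komap, BAG_OF_GENOMES)
            assoc = associate_features(_flatten_ko_index(strat), meta,
                                       "underarm", "children")
            n_present, n_sig = count_significant_kos(
                "PW_PYRUVATE", "Staphylococcus_epidermidis", strat, assoc,
                komap.catalog)
            assert n_present == 3
            assert n_sig <= n_present
            hits += n_sig == 3
        assert hits >= 13

    def test_counts_bounded_on_cohort_fixture(self, default_cohort):
        genes, komap, meta = (default_cohort["genes"], default_cohort["komap"],
                              default_cohort["meta"])
        kept = filter_gene_families(genes, meta, 10.0, "underarm")
        strat = aggregate_to_ko(kept, komap, BAG_OF_GENOMES)
        assoc = associate_features(_flatten_ko_index(strat), meta,
                                   "underarm", "youth")
        n_present, n_sig = count_significant_kos(
            "PW_BCAA_BIOSYNTH", "Staphylococcus_epidermidis", strat, assoc,
            komap.catalog)
        assert 0 <= n_sig <= n_present


class TestSignConsistency:
    def _assoc(self, features_rho):
        return pd.DataFrame({"feature": list(features_rho),
                             "rho": list(features_rho.values())})

    def test_unanimous_and_split(self):
        catalog = KoCatalog({"PW": ("K1", "K2", "K3", "K4")})
        allpos = self._assoc({"K1": 0.5, "K2": 0.3, "K3": 0.2, "K4": 0.9})
        assert pathway_sign_consistency(allpos, catalog, "PW") == 1.0
        split = self._assoc({"K1": 0.5, "K2": 0.3, "K3": -0.2, "K4": -0.9})
        assert pathway_sign_consistency(split, catalog, "PW") == 0.5

    def test_insufficient_kos_flagged_nan(self):
        catalog = KoCatalog({"PW": ("K1", "K2")})
        one = self._assoc({"K1": 0.5})
        assert np.isnan(pathway_sign_consistency(one, catalog, "PW"))

    def test_opposed_species_consistent_per_species_inconsistent_pooled(self):
        catalog = KoCatalog({"PW": ("K1", "K2")})
        strat = self._assoc({
            "K1|g__A.s__A_x": 0.6, "K2|g__A.s__A_x": 0.5,
            "K1|g__B.s__B_y": -0.6, "K2|g__B.s__B_y": -0.5,
        })
        per_species = pathway_sign_consistency(strat, catalog, "PW",
                                               by_species=True)
        assert per_species == {"A_x": 1.0, "B_y": 1.0}
        pooled = self._assoc({"K1": 0.05, "K2": -0.04})
        assert pathway_sign_consistency(pooled, catalog, "PW") == 0.5
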