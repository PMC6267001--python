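"""End-to-end pipeline: simulate/load -> filter -> associate -> functional
MWAS -> constrained ordination, with a manifest for reproducibility.

A single :class:`PipelineConfig` (usually from YAML) drives everything; all
default thresholds equal the gates used throughout the package (taxa 1%,
gene-family RPK 10, pathway coverage 0.3, q 0.1, |rho| 0.2, two-of-six
candidate rule).  Reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .associate import STRATA, associate_all, associate_features, render_table
from .errors import ConfigError
from .functional import (BAG_OF_GENES, BAG_OF_GENOMES, KoCatalog, KoMap,
                         aggregate_to_ko, count_significant_kos,
                         pathway_candidate_rule, pathway_sign_consistency)
from .io import (filter_gene_families, filter_pathways_by_coverage,
                 filter_taxa_by_abundance, read_metadata,
                 read_pathway_tables, read_stratified_gene_table,
                 read_taxon_table, write_metadata, write_pathway_tables,
                 write_stratified_gene_table, write_taxon_table)
from .ordination import DEFAULT_N_PERM, bray_curtis, build_constraints, cap
from .simulate import (SimConfig, simulate_cohort, simulate_gene_tables,
                       simulate_taxon_profiles)

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.6g"


@dataclass
class Thresholds:
    taxon_abundance: float = 1.0   # percent, mean per age group
    gene_rpk: float = 10.0         # mean community RPK per age group
    pathway_coverage: float = 0.3  # mean coverage across the site's samples
    q: float = 0.1                 # BH-adjusted significance level
    rho: float = 0.2               # |rho| gate accompanying the q gate
    min_hits: int = 2              # of the six (stratum, test) comparisons

    def validate(self) -> None:
        for name in ("taxon_abundance", "gene_rpk", "pathway_coverage"):
            if getattr(self, name) < 0:
                raise ConfigError(f"thresholds.{name} must be >= 0")
        if not 0 <= self.q <= 1:
            raise ConfigError("thresholds.q must be in [0, 1]")


@dataclass
class PipelineConfig:
    """Everything one run needs; either a simulate block or input paths."""

    simulate: SimConfig | None = None
    inputs: dict | None = None  # paths: metadata, taxa, genes, pathway_*, maps
    sites: tuple = ("underarm", "neck", "head")
    strata: tuple = STRATA
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    out_dir: str = "skinmwas_out"

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' and 'inputs' must be given")
        if self.simulate is not None:
            self.simulate.validate()
        self.thresholds.validate()
        if self.inputs is not None:
            required = ("metadata", "taxa", "genes", "pathway_abundance",
                        "pathway_coverage", "family_ko_map")
            for key in required:
                if key not in self.inputs:
                    raise ConfigError(f"inputs.{key} is required")
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(f"inputs.{key}: no such file {self.inputs[key]}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "simulate" in raw:
            sim = dict(raw["simulate"] or {})
            if "planted_taxa" in sim:
                from .simulate import PlantedEffect
                sim["planted_taxa"] = tuple(
                    PlantedEffect(**{**p, "linked_kos": tuple(p.get("linked_kos", ()))})
                    for p in sim["planted_taxa"])
            for key in ("sites", "timepoints"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "sex_split" in sim:
                sim["sex_split"] = {g: tuple(v) for g, v in sim["sex_split"].items()}
            kwargs["simulate"] = SimConfig(**sim)
        if "inputs" in raw:
            kwargs["inputs"] = dict(raw["inputs"])
        if "thresholds" in raw:
            kwargs["thresholds"] = Thresholds(**raw["thresholds"])
        for key in ("sites", "strata"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("n_perm", "seed", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def fingerprint(self) -> str:
        payload = dataclasses.asdict(self)
        if self.simulate is not None:
            payload["simulate"] = dataclasses.asdict(self.simulate)
            payload["simulate"].pop("ko_catalog", None)
        payload["thresholds"] = dataclasses.asdict(self.thresholds)
        def _stringify(obj):
            if isinstance(obj, dict):
                return {str(k): _stringify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_stringify(v) for v in obj]
            return obj

        blob = json.dumps(_stringify(payload), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def summarize_odor_characters(meta: pd.DataFrame) -> pd.DataFrame:
    """Counts and mean odor intensity per (site, age group, timepoint) and
    odor-character combination.  Counts partition the samples of each cell."""
    grouped = meta.groupby(["site", "age_group", "timepoint", "odor_characters"])
    out = grouped["odor_intensity"].agg(n_samples="size", mean_intensity="mean")
    return out.reset_index()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)


def _flatten_ko_index(ko_strat: pd.DataFrame) -> pd.DataFrame:
    flat = ko_strat.copy()
    flat.index = [f"{ko}|{stratum}" for ko, stratum in ko_strat.index]
    flat.index.name = "ko_stratum"
    return flat


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a manifest dict (also written to
    ``out_dir/manifest.json``)."""
    t0 = time.monotonic()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    # ---- stage 1: obtain inputs -------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        meta, truth = simulate_cohort(sim)
        taxa = simulate_taxon_profiles(meta, truth, sim)
        genes, pathways = simulate_gene_tables(taxa, sim)
        komap = KoMap(genes.attrs["family_to_ko"], sim.catalog())
        inputs_dir = out / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        write_metadata(meta, inputs_dir / "metadata.tsv")
        write_taxon_table(taxa, inputs_dir / "taxon_table.tsv")
        write_stratified_gene_table(genes, inputs_dir / "gene_families.tsv")
        write_pathway_tables(pathways, inputs_dir / "pathway_abundance.tsv",
                             inputs_dir / "pathway_coverage.tsv")
        komap.to_tsv(inputs_dir / "family_ko_map.tsv")
        truth.to_json(inputs_dir / "ground_truth.json")
    else:
        paths = config.inputs
        meta = read_metadata(paths["metadata"])
        taxa = read_taxon_table(paths["taxa"])
        genes = read_stratified_gene_table(paths["genes"])
        pathways = read_pathway_tables(paths["pathway_abundance"],
                                       paths["pathway_coverage"])
        catalog = (KoCatalog.from_tsv(paths["ko_pathway_map"])
                   if "ko_pathway_map" in paths else None)
        komap = KoMap.from_tsv(paths["family_ko_map"], catalog)
    logger.info("inputs ready: %d samples, %d taxa, %d gene-family rows",
                len(meta), len(taxa), len(genes))

    catalog = komap.catalog
    manifest_outputs = {}

    # ---- stage 2: per-site analyses ---------------------------------------
    for site in config.sites:
        site_dir = out / site
        site_dir.mkdir(exist_ok=True)
        site_meta = meta[meta["site"] == site]

        kept_taxa = filter_taxa_by_abundance(taxa, meta, th.taxon_abundance, site)
        assoc = associate_all(kept_taxa, meta, site, config.strata, th.q, th.rho)
        _write_tsv(assoc, site_dir / "taxon_associations.tsv")
        (site_dir / "taxon_report.txt").write_text(
            render_table(assoc, th.q).to_string(index=False) + "\n", encoding="utf-8")

        # constrained ordination on the site's community profile
        site_taxa = kept_taxa[site_meta["sample_id"]].T
        dm = bray_curtis(site_taxa)
        constraints = build_constraints(site_meta)
        cap_res = cap(dm, constraints, n_perm=config.n_perm, seed=config.seed)
        cap_summary = pd.DataFrame({
            "site": [site], "pseudo_F": [cap_res.pseudo_f],
            "p_value": [cap_res.p_value],
            "constrained_inertia": [cap_res.constrained_inertia],
            "total_inertia": [cap_res.total_inertia],
            "n_permutations": [cap_res.n_permutations],
        })
        _write_tsv(cap_summary, site_dir / "cap_summary.tsv")
        _write_tsv(cap_res.sample_scores, site_dir / "cap_sample_scores.tsv", index=True)
        _write_tsv(cap_res.biplot_scores, site_dir / "cap_biplot_scores.tsv", index=True)

        # functional MWAS
        kept_genes = filter_gene_families(genes, meta, th.gene_rpk, site)
        ko_pooled = aggregate_to_ko(kept_genes, komap, BAG_OF_GENES)
        ko_strat = _flatten_ko_index(aggregate_to_ko(kept_genes, komap, BAG_OF_GENOMES))

        kept_pw = filter_pathways_by_coverage(pathways, th.pathway_coverage, meta, site)
        pw_rows = pathways.abundance.loc[kept_pw, site_meta["sample_id"]]
        colsum = pw_rows.sum(axis=0)
        pw_rel = pw_rows / colsum.replace(0, 1.0)
        qcells = {}
        for stratum in config.strata:
            a = associate_features(pw_rel, meta, site, stratum, th.q, th.rho)
            a = a.set_index("feature")
            qcells[(stratum, "spearman")] = a["q_spearman"]
            qcells[(stratum, "wilcoxon")] = a["q_wilcoxon"]
        qtable = pd.DataFrame(qcells)
        qtable.columns = [f"q_{s}_{t}" for s, t in qtable.columns]
        candidates = pathway_candidate_rule(qtable, th.q, th.min_hits)
        candidates.index.name = "pathway"
        _write_tsv(candidates.reset_index(), site_dir / "pathway_candidates.tsv")

        # per-(pathway, species) significant-KO counts on candidate pathways
        ko_assoc = {s: associate_features(ko_strat, meta, site, s, th.q, th.rho)
                    for s in config.strata}
        count_rows = []
        cand_ids = list(candidates.index[candidates["candidate"]])
        ko_table_mi = aggregate_to_ko(kept_genes, komap, BAG_OF_GENOMES)
        species_present = sorted({tok for _, tok in ko_table_mi.index
                                  if tok != "unclassified"})
        from .taxa import species_from_stratum
        for pw in cand_ids:
            for token in species_present:
                sp = species_from_stratum(token)
                for stratum in config.strata:
                    n_present, n_sig = count_significant_kos(
                        pw, sp, ko_table_mi, ko_assoc[stratum], catalog,
                        th.q, th.rho)
                    if n_present:
                        count_rows.append((pw, sp, stratum, n_present, n_sig))
        counts = pd.DataFrame(count_rows, columns=[
            "pathway", "species", "stratum", "n_kos_present", "n_kos_significant"])
        _write_tsv(counts, site_dir / "species_ko_counts.tsv")

        # within-pathway sign consistency for both modes ('youth' stratum)
        pooled_assoc = associate_features(ko_pooled, meta, site, "youth", th.q, th.rho)
        cons_rows = []
        for pw in cand_ids:
            pooled = pathway_sign_consistency(pooled_assoc, catalog, pw)
            per_sp = pathway_sign_consistency(ko_assoc["youth"], catalog, pw,
                                              by_species=True)
            for sp, frac in sorted(per_sp.items()):
                cons_rows.append((pw, BAG_OF_GENOMES, sp, frac))
            cons_rows.append((pw, BAG_OF_GENES, "all", pooled))
        _write_tsv(pd.DataFrame(cons_rows, columns=["pathway", "mode", "species",
                                                    "sign_consistency"]),
                   site_dir / "pathway_sign_consistency.tsv")
        logger.info("site %s done: %d taxa kept, %d candidate pathways",
                    site, len(kept_taxa), len(cand_ids))

    # ---- stage 3: cohort-level summaries ----------------------------------
    _write_tsv(summarize_odor_characters(meta), out / "odor_characters.tsv")

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest_outputs[str(path.relative_to(out))] = _sha256(path)
    manifest = {
        "package": "skinmwas",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.fingerprint(),
        "thresholds": dataclasses.asdict(config.thresholds),
        "sites": list(config.sites),
        "strata": list(config.strata),
        "n_perm": config.n_perm,
        "outputs": manifest_outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return manifest
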