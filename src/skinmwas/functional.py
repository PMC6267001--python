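"""Functional MWAS: KO aggregation in pooled and taxon-stratified modes.

The "bag of genes" mode sums community-total gene-family abundances into one
row per KO, discarding taxonomic origin.  The "bag of genomes" mode keeps the
per-taxon strata, yielding one row per (KO, taxon).  The two are linked by an
additivity identity: marginalizing the stratified table over taxa recovers
the pooled table exactly, so the modes differ only in resolution, not mass.

Downstream rules implemented here:

* candidate pathways: FDR-adjusted p < 0.1 in at least two of the six
  (stratum x test) comparisons — three strata (youth, children, teens) times
  two tests (cross-sectional Spearman, longitudinal signed-rank);
* per-(pathway, species) counts of member KOs present and of member KOs whose
  stratified abundance is significantly *positively* correlated with odor;
* within-pathway sign consistency, the diagnostic that separates the two
  modes when related species carry the same enzyme with opposite effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import IncompleteDesignError, MappingError
from .taxa import species_from_stratum

logger = logging.getLogger(__name__)

BAG_OF_GENES = "bag_of_genes"
BAG_OF_GENOMES = "bag_of_genomes"


@dataclass(frozen=True)
class KoCatalog:
    """KO -> pathway catalog: pathway membership lists, one-to-many allowed."""

    pathways: dict  # pathway_id -> tuple of KO ids

    def __post_init__(self):
        for pw, members in self.pathways.items():
            if not members:
                raise MappingError(f"pathway {pw!r} has no member KOs")

    @property
    def pathway_ids(self) -> list:
        return list(self.pathways)

    @property
    def ko_ids(self) -> list:
        seen = {}
        for members in self.pathways.values():
            for k in members:
                seen.setdefault(k, None)
        return list(seen)

    def ko_to_pathways(self) -> dict:
        out: dict[str, list] = {}
        for pw, members in self.pathways.items():
            for k in members:
                out.setdefault(k, []).append(pw)
        return out

    @classmethod
    def from_tsv(cls, path) -> "KoCatalog":
        """Read a two-column (pathway, KO) TSV; '#' comment lines allowed."""
        pathways: dict[str, list] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise MappingError(f"{path}: line {ln}: expected 2 columns, got {len(parts)}")
                pw, ko = parts
                pathways.setdefault(pw, []).append(ko)
        if not pathways:
            raise MappingError(f"{path}: empty KO->pathway catalog")
        return cls({pw: tuple(ks) for pw, ks in pathways.items()})


def default_catalog() -> KoCatalog:
    """The bundled toy KO->pathway catalog (stand-ins for branched-chain
    amino-acid biosynthesis/degradation, pyruvate metabolism, and decoys)."""
    path = resources.files("skinmwas.data").joinpath("ko_to_pathway.tsv")
    with resources.as_file(path) as p:
        return KoCatalog.from_tsv(p)


@dataclass
class KoMap:
    """Gene-family -> KO mapping plus the KO -> pathway catalog."""

    family_to_ko: dict  # family -> KO id or None (unmapped)
    catalog: KoCatalog = field(default_factory=default_catalog)

    def __post_init__(self):
        known = set(self.catalog.ko_ids)
        dangling = {k for k in self.family_to_ko.values() if k is not None and k not in known}
        if dangling:
            raise MappingError(
                f"family map references KOs absent from the catalog: {sorted(dangling)}")

    @classmethod
    def from_tsv(cls, family_path, catalog: KoCatalog | None = None) -> "KoMap":
        fam: dict[str, str | None] = {}
        with open(family_path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise MappingError(
                        f"{family_path}: line {ln}: expected 2 columns, got {len(parts)}")
                family, ko = parts
                if family in fam:
                    raise MappingError(f"{family_path}: line {ln}: duplicate family {family!r}")
                fam[family] = ko if ko not in ("", "NA", "unmapped") else None
        return cls(fam, catalog or default_catalog())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# Gene Family\tKO\n")
            for family, ko in self.family_to_ko.items():
                fh.write(f"{family}\t{ko if ko is not None else 'unmapped'}\n")


def aggregate_to_ko(genes: pd.DataFrame, komap: KoMap, mode: str = BAG_OF_GENOMES,
                    ) -> pd.DataFrame:
    """Aggregate a stratified gene-family table to KO level.

    ``bag_of_genes`` sums the community TOTAL rows of all families mapping to
    each KO (index: KO).  ``bag_of_genomes`` sums within each (KO, stratum),
    strata being taxa plus 'unclassified' (index: (KO, stratum) MultiIndex).
    Unmapped families are dropped; their count is logged.
    """
    if mode not in (BAG_OF_GENES, BAG_OF_GENOMES):
        raise ValueError(f"unknown mode {mode!r}")
    if not komap.family_to_ko:
        raise MappingError("empty gene-family -> KO mapping")
    fams_in_table = genes.index.get_level_values("gene_family")
    mapped = fams_in_table.map(lambda f: komap.family_to_ko.get(f))
    n_unmapped = len({f for f, k in zip(fams_in_table, mapped) if k is None})
    if n_unmapped:
        logger.info("aggregate_to_ko: dropping %d unmapped gene families", n_unmapped)

    work = genes.copy()
    work["_ko"] = mapped
    work = work[work["_ko"].notna()]
    if mode == BAG_OF_GENES:
        total = work.xs("TOTAL", level="stratum")
        out = total.groupby("_ko").sum()
        out.index.name = "ko"
    else:
        strata = work[work.index.get_level_values("stratum") != "TOTAL"]
        out = strata.groupby(["_ko", strata.index.get_level_values("stratum")]).sum()
        out.index.names = ["ko", "stratum"]
    return out


def marginalize_strata(ko_strat: pd.DataFrame) -> pd.DataFrame:
    """Sum a (KO, stratum) table over strata -> community KO table."""
    out = ko_strat.groupby(level="ko").sum()
    return out


@dataclass
class PathwayCandidate:
    pathway_id: str
    q_values: dict  # (stratum, test) -> q
    n_hits: int
    candidate: bool


def pathway_candidate_rule(qtable: pd.DataFrame, q_threshold: float = 0.1,
                           min_hits: int = 2) -> pd.DataFrame:
    """Apply the two-of-six candidate rule to a pathway x comparison q-table.

    ``qtable`` has one row per pathway and six columns, one per
    (stratum, test) comparison: {youth, children, teens} x {spearman,
    wilcoxon}.  A pathway is a candidate when at least ``min_hits`` of its
    adjusted p-values fall below ``q_threshold``.  NaN cells (e.g. a pathway
    skipped as constant in one stratum) never count as hits.
    """
    if qtable.shape[1] != 6:
        raise IncompleteDesignError(
            f"expected 6 (stratum, test) comparisons per pathway, got {qtable.shape[1]}: "
            f"{list(qtable.columns)}")
    hits = (qtable < q_threshold).sum(axis=1)
    out = qtable.copy()
    out["n_hits"] = hits
    out["candidate"] = hits >= min_hits
    return out


def count_significant_kos(pathway: str, species: str, ko_table: pd.DataFrame,
                          assoc: pd.DataFrame, catalog: KoCatalog,
                          q_threshold: float = 0.1, rho_threshold: float = 0.2,
                          ) -> tuple[int, int]:
    """Count a pathway's member KOs present in *species* and those whose
    stratified abundance is significantly positively odor-correlated.

    ``ko_table`` is the bag-of-genomes (KO, stratum) abundance table used to
    decide presence (detected in >= 1 sample); ``assoc`` is the association
    table over its flattened 'ko|stratum' features, with columns ``feature``,
    ``rho`` and ``q_spearman``.
    """
    if pathway not in catalog.pathways:
        raise MappingError(f"unknown pathway {pathway!r}")
    members = catalog.pathways[pathway]
    present = set()
    for (ko, stratum) in ko_table.index:
        if ko in members and species_from_stratum(stratum) == species:
            if (ko_table.loc[(ko, stratum)] > 0).any():
                present.add((ko, stratum))
    n_present = len({ko for ko, _ in present})
    sig = assoc.set_index("feature") if "feature" in assoc.columns else assoc
    n_sig = 0
    for ko, stratum in present:
        feat = f"{ko}|{stratum}"
        if feat not in sig.index:
            continue
        row = sig.loc[feat]
        if row["q_spearman"] < q_threshold and row["rho"] > rho_threshold:
            n_sig += 1
    return n_present, n_sig


def pathway_sign_consistency(assoc: pd.DataFrame, catalog: KoCatalog, pathway: str,
                             by_species: bool = False):
    """Fraction of a pathway's member KOs sharing the majority Spearman sign.

    With ``by_species`` (bag-of-genomes results whose features are
    'ko|stratum'), returns a dict species -> fraction; otherwise a single
    float over the pooled member-KO correlations.  Fewer than two member KOs
    with a defined, nonzero correlation is undefined: NaN with a log message.
    """
    if pathway not in catalog.pathways:
        raise MappingError(f"unknown pathway {pathway!r}")
    members = set(catalog.pathways[pathway])
    table = assoc.set_index("feature") if "feature" in assoc.columns else assoc

    def _fraction(rhos: np.ndarray) -> float:
        rhos = rhos[np.isfinite(rhos) & (rhos != 0)]
        if len(rhos) < 2:
            logger.info("sign consistency undefined for %s: < 2 usable KOs", pathway)
            return float("nan")
        n_pos = int((rhos > 0).sum())
        return max(n_pos, len(rhos) - n_pos) / len(rhos)

    if not by_species:
        rhos = np.array([table.loc[f, "rho"] for f in table.index
                         if f.split("|", 1)[0] in members])
        return _fraction(rhos)
    groups: dict[str, list] = {}
    for feat in table.index:
        ko, _, stratum = feat.partition("|")
        if ko in members and stratum:
            groups.setdefault(species_from_stratum(stratum), []).append(table.loc[feat, "rho"])
    return {sp: _fraction(np.array(v)) for sp, v in groups.items()}
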