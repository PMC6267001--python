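"""Readers, writers and abundance/coverage filters for the profile dialects.

Three tab-separated dialects are supported, mirroring the outputs of the
common profiling tools they emulate:

* merged taxonomic table — first column a full rank-prefixed clade string
  (``k__...|g__Genus|s__Genus_species``), one column per sample, values in
  percent relative abundance;
* stratified gene-family table — header ``# Gene Family``; rows are either a
  bare family id (community total) or ``FAMILY|g__Genus.s__species`` /
  ``FAMILY|unclassified`` strata, values in RPK;
* pathway abundance and coverage tables — one row per pathway.

Filters implement the abundance gates applied before association testing:
taxa kept when mean relative abundance exceeds 1% in either age group at the
site; gene families kept when the community mean RPK exceeds 10 in either
group (survivors re-normalized per sample to relative abundances); pathways
kept when mean coverage across all the site's samples exceeds 0.3.  All
inequalities are strict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FilterError, ParseError
from .simulate import PathwayTable

_META_COLUMNS = ["sample_id", "subject_id", "age_group", "sex", "site",
                 "timepoint", "odor_intensity", "odor_characters"]

_FLOAT_FORMAT = "%.6g"  # round-trip lossless at 6 significant digits


# ---------------------------------------------------------------------------
# generic TSV plumbing

def _read_table(path, first_col: str) -> pd.DataFrame:
    """Read a dialect table: first line (possibly '#'-prefixed) is the header,
    later '#' lines are comments.  Returns a string-indexed float frame."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].lstrip("# ").split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: header has no sample columns")
    samples = header[1:]
    dup = {s for s in samples if samples.count(s) > 1}
    if dup:
        raise ParseError(f"{path}: line 1: duplicated sample column(s) {sorted(dup)}")
    index, data = [], []
    for ln, line in enumerate(lines[1:], 2):
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"{path}: line {ln}: expected {len(header)} columns, got {len(parts)}")
        try:
            data.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: non-numeric cell ({exc})") from None
        index.append(parts[0])
    dup_rows = {k for k in index if index.count(k) > 1}
    if dup_rows:
        raise ParseError(f"{path}: duplicate row key(s) {sorted(dup_rows)[:5]}")
    df = pd.DataFrame(data, index=index, columns=samples)
    df.index.name = first_col
    return df


def _write_table(df: pd.DataFrame, path, first_col: str) -> None:
    out = df.copy()
    out.index.name = first_col
    out.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# metadata

def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the per-sample design + phenotype table."""
    meta = pd.read_csv(path, sep="\t", dtype={"odor_characters": str})
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample_id(s) {dups[:5]}")
    key = meta[["subject_id", "site", "timepoint"]]
    if key.duplicated().any():
        raise ParseError(f"{path}: duplicate (subject, site, timepoint) records")
    per_pair = meta.groupby(["subject_id", "site"])["timepoint"].nunique()
    if (per_pair > 2).any():
        raise ParseError(f"{path}: a (subject, site) pair has more than 2 timepoints")
    odor = meta["odor_intensity"]
    if ((odor < 0) | (odor > 100)).any():
        raise ParseError(f"{path}: odor_intensity outside [0, 100]")
    return meta


# ---------------------------------------------------------------------------
# taxon table (merged-profiler dialect)

def write_taxon_table(table: pd.DataFrame, path) -> None:
    _write_table(table, path, "#clade_name")


def read_taxon_table(path) -> pd.DataFrame:
    """Read a merged clade x sample relative-abundance table (percent)."""
    df = _read_table(path, "clade_name")
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative relative abundance")
    # per-sample totals within one rank must not exceed 100; the tolerance
    # covers 6-significant-digit serialization rounding
    species = df[[("s__" in ix) for ix in df.index]]
    if len(species) and (species.sum(axis=0) > 100 + 0.01).any():
        raise ParseError(f"{path}: species relative abundances sum above 100")
    return df


def parse_clade_ranks(clade: str) -> dict:
    """Split a clade string into a rank-prefix -> name mapping."""
    out = {}
    for part in clade.split("|"):
        if len(part) > 3 and part[1:3] == "__":
            out[part[0]] = part[3:]
    return out


# ---------------------------------------------------------------------------
# stratified gene-family table

def write_stratified_gene_table(genes: pd.DataFrame, path) -> None:
    flat = genes.copy()
    flat.index = [fam if stratum == "TOTAL" else f"{fam}|{stratum}"
                  for fam, stratum in genes.index]
    _write_table(flat, path, "# Gene Family")


def read_stratified_gene_table(path) -> pd.DataFrame:
    """Read a stratified gene-family RPK table into a (family, stratum)
    MultiIndex frame; community rows get the stratum label 'TOTAL'."""
    df = _read_table(path, "gene_family")
    keys = []
    for row in df.index:
        fam, _, stratum = row.partition("|")
        keys.append((fam, stratum if stratum else "TOTAL"))
    df.index = pd.MultiIndex.from_tuples(keys, names=["gene_family", "stratum"])
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative RPK value")
    totals = df.xs("TOTAL", level="stratum")
    for (fam, stratum) in df.index:
        if stratum == "TOTAL":
            continue
        if fam not in totals.index:
            raise ParseError(f"{path}: stratum row {fam}|{stratum} lacks a community row")
    strata_sum = df[df.index.get_level_values("stratum") != "TOTAL"].groupby("gene_family").sum()
    aligned = totals.reindex(strata_sum.index)
    # tolerance covers 6-significant-digit serialization rounding per stratum
    if ((strata_sum - aligned) > 1e-5 * aligned.abs() + 0.01).any().any():
        raise ParseError(f"{path}: strata exceed the community total for some family")
    return df


# ---------------------------------------------------------------------------
# pathway tables

def write_pathway_tables(paths: PathwayTable, abundance_path, coverage_path) -> None:
    _write_table(paths.abundance, abundance_path, "# Pathway")
    _write_table(paths.coverage, coverage_path, "# Pathway")


def read_pathway_tables(abundance_path, coverage_path) -> PathwayTable:
    ab = _read_table(abundance_path, "pathway")
    cov = _read_table(coverage_path, "pathway")
    if list(ab.index) != list(cov.index) or list(ab.columns) != list(cov.columns):
        raise ParseError("pathway abundance and coverage tables are not aligned")
    if ((cov.to_numpy() < 0) | (cov.to_numpy() > 1)).any():
        raise ParseError(f"{coverage_path}: coverage outside [0, 1]")
    return PathwayTable(abundance=ab, coverage=cov)


# ---------------------------------------------------------------------------
# filters

def _group_samples(meta: pd.DataFrame, site: str | None) -> dict:
    sub = meta if site is None else meta[meta["site"] == site]
    groups = {}
    for grp in ("children", "teens"):
        ids = sub.loc[sub["age_group"] == grp, "sample_id"].tolist()
        if not ids:
            raise FilterError(f"empty stratum {grp!r}"
                              + (f" at site {site!r}" if site else ""))
        groups[grp] = ids
    return groups


def filter_taxa_by_abundance(taxa: pd.DataFrame, meta: pd.DataFrame,
                             threshold: float = 1.0, site: str | None = None,
                             ) -> pd.DataFrame:
    """Keep taxa whose mean relative abundance exceeds ``threshold`` percent
    in either age group over the site's samples.  Values and row order are
    preserved; columns are restricted to the site's samples."""
    groups = _group_samples(meta, site)
    cols = [s for ids in groups.values() for s in ids]
    sub = taxa[cols]
    keep = np.zeros(len(sub), dtype=bool)
    for ids in groups.values():
        keep |= sub[ids].mean(axis=1).to_numpy() > threshold
    return sub[keep]


def filter_gene_families(genes: pd.DataFrame, meta: pd.DataFrame,
                         min_mean_rpk: float = 10.0, site: str | None = None,
                         ) -> pd.DataFrame:
    """Keep gene families whose community (TOTAL) mean RPK exceeds
    ``min_mean_rpk`` in either age group, then re-normalize survivors per
    sample so the TOTAL rows sum to 1.

    All strata of a surviving family are scaled by the same per-sample
    factor, preserving the stratified-additivity identity.
    """
    groups = _group_samples(meta, site)
    cols = [s for ids in groups.values() for s in ids]
    sub = genes[cols]
    totals = sub.xs("TOTAL", level="stratum")
    keep = np.zeros(len(totals), dtype=bool)
    for ids in groups.values():
        keep |= totals[ids].mean(axis=1).to_numpy() > min_mean_rpk
    kept_fams = set(totals.index[keep])
    if not kept_fams:
        raise EmptyResultError(
            f"no gene family passes mean RPK > {min_mean_rpk} in either group")
    out = sub[[fam in kept_fams for fam in sub.index.get_level_values("gene_family")]]
    denom = out.xs("TOTAL", level="stratum").sum(axis=0)
    scale = np.where(denom.to_numpy() > 0, 1.0 / denom.to_numpy(), 0.0)
    return out * scale


def filter_pathways_by_coverage(paths: PathwayTable, min_mean_cov: float = 0.3,
                                meta: pd.DataFrame | None = None,
                                site: str | None = None) -> list:
    """Pathway ids whose mean coverage across all the (site's) samples
    exceeds ``min_mean_cov``; both age groups and timepoints pooled."""
    cov = paths.coverage
    if meta is not None and site is not None:
        cols = meta.loc[meta["site"] == site, "sample_id"].tolist()
        if not cols:
            raise FilterError(f"no samples at site {site!r}")
        cov = cov[cols]
    mean_cov = cov.mean(axis=1)
    return [pw for pw, m in mean_cov.items() if m > min_mean_cov]
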