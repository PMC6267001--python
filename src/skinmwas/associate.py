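"""Dual-mode feature-phenotype association with FDR and significance calls.

For each feature (taxon, KO stratum, or pathway) at one body site and one age
stratum ('youth' pools children and teens):

* cross-sectional: Spearman correlation between abundance and odor intensity
  over all the stratum's samples at that site, both timepoints pooled;
* longitudinal: Wilcoxon signed-rank over subject-paired first/second
  timepoint abundances, with the direction arrow from the sign of the median
  paired difference.

Benjamini-Hochberg adjustment is applied across features separately within
each (site, stratum, test) family.  A feature is called significant when its
adjusted Spearman p-value is below ``q_threshold`` and |rho| exceeds
``rho_threshold``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConstantInputError, PairingError
from .stats import bh_adjust, spearman, wilcoxon_signed_rank

logger = logging.getLogger(__name__)

YOUTH = "youth"
STRATA = (YOUTH, "children", "teens")

UP, DOWN, NONE = "up", "down", "none"


def _stratum_meta(meta: pd.DataFrame, site: str, stratum: str) -> pd.DataFrame:
    sub = meta[meta["site"] == site]
    if stratum != YOUTH:
        sub = sub[sub["age_group"] == stratum]
    return sub


def associate_features(features: pd.DataFrame, meta: pd.DataFrame, site: str,
                       stratum: str, q_threshold: float = 0.1,
                       rho_threshold: float = 0.2) -> pd.DataFrame:
    """Associate every feature (row) of ``features`` with odor intensity.

    ``features`` is a feature x sample abundance table whose columns cover
    the selected samples.  Returns a tidy frame with one row per testable
    feature: rho, raw and adjusted p-values for both tests, the direction of
    the post-exercise change, and the significance call.  Features constant
    across the selected samples are excluded with a logged reason (listed in
    ``result.attrs['skipped']``), not an error.
    """
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}, got {stratum!r}")
    sub = _stratum_meta(meta, site, stratum)
    subjects = sub["subject_id"].unique()
    if len(subjects) < 3:
        raise ValueError(
            f"need >= 3 subjects at ({site}, {stratum}), got {len(subjects)}")
    missing = [s for s in sub["sample_id"] if s not in features.columns]
    if missing:
        raise PairingError(f"features table lacks samples: {missing[:5]}...")

    tps = list(dict.fromkeys(sub["timepoint"]))  # order of appearance
    if len(tps) != 2:
        raise PairingError(f"expected 2 timepoints at ({site}, {stratum}), got {tps}")
    by_subj = sub.pivot_table(index="subject_id", columns="timepoint",
                              values="sample_id", aggfunc="first")
    unpaired = by_subj.index[by_subj.isna().any(axis=1)].tolist()
    if unpaired:
        raise PairingError(f"subjects missing a timepoint at ({site}, {stratum}): {unpaired}")
    before_ids = by_subj[tps[0]].tolist()
    after_ids = by_subj[tps[1]].tolist()

    sample_ids = sub["sample_id"].tolist()
    odor = sub.set_index("sample_id")["odor_intensity"]

    rows, skipped = [], []
    for feat in features.index:
        x = features.loc[feat, sample_ids].to_numpy(dtype=float)
        try:
            rho, p_s = spearman(x, odor[sample_ids].to_numpy())
        except ConstantInputError:
            skipped.append(feat)
            logger.info("associate_features: skipping constant feature %r at (%s, %s)",
                        feat, site, stratum)
            continue
        before = features.loc[feat, before_ids].to_numpy(dtype=float)
        after = features.loc[feat, after_ids].to_numpy(dtype=float)
        stat_w, p_w = wilcoxon_signed_rank(before, after)
        med = float(np.median(after - before))
        direction = UP if med > 0 else DOWN if med < 0 else NONE
        rows.append((feat, site, stratum, rho, p_s, p_w, direction))

    feat_label = features.index.name or "feature"
    out = pd.DataFrame(rows, columns=["feature", "site", "stratum", "rho",
                                      "p_spearman", "p_wilcoxon", "direction"])
    if len(out):
        out["q_spearman"] = bh_adjust(out["p_spearman"].to_numpy())
        out["q_wilcoxon"] = bh_adjust(out["p_wilcoxon"].to_numpy())
        out["significant"] = (out["q_spearman"] < q_threshold) & \
            (out["rho"].abs() > rho_threshold)
    else:
        out["q_spearman"] = out["q_wilcoxon"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    out = out[["feature", "site", "stratum", "rho", "p_spearman", "q_spearman",
               "p_wilcoxon", "q_wilcoxon", "direction", "significant"]]
    out.attrs["skipped"] = skipped
    out.attrs["feature_kind"] = feat_label
    return out


def associate_all(features: pd.DataFrame, meta: pd.DataFrame, site: str,
                  strata=STRATA, q_threshold: float = 0.1,
                  rho_threshold: float = 0.2) -> pd.DataFrame:
    """Run :func:`associate_features` for several strata and concatenate."""
    parts = [associate_features(features, meta, site, s, q_threshold, rho_threshold)
             for s in strata]
    out = pd.concat(parts, ignore_index=True)
    out.attrs["skipped"] = sorted({f for p in parts for f in p.attrs["skipped"]})
    return out


def render_table(assoc: pd.DataFrame, q_threshold: float = 0.1) -> pd.DataFrame:
    """Human-readable view: 'n.s.' for adjusted p above threshold, arrows
    for direction.  Machine consumers should use the numeric frame."""
    view = assoc.copy()
    arrow = {UP: "↑", DOWN: "↓", NONE: "-"}
    view["direction"] = view["direction"].map(arrow)
    for col in ("q_spearman", "q_wilcoxon"):
        view[col] = [f"{q:.2g}" if q < q_threshold else "n.s." for q in assoc[col]]
    view["rho"] = [f"{r:.2f}" for r in assoc["rho"]]
    return view[["feature", "site", "stratum", "rho", "q_spearman",
                 "q_wilcoxon", "direction", "significant"]]
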