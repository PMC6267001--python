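"""Synthetic skin-microbiome cohort generator with a planted-effect ledger.

The generator emulates a two-age-group malodor study: children and teenagers
(15 subjects each by default), sampled at three body sites (underarm, neck,
head) at two timepoints (1 h after shower and 8 h, after exercise), with a
perfumer-style odor-intensity score on a 0-100 scale per sample.  Default
design: 30 subjects x 3 sites x 2 timepoints = 180 samples.

Species relative abundances are drawn from a logistic-normal composition
closed to 100%.  Selected ("planted") species are coupled to the odor score
through a shared Gaussian latent factor (a Gaussian copula): the generator
converts a requested Spearman correlation into a Gaussian loading via the
Greiner relation r = 2 sin(pi * rho / 6), inflated by a fixed calibration
factor that compensates the rank-correlation attenuation introduced by
compositional closure, odor noise, and the detection floor.  Everything else
(null species, gene-family noise) is independent of the phenotype, giving
calibrated null features for FDR checks.

All randomness flows from a single integer seed through labeled per-stage
streams (see :mod:`skinmwas._rng`), so identical configurations reproduce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .errors import AlignmentError, ConfigError
from .functional import KoCatalog, default_catalog
from .taxa import clade_string, species_from_clade, stratum_token

CHILDREN = "children"
TEENS = "teens"
GROUPS = (CHILDREN, TEENS)


@dataclass(frozen=True)
class PlantedEffect:
    """One planted taxon-phenotype association.

    ``target_spearman`` is the signed rank correlation the generator aims for
    between the taxon's relative abundance and odor intensity among the
    samples of ``site`` restricted to ``stratum`` ('children', 'teens' or
    'both').  ``exercise_shift`` multiplies the taxon's latent abundance at
    the second timepoint before compositional closure, producing the paired
    longitudinal signal.  ``linked_kos`` are forced into the taxon's KO
    repertoire so its functional strata inherit the association.
    """

    taxon: str
    site: str
    stratum: str = "both"
    target_spearman: float = 0.6
    exercise_shift: float = 1.5
    linked_kos: tuple[str, ...] = ()
    mean_log_abundance: float = 0.5
    #: reuse another planted taxon's latent factor (negated when the two
    #: targets have opposite signs), e.g. for competition-style opposed pairs
    latent_anchor: str | None = None

    @property
    def effect_direction(self) -> str:
        return "+" if self.target_spearman >= 0 else "-"


_DEFAULT_PLANTED = (
    PlantedEffect("Staphylococcus_epidermidis", "underarm", "both", 0.65, 2.2,
                  ("K01652", "K00826", "K00161", "K00162", "K01760")),
    PlantedEffect("Cutibacterium_avidum", "underarm", "both", 0.50, 1.8,
                  ("K00645", "K02160")),
    PlantedEffect("Staphylococcus_hominis", "neck", "children", 0.60, 2.0,
                  ("K00826", "K00166", "K00627", "K01760")),
    PlantedEffect("Cutibacterium_granulosum", "neck", "both", -0.40, 0.5,
                  ("K00134", "K00927")),
    PlantedEffect("Acinetobacter_schindleri", "neck", "both", -0.35, 0.6,
                  ("K00059",)),
)

# Expected perfumer score per (site, age group, timepoint): underarm odor is
# strongest and rises most after exercise; teens exceed children there.
_DEFAULT_BASELINES = {
    ("underarm", CHILDREN, "1h"): 30.0, ("underarm", CHILDREN, "8h"): 50.0,
    ("underarm", TEENS, "1h"): 45.0, ("underarm", TEENS, "8h"): 65.0,
    ("neck", CHILDREN, "1h"): 25.0, ("neck", CHILDREN, "8h"): 33.0,
    ("neck", TEENS, "1h"): 28.0, ("neck", TEENS, "8h"): 38.0,
    ("head", CHILDREN, "1h"): 24.0, ("head", CHILDREN, "8h"): 32.0,
    ("head", TEENS, "1h"): 20.0, ("head", TEENS, "8h"): 26.0,
}

#: Residual copula inflation applied after the analytic mixture correction,
#: compensating rank-correlation attenuation from compositional closure and
#: the detection floor; frozen from a Monte-Carlo calibration of realized
#: vs. target Spearman at default settings.
COPULA_INFLATION = 1.05


@dataclass
class SimConfig:
    """Full description of one synthetic cohort; see module docstring."""

    n_children: int = 15
    n_teens: int = 15
    #: (female, male) counts per group; defaults mirror an 8F/7M recruitment.
    sex_split: dict = field(default_factory=lambda: {CHILDREN: (8, 7), TEENS: (8, 7)})
    sites: tuple[str, ...] = ("underarm", "neck", "head")
    timepoints: tuple[str, ...] = ("1h", "8h")
    n_taxa: int = 30
    n_null_taxa: int | None = None  # derived as n_taxa - len(planted) if None
    planted_taxa: tuple[PlantedEffect, ...] = _DEFAULT_PLANTED
    n_gene_families: int = 80
    ko_catalog: KoCatalog | None = None  # None -> bundled toy catalog
    sigma_log_abundance: float = 1.0
    sigma_odor_noise: float = 5.0
    sigma_subject: float = 5.0
    odor_baseline: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINES))
    detection_floor: float = 0.001  # percent; abundances below are zeroed
    unclassified_fraction: float = 0.10
    rpk_scale: float = 200.0
    sigma_rpk: float = 0.3
    #: log-sd of the per-(family, species) copy factor
    sigma_copy_factor: float = 0.3
    ko_carry_prob: float = 0.4
    #: when True, planted taxa carry exactly their linked KOs
    exclusive_repertoires: bool = False
    subject_persistence: float = 0.5  # latent corr between a subject's 1h/8h
    copula_inflation: float = COPULA_INFLATION
    seed: int = 0

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_children < 2:
            raise ConfigError(f"n_children must be >= 2, got {self.n_children}")
        if self.n_teens < 2:
            raise ConfigError(f"n_teens must be >= 2, got {self.n_teens}")
        if len(self.timepoints) != 2:
            raise ConfigError(f"timepoints must have exactly 2 entries, got {self.timepoints}")
        for name in ("sigma_log_abundance", "sigma_odor_noise", "sigma_subject", "sigma_rpk"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for grp, n in ((CHILDREN, self.n_children), (TEENS, self.n_teens)):
            split = self.sex_split.get(grp)
            if split is None or sum(split) != n:
                raise ConfigError(f"sex_split[{grp!r}] must sum to {n}, got {split}")
        names = [e.taxon for e in self.planted_taxa]
        if len(set(names)) != len(names):
            raise ConfigError(f"planted_taxa contains duplicate taxa: {names}")
        if len(names) > self.n_taxa:
            raise ConfigError(
                f"n_taxa={self.n_taxa} smaller than {len(names)} planted taxa")
        if self.n_null_taxa is not None and len(names) + self.n_null_taxa != self.n_taxa:
            raise ConfigError(
                f"n_null_taxa={self.n_null_taxa} inconsistent with n_taxa={self.n_taxa} "
                f"and {len(names)} planted taxa")
        for e in self.planted_taxa:
            if abs(e.target_spearman) > 0.95:
                raise ConfigError(
                    f"planted_taxa[{e.taxon}].target_spearman must satisfy |rho| <= 0.95")
            if e.exercise_shift <= 0:
                raise ConfigError(f"planted_taxa[{e.taxon}].exercise_shift must be > 0")
            if e.site not in self.sites:
                raise ConfigError(f"planted_taxa[{e.taxon}].site {e.site!r} not in sites")
            if e.stratum not in (*GROUPS, "both"):
                raise ConfigError(f"planted_taxa[{e.taxon}].stratum {e.stratum!r} invalid")
            if e.latent_anchor is not None:
                anchors = {a.taxon: a for a in self.planted_taxa}
                if e.latent_anchor not in anchors or e.latent_anchor == e.taxon:
                    raise ConfigError(
                        f"planted_taxa[{e.taxon}].latent_anchor must name another "
                        "planted taxon")
                anchor = anchors[e.latent_anchor]
                if anchor.site != e.site or anchor.stratum != e.stratum:
                    raise ConfigError(
                        f"planted_taxa[{e.taxon}].latent_anchor must share site "
                        "and stratum")
                if anchor.latent_anchor is not None:
                    raise ConfigError(
                        f"planted_taxa[{e.taxon}].latent_anchor must be an "
                        "un-anchored effect")
                if abs(abs(anchor.target_spearman) - abs(e.target_spearman)) > 1e-9:
                    raise ConfigError(
                        f"planted_taxa[{e.taxon}] and its latent_anchor must have "
                        "equal |target_spearman| (they share one latent factor)")
        for site in self.sites:
            for grp in GROUPS:
                for tp in self.timepoints:
                    if (site, grp, tp) not in self.odor_baseline:
                        raise ConfigError(f"odor_baseline missing ({site}, {grp}, {tp})")
        self._solve_loadings()  # raises ConfigError when jointly unattainable
        if not 0 <= self.unclassified_fraction < 1:
            raise ConfigError(
                f"unclassified_fraction must be in [0, 1), got {self.unclassified_fraction}")

    # -- derived quantities ----------------------------------------------
    @property
    def null_taxon_names(self) -> tuple[str, ...]:
        n_null = self.n_taxa - len(self.planted_taxa)
        genera = ("Moraxella", "Streptococcus", "Micrococcus", "Corynebacterium",
                  "Staphylococcus", "Cutibacterium")
        return tuple(f"{genera[i % len(genera)]}_nullsp_{i + 1:02d}" for i in range(n_null))

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(e.taxon for e in self.planted_taxa) + self.null_taxon_names

    def catalog(self) -> KoCatalog:
        return self.ko_catalog if self.ko_catalog is not None else default_catalog()

    def _active_effects(self, site: str, group: str) -> list[PlantedEffect]:
        return [e for e in self.planted_taxa
                if e.site == site and e.stratum in (group, "both")]

    def _anchor_root(self, effect: PlantedEffect) -> str:
        return effect.latent_anchor if effect.latent_anchor is not None else effect.taxon

    def _cell_s(self, loadings: dict, site: str, group: str) -> float:
        """Fraction of odor variance from planted latents in one cell.

        Effects sharing a latent anchor ride one factor, so each anchor
        group contributes a single squared loading.
        """
        roots = {self._anchor_root(a): abs(loadings[a.taxon])
                 for a in self._active_effects(site, group)}
        return sum(r * r for r in roots.values())

    def _solve_loadings(self) -> dict[str, float]:
        """Per-effect Gaussian latent loading hitting the target Spearman.

        The target is evaluated on the effect's stratum pooled over both
        timepoints, i.e. on a mixture of (group, timepoint) cells whose odor
        baselines and exercise log-shifts differ.  Writing the within-cell
        latent correlation as r and matching the pooled Gaussian correlation
        to the Greiner-transformed target G = 2 sin(pi * rho / 6) gives

            r = (G * sqrt((E[V] + Var(mu_o)) * (sigma^2 + Var(s)))
                 - Cov(mu_o, s)) / (sigma * E[sqrt(V)])

        with V the within-cell odor variance (itself s0^2 / (1 - sum r^2)
        over the cell's active effects), mu_o the cell odor baselines and s
        the cell log exercise shifts.  Solved by fixed-point iteration; a
        residual multiplicative calibration (``copula_inflation``) absorbs
        closure/floor attenuation the Gaussian algebra cannot see.
        """
        s0sq = self.sigma_subject ** 2 + self.sigma_odor_noise ** 2
        sigma = self.sigma_log_abundance
        n_by_group = {CHILDREN: self.n_children, TEENS: self.n_teens}
        loadings = {
            e.taxon: 2.0 * math.sin(math.pi * e.target_spearman / 6.0)
            for e in self.planted_taxa
        }
        if not loadings:
            return loadings

        def cell_var(site, grp):
            # cap S during iteration; infeasibility is checked after convergence
            return s0sq / (1.0 - min(0.97, self._cell_s(loadings, site, grp)))

        for _ in range(40):
            new = {}
            for e in self.planted_taxa:
                groups = GROUPS if e.stratum == "both" else (e.stratum,)
                cells, weights = [], []
                for g in groups:
                    for tp, shift in zip(self.timepoints, (0.0, math.log(e.exercise_shift))):
                        cells.append((self.odor_baseline[(e.site, g, tp)], shift,
                                      cell_var(e.site, g)))
                        weights.append(n_by_group[g])
                w = np.array(weights, dtype=float)
                w /= w.sum()
                mu_o = np.array([c[0] for c in cells])
                s_x = np.array([c[1] for c in cells])
                v = np.array([c[2] for c in cells])
                var_mu_o = float(w @ mu_o ** 2 - (w @ mu_o) ** 2)
                var_s = float(w @ s_x ** 2 - (w @ s_x) ** 2)
                cov_mu = float(w @ (mu_o * s_x) - (w @ mu_o) * (w @ s_x))
                g_target = (2.0 * math.sin(math.pi * e.target_spearman / 6.0)
                            * self.copula_inflation)
                num = g_target * math.sqrt((float(w @ v) + var_mu_o)
                                           * (sigma ** 2 + var_s)) - cov_mu
                r = num / (sigma * float(w @ np.sqrt(v)))
                r = math.copysign(min(abs(r), 0.995), r)
                # damped update for a stable fixed point
                new[e.taxon] = 0.5 * loadings[e.taxon] + 0.5 * r
            if max(abs(new[t] - loadings[t]) for t in new) < 1e-10:
                loadings = new
                break
            loadings = new
        for site in self.sites:
            for grp in GROUPS:
                if self._cell_s(loadings, site, grp) > 0.97:
                    raise ConfigError(
                        f"planted_taxa targets at ({site}, {grp}) jointly unattainable "
                        "(sum of squared latent loadings > 0.97)")
        return loadings

    def _latent_loading(self, effect: PlantedEffect) -> float:
        """Solved Gaussian-copula loading for one effect's target Spearman."""
        return self._solve_loadings()[effect.taxon]

    def _odor_loadings(self, site: str, group: str) -> dict[str, float]:
        """Score-scale coefficient of each active effect's latent in the odor
        model: with s0^2 the non-planted odor variance and S the sum of
        squared loadings in the cell, V = s0^2 / (1 - S) and c_e = r_e *
        sqrt(V), so corr(latent_e, odor) = r_e within the cell."""
        active = self._active_effects(site, group)
        s0sq = self.sigma_subject ** 2 + self.sigma_odor_noise ** 2
        solved = self._solve_loadings()
        s = self._cell_s(solved, site, group)
        v = s0sq / (1.0 - s)
        group_size = {}
        for e in active:
            root = self._anchor_root(e)
            group_size[root] = group_size.get(root, 0) + 1
        # members of an anchor group share one latent: split the coefficient
        return {e.taxon: solved[e.taxon] * math.sqrt(v) / group_size[self._anchor_root(e)]
                for e in active}


@dataclass
class RealizedEffect:
    """A planted effect plus the latent correlation actually encoded."""

    effect: PlantedEffect
    latent_loading: float
    #: Spearman implied by the Gaussian loading (Greiner's inverse relation).
    latent_spearman: float


@dataclass
class GroundTruth:
    """Simulator ledger: what was planted, what is null, and the latents."""

    planted: list[RealizedEffect]
    null_taxa: list[str]
    latents: pd.DataFrame  # samples x planted taxa; shared odor/abundance factor
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "null_taxa": list(self.null_taxa),
            "planted": [
                {**dataclasses.asdict(r.effect),
                 "latent_loading": r.latent_loading,
                 "latent_spearman": r.latent_spearman}
                for r in self.planted
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _implied_spearman(r: float) -> float:
    return (6.0 / math.pi) * math.asin(r / 2.0)


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate per-sample metadata (design + odor phenotype) and ground truth.

    Returns one record per (subject, site, timepoint).  Odor intensity is the
    cell baseline plus a subject random effect, the planted taxa's latent
    contributions, and Gaussian noise, clipped to [0, 100].
    """
    config.validate()
    rng = stage_rng(config.seed, "cohort")

    subjects, groups, sexes = [], [], []
    for grp, prefix, n in ((CHILDREN, "C", config.n_children), (TEENS, "T", config.n_teens)):
        n_f, n_m = config.sex_split[grp]
        for i in range(n):
            subjects.append(f"{prefix}{i + 1:02d}")
            groups.append(grp)
            sexes.append("F" if i < n_f else "M")

    tp1, tp2 = config.timepoints
    rows = []
    for subj, grp, sex in zip(subjects, groups, sexes):
        for site in config.sites:
            for tp in config.timepoints:
                rows.append((f"{subj}_{site}_{tp}", subj, grp, sex, site, tp))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "age_group", "sex", "site", "timepoint"])

    # Shared latent factor per (planted effect, subject, timepoint) at the
    # effect's site, with within-subject persistence between timepoints.
    n_subj = len(subjects)
    phi = config.subject_persistence
    latents = pd.DataFrame(0.0, index=meta["sample_id"],
                           columns=[e.taxon for e in config.planted_taxa])
    for e in config.planted_taxa:
        # draw unconditionally so the stream is stable under anchoring
        z1 = rng.standard_normal(n_subj)
        z2 = phi * z1 + math.sqrt(1.0 - phi * phi) * rng.standard_normal(n_subj)
        for subj, a, b in zip(subjects, z1, z2):
            latents.loc[f"{subj}_{e.site}_{tp1}", e.taxon] = a
            latents.loc[f"{subj}_{e.site}_{tp2}", e.taxon] = b
    for e in config.planted_taxa:
        if e.latent_anchor is not None:
            anchor = next(a for a in config.planted_taxa if a.taxon == e.latent_anchor)
            sign = 1.0 if e.target_spearman * anchor.target_spearman >= 0 else -1.0
            latents[e.taxon] = sign * latents[anchor.taxon]

    subj_effect = dict(zip(subjects, rng.normal(0.0, config.sigma_subject, n_subj)))
    noise = rng.normal(0.0, config.sigma_odor_noise, len(meta))

    odor = np.empty(len(meta))
    planted_contrib = np.zeros(len(meta))
    cell_loadings = {(site, grp): config._odor_loadings(site, grp)
                     for site in config.sites for grp in GROUPS}
    for i, row in enumerate(meta.itertuples(index=False)):
        cell = config.odor_baseline[(row.site, row.age_group, row.timepoint)]
        contrib = 0.0
        for taxon, c in cell_loadings[(row.site, row.age_group)].items():
            contrib += c * latents.at[row.sample_id, taxon]
        planted_contrib[i] = contrib
        odor[i] = cell + subj_effect[row.subject_id] + contrib + noise[i]
    meta["odor_intensity"] = np.clip(odor, 0.0, 100.0)

    meta["odor_characters"] = _odor_characters(config, meta, planted_contrib)

    truth = GroundTruth(
        planted=[
            RealizedEffect(e, config._latent_loading(e),
                           _implied_spearman(config._latent_loading(e)))
            for e in config.planted_taxa
        ],
        null_taxa=list(config.null_taxon_names),
        latents=latents,
        seed=config.seed,
    )
    return meta, truth


def _odor_characters(config: SimConfig, meta: pd.DataFrame,
                     planted_contrib: np.ndarray) -> list[str]:
    """Heuristic sour/sulfur/greasy flags from latent planted contributions.

    Thresholded latent scores: positive planted contributions drive 'sour'
    everywhere and 'sulfur' mostly in teens; 'greasy' is head-specific.  This
    reproduces the shape of character-by-group summaries without any claim of
    chemical realism.
    """
    rng = stage_rng(config.seed, "characters")
    is_teen = (meta["age_group"] == TEENS).to_numpy(float)
    is_head = (meta["site"] == "head").to_numpy(float)
    pos = np.maximum(planted_contrib, 0.0)
    sour = pos + rng.normal(0, 3, len(meta)) - 2.0 > 0
    sulfur = pos * (0.4 + 0.6 * is_teen) + rng.normal(0, 3, len(meta)) - 5.0 > 0
    greasy = 8.0 * is_head + rng.normal(0, 3, len(meta)) - 4.0 > 0
    out = []
    for s, su, g in zip(sour, sulfur, greasy):
        labels = [name for name, flag in (("sour", s), ("sulfur", su), ("greasy", g)) if flag]
        out.append("+".join(labels) if labels else "none")
    return out


def simulate_taxon_profiles(metadata: pd.DataFrame, truth: GroundTruth,
                            config: SimConfig) -> pd.DataFrame:
    """Species relative-abundance table (clade rows x sample columns, percent).

    Log abundances are Gaussian; planted taxa reuse the shared latent factor
    at their site (their only abundance-side noise is compositional), the
    exercise shift scales the second-timepoint latent abundance before
    closure, and values below the detection floor are zeroed with the
    remainder re-closed to 100.
    """
    config.validate()
    if list(truth.latents.index) != list(metadata["sample_id"]):
        raise AlignmentError("metadata and ground-truth latents have different sample sets")
    rng = stage_rng(config.seed, "taxa")

    taxa = config.taxa
    n_null = len(config.null_taxon_names)
    mu_null = rng.normal(0.0, 1.0, n_null)
    eps = rng.standard_normal((len(metadata), len(taxa)))

    mu = np.concatenate([
        np.array([e.mean_log_abundance for e in config.planted_taxa]),
        mu_null,
    ])
    tp2 = config.timepoints[1]
    site_arr = metadata["site"].to_numpy()
    tp_arr = metadata["timepoint"].to_numpy()

    logab = mu[None, :] + config.sigma_log_abundance * eps
    for j, e in enumerate(config.planted_taxa):
        at_site = site_arr == e.site
        z = truth.latents[e.taxon].to_numpy()
        logab[at_site, j] = mu[j] + config.sigma_log_abundance * z[at_site]
        logab[at_site & (tp_arr == tp2), j] += math.log(e.exercise_shift)

    raw = np.exp(logab)
    rel = 100.0 * raw / raw.sum(axis=1, keepdims=True)
    rel[rel < config.detection_floor] = 0.0
    rel = 100.0 * rel / rel.sum(axis=1, keepdims=True)

    table = pd.DataFrame(rel.T, index=[clade_string(t) for t in taxa],
                         columns=metadata["sample_id"])
    table.index.name = "clade_name"
    table.columns.name = None
    return table


@dataclass
class PathwayTable:
    """Per-pathway community abundance (RPK) and coverage in [0, 1]."""

    abundance: pd.DataFrame  # pathways x samples
    coverage: pd.DataFrame   # pathways x samples


def simulate_gene_tables(taxa_table: pd.DataFrame, config: SimConfig,
                         ) -> tuple[pd.DataFrame, PathwayTable]:
    """Taxon-stratified gene-family RPK table plus pathway abundance/coverage.

    Each species carries a fixed binary KO repertoire (planted taxa always
    carry their linked KOs).  A stratified RPK value is the species' relative
    abundance times a per-(family, species) copy factor times log-normal
    noise; an 'unclassified' stratum receives a configurable fraction of each
    family's total, and the community TOTAL row is the exact sum of strata.
    Pathway coverage is the fraction of a pathway's member KOs with nonzero
    community abundance in the sample.
    """
    config.validate()
    catalog = config.catalog()
    rng = stage_rng(config.seed, "genes")

    species = [species_from_clade(c) for c in taxa_table.index]
    kos = catalog.ko_ids
    if config.n_gene_families < len(kos):
        raise ConfigError(
            f"n_gene_families={config.n_gene_families} smaller than KO catalog ({len(kos)})")

    linked = {e.taxon: set(e.linked_kos) for e in config.planted_taxa}
    for taxon, ks in linked.items():
        unknown = ks - set(kos)
        if unknown:
            raise ConfigError(f"linked_kos of {taxon} not in KO catalog: {sorted(unknown)}")

    carry = rng.random((len(species), len(kos))) < config.ko_carry_prob
    ko_index = {k: i for i, k in enumerate(kos)}
    for i, sp in enumerate(species):
        if sp in linked and config.exclusive_repertoires:
            carry[i, :] = False
        for k in linked.get(sp, ()):
            carry[i, ko_index[k]] = True
    # species in an anchor group (opposed competition pairs) share one
    # repertoire, so their per-genome functional content is identical
    sp_index = {sp: i for i, sp in enumerate(species)}
    for e in config.planted_taxa:
        if e.latent_anchor is not None and e.taxon in sp_index                 and e.latent_anchor in sp_index:
            carry[sp_index[e.taxon]] = carry[sp_index[e.latent_anchor]]

    # Gene families: one per KO first (so every KO is represented), the rest
    # drawn uniformly over KOs plus an unmapped pool.
    fam_ko: list[str | None] = list(kos)
    extra = config.n_gene_families - len(kos)
    choices = list(kos) + [None]
    probs = np.full(len(choices), 0.85 / len(kos))
    probs[-1] = 0.15
    idx = rng.choice(len(choices), size=extra, p=probs)
    fam_ko.extend(choices[i] for i in idx)
    families = [f"FAM_{i + 1:05d}" for i in range(config.n_gene_families)]
    family_to_ko = dict(zip(families, fam_ko))

    base_rpk = config.rpk_scale * rng.lognormal(0.0, 0.5, len(families))
    rel = taxa_table.to_numpy() / 100.0  # taxa x samples
    samples = list(taxa_table.columns)

    rows, data = [], []
    f = config.unclassified_fraction
    for fi, (fam, ko) in enumerate(zip(families, fam_ko)):
        strata_sum = np.zeros(len(samples))
        fam_rows, fam_data = [], []
        if ko is not None:
            for si, sp in enumerate(species):
                if not carry[si, ko_index[ko]]:
                    continue
                factor = (rng.lognormal(0.0, config.sigma_copy_factor)
                          if config.sigma_copy_factor > 0 else 1.0)
                noise = np.exp(config.sigma_rpk * rng.standard_normal(len(samples)))
                vals = rel[si] * base_rpk[fi] * factor * noise
                fam_rows.append((fam, stratum_token(sp)))
                fam_data.append(vals)
                strata_sum += vals
        unclassified = (f / (1.0 - f)) * strata_sum
        total = strata_sum + unclassified
        rows.append((fam, "TOTAL"))
        data.append(total)
        rows.extend(fam_rows)
        data.extend(fam_data)
        if f > 0:
            rows.append((fam, "unclassified"))
            data.append(unclassified)

    genes = pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(rows, names=["gene_family", "stratum"]),
        columns=samples)
    genes.attrs["family_to_ko"] = family_to_ko

    # Pathway abundance = sum of member-KO community totals; coverage = the
    # fraction of member KOs detected (> 0) in the sample.
    totals = genes.xs("TOTAL", level="stratum")
    ko_total = pd.DataFrame(0.0, index=kos, columns=samples)
    for fam, ko in family_to_ko.items():
        if ko is not None:
            ko_total.loc[ko] += totals.loc[fam]
    ab_rows, cov_rows = [], []
    for pw in catalog.pathway_ids:
        members = list(catalog.pathways[pw])
        ab_rows.append(ko_total.loc[members].sum(axis=0))
        cov_rows.append((ko_total.loc[members] > 0).mean(axis=0))
    abundance = pd.DataFrame(ab_rows, index=catalog.pathway_ids, columns=samples)
    coverage = pd.DataFrame(cov_rows, index=catalog.pathway_ids, columns=samples)
    abundance.index.name = coverage.index.name = "pathway"
    return genes, PathwayTable(abundance=abundance, coverage=coverage)


def default_config(**overrides) -> SimConfig:
    """The study-design default configuration (180 samples), with overrides."""
    return dataclasses.replace(SimConfig(), **overrides)


def single_site_config(target_spearman: float = 0.8, exercise_shift: float = 1.8,
                       n_null: int = 20, stratum: str = CHILDREN,
                       taxon: str = "Staphylococcus_epidermidis",
                       mean_log_abundance: float = 0.5,
                       seed: int = 0, **overrides) -> SimConfig:
    """Reduced one-site cohort: one planted taxon among ``n_null`` nulls.

    The workhorse for parameter-recovery and calibration experiments: the
    children stratum at the underarm gives 15 subjects x 2 timepoints = 30
    samples.
    """
    planted = (PlantedEffect(taxon, "underarm", stratum, target_spearman,
                             exercise_shift, ("K01652", "K00826"),
                             mean_log_abundance),)
    baselines = {k: v for k, v in _DEFAULT_BASELINES.items() if k[0] == "underarm"}
    return SimConfig(sites=("underarm",), n_taxa=n_null + 1, planted_taxa=planted,
                     odor_baseline=baselines, seed=seed, **overrides)


def null_config(n_taxa: int = 20, seed: int = 0, **overrides) -> SimConfig:
    """One-site cohort with no planted effects: every taxon is null."""
    baselines = {k: v for k, v in _DEFAULT_BASELINES.items() if k[0] == "underarm"}
    return SimConfig(sites=("underarm",), n_taxa=n_taxa, planted_taxa=(),
                     odor_baseline=baselines, seed=seed, **overrides)


def opposed_ko_config(target: float = 0.7, seed: int = 0, **overrides) -> SimConfig:
    """Two species carrying the same KO with opposite planted odor effects.

    The fixture behind the pooled-vs-stratified contrast: per-species
    analysis sees one positive and one negative association on the shared
    enzyme, while the pooled community total cancels to noise.
    """
    shared = ("K01652", "K00826")
    planted = (
        PlantedEffect("Staphylococcus_epidermidis", "underarm", "both",
                      target, 1.0, shared, 1.5),
        PlantedEffect("Staphylococcus_hominis", "underarm", "both",
                      -target, 1.0, shared, 1.5,
                      latent_anchor="Staphylococcus_epidermidis"),
    )
    # flat baselines: no design structure, isolating the resolution contrast
    baselines = {("underarm", g, tp): 40.0 for g in GROUPS for tp in ("1h", "8h")}
    overrides.setdefault("sigma_copy_factor", 0.0)  # matched copy numbers
    overrides.setdefault("sigma_rpk", 0.05)  # keep cancellation sharp
    overrides.setdefault("n_children", 50)
    overrides.setdefault("n_teens", 50)
    overrides.setdefault("sex_split", {CHILDREN: (25, 25), TEENS: (25, 25)})
    overrides.setdefault("subject_persistence", 1e-9)  # timepoints independent
    return SimConfig(sites=("underarm",), n_taxa=12, planted_taxa=planted,
                     odor_baseline=baselines, seed=seed, **overrides)
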