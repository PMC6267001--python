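# Methods

This note documents the models, parameters, and numerical choices behind
`skinmwas`: the association machinery, the functional (KO/pathway) analysis,
the ordination, and — at greatest length — the synthetic-cohort generator,
since its guarantees determine what the test suite does and does not show.

## Study design and statistical model

The unit of analysis is one sample: a (subject, body site, timepoint)
triple with a continuous odor-intensity score in [0, 100] and taxonomic and
functional abundance profiles. The default design is 15 children and 15
teenagers (8 F / 7 M each), three sites (underarm, neck, head), two
timepoints (1 h after a standardized shower; 8 h, after exercise) — 180
samples.

Association testing is dual-mode:

* **Cross-sectional**: Spearman's ρ between a feature's abundance and odor
  intensity over all of a stratum's samples at one site, both timepoints
  pooled. Pooling gives one ρ per (feature, site, stratum) but ignores
  within-subject dependence between a subject's two samples; this is a
  deliberate simplification (no mixed-effects modeling is attempted), and
  its consequences are visible in the generator's calibration (below).
* **Longitudinal**: Wilcoxon signed-rank on subject-paired 1 h/8 h
  abundances; zero differences are dropped (classic treatment), and an
  all-zero difference vector is reported as a degenerate p = 1 rather than
  an error. The direction call is the sign of the median paired
  difference; an exactly zero median yields "none".

Strata are `children`, `teens`, and `youth` (the pool of both). The BH
adjustment runs across features *within* one (site, stratum, test) family;
per-site, per-stratum families match the way such results are reported one
site and stratum at a time. The significance call is q < 0.1 together with
|ρ| > 0.2. The absolute value matters: negative associations (community
members depleted in high-odor samples) are first-class results.

### p-value computation

Spearman p-values use the exact permutation null for n ≤ 9 with untied
data (the full n! distribution, cached per n) and the t-approximation
otherwise. The signed-rank test uses scipy's exact null for ≤ 25 nonzero
untied pairs, its tie-corrected normal approximation otherwise; the
rank-sum test uses scipy's exact/asymptotic policy. All three are verified
against brute-force enumeration oracles (all pairings, all 2^n signings,
all C(n+m, n) assignments) in the test suite; the oracles share no code
with the implementations.

## Filters

Applied per site before any testing, with strict inequalities throughout:

| gate | rule | default |
|---|---|---|
| taxa | mean relative abundance in either age group > threshold | 1% |
| gene families | mean community (TOTAL-row) RPK in either age group > threshold | 10 |
| pathways | mean coverage across all the site's samples > threshold | 0.3 |

Surviving gene families are re-normalized per sample so the TOTAL rows sum
to 1; every stratum of a family is scaled by the same per-sample factor, so
the stratified-additivity identity survives filtering exactly. The gate is
evaluated on community totals, not per-stratum means, because the gate
conceptually precedes taxonomic attribution. Re-normalization is per
sample (across families) rather than per family (across samples) because
the downstream correlations need per-sample relative abundances. The taxon
and pathway filters are idempotent and value-preserving; the gene-family
filter is not idempotent in the literal sense (its output is on a different
scale than its input gate), which is intrinsic to the re-normalization and
not a defect.

## Functional analysis: pooled vs. taxon-stratified

Gene families map many-to-one onto KOs; KOs map one-to-many onto pathways.
`bag_of_genes` sums community totals per KO; `bag_of_genomes` sums within
each (KO, taxon) stratum, keeping an `unclassified` stratum. Marginalizing
the stratified table over taxa reproduces the pooled table exactly — an
invariant asserted on every fixture.

Pathway-level association uses pathway abundance (renormalized to per-sample
relative values) with the same dual tests as taxa; a pathway is a
*candidate* when at least 2 of its 6 (stratum × test) adjusted p-values
fall below 0.1. Candidate pathways get per-(pathway, species) counts of
member KOs present (detected in ≥ 1 sample of the site) and of member KOs
whose stratified abundance is significantly *positively* correlated with
odor. A sign-consistency diagnostic — the fraction of a pathway's member
KOs sharing the majority correlation sign — is reported for both modes; on
communities where related species carry the same enzyme with opposite
effects, the stratified mode is consistent per species while the pooled
mode is not, which is the central methodological contrast the package
encodes as a test.

## Ordination

Bray–Curtis dissimilarity is computed by scipy; principal coordinates by
double-centering −½d² and symmetric eigendecomposition, with negative
eigenvalues reported but never corrected (coordinates for them are zero).
The constrained analysis is distance-based RDA: the axes with positive
eigenvalues are regressed on the constraint matrix (odor intensity numeric;
age, timepoint, sex as centered indicators; collinear columns dropped with
a warning), the fitted values are eigen-analyzed, and pseudo-F =
(constrained/q)/(residual/(n−q−1)). Significance is by row permutation of
the constraint matrix, p = (1 + #{F′ ≥ F})/(1 + n_perm), with a default of
999 permutations and hence a p floor of 1/1000. Which constrained-ordination
variant (discriminant CAP vs. distance-based RDA) a given external study
used is usually not recoverable from its text; the db-RDA form is chosen
here because its permutation test is the better-defined object, and the two
give the same qualitative test under this permutation scheme. The
Pythagorean identity constrained + residual = total inertia (over positive
axes) is asserted at 1e-8, and the pseudo-F is checked to order fixtures
identically to PERMANOVA's statistic on the same distances.

## The synthetic cohort generator

The generator's job is to produce cohorts on which (a) planted
feature–phenotype associations are recovered at a *known, targeted*
Spearman correlation, and (b) everything unplanted is genuinely null. Both
properties are quantitative promises, checked by Monte-Carlo in the tests.

**Composition.** Species log-abundances are Gaussian (per-species mean;
common log-SD σ = 1); samples are closed to 100% (logistic-normal), values
below a detection floor (0.001%) are zeroed, and the remainder re-closed.
Planted species default to a mean log-abundance of 0.5, a deliberately
moderate compositional share: a dominant planted species leaks into every
other feature through the closure denominator, which both distorts null
features and attenuates co-planted effects.

**Phenotype coupling (Gaussian copula).** Each planted effect has a latent
factor z per (subject, timepoint), shared between the taxon's log-abundance
(σ·z) and the odor score (c·z). Only the rank-correlation structure matters
downstream, so no mechanistic odor chemistry is modeled. Odor is
baseline(site, group, timepoint) + subject effect (SD 5) + Σ planted
contributions + noise (SD 5), clipped to [0, 100]; the default baselines
make underarm odor strongest and rising most after exercise, with teens
above children there.

Hitting a *target* Spearman after pooling is the delicate part: the pooled
sample set mixes (group, timepoint) cells whose odor baselines and
exercise shifts differ, which adds odor variance that carries no
taxon signal. The generator therefore solves for each effect's latent
loading analytically from the pooled-mixture moments — matching the pooled
Gaussian correlation, after the Greiner transform G = 2 sin(πρ/6), against
the cell baselines, log exercise shifts, and per-cell variances — by a
damped fixed-point iteration (the per-cell variance depends on all
loadings). A single residual calibration factor (1.05) absorbs what the
Gaussian algebra cannot see: compositional closure, the detection floor,
clipping, and rank-vs-linear slippage on mixtures. That factor was frozen
from a Monte-Carlo calibration at default settings; with it, each default
planted effect's mean realized ρ sits within ~0.05 of target, and the test
suite asserts the weaker ±0.1 band over 100 replicates. Targets whose
summed squared loadings would exceed 0.97 in any cell are rejected as
jointly unattainable at configuration time.

**Longitudinal signal.** The exercise shift multiplies the 8 h latent
abundance before closure (defaults between 0.5 and 2.2 per effect, aligned
in sign with the effect), and a subject-persistence parameter (0.5)
correlates a subject's two latents.

**Functional tables.** Each species carries a fixed binary KO repertoire
(carriage probability 0.4; planted taxa always carry their linked KOs).
A stratified RPK value is species relative abundance × per-family base RPK
(log-normal around 200) × per-(family, species) copy factor (log-SD 0.3)
× per-sample log-normal noise (log-SD 0.3). An `unclassified` stratum
receives a fixed fraction (10%) of each family's total; TOTAL rows are
exact sums. Pathway abundance sums member-KO totals; coverage is the
fraction of member KOs detected per sample. A small bundled toy KO→pathway
catalog (branched-chain amino-acid biosynthesis/degradation, pyruvate
metabolism, and decoy pathways) ships with the package; a real catalog can
be supplied as a two-column TSV.

**Odor characters.** Sour/sulfur/greasy flags are thresholded latent
scores derived from the positive planted contributions (sulfur weighted
toward teens, greasy toward the head site) plus noise. They enable
character-distribution summaries; no chemical realism is claimed.

**Determinism.** One integer master seed; each stage (cohort, taxa, genes,
characters, ordination permutations) draws from its own labeled child
stream, so outputs are byte-identical given the seed and independent of
other stages' draw counts.

### Special-purpose fixtures

`single_site_config` plants one effect among n null species at one site —
the workhorse for recovery and calibration experiments (children stratum:
15 subjects × 2 timepoints = 30 samples).

`opposed_ko_config` builds the pooled-vs-stratified contrast: two species
carrying the same KOs with opposite associations. The pair shares one
latent factor with opposite signs (competition-style coupling, via
`latent_anchor`), one KO repertoire, matched copy factors, small RPK noise,
neutral exercise shifts, and flat odor baselines, with 50 + 50 subjects.
Each of these choices closes a specific leak by which the pooled KO row
would otherwise acquire a spurious directional correlation: asymmetric
genome content biases the per-sample renormalization denominator;
asymmetric shifts or copy factors break the even-function cancellation;
RPK noise scales with the planted abundances; and cell-mean latent
fluctuations interact with baseline gaps. With all of them in place the
pooled contribution of the pair is an even function of the shared latent,
and the stratified analysis recovers both effects while the pooled analysis
recovers neither in ~99% of seeds.

## What the synthetic cohorts do and do not show

The generator reproduces the statistical skeleton the pipeline assumes:
compositionality with sparsity, rank-coupled phenotype effects, paired
longitudinal shifts, stratified functional additivity, and calibrated
nulls. It does not emulate sequencing error, profiler misassignment,
strain-level variation, batch effects, or realistic phylogenetic
correlation among taxa — so green tests certify the pipeline's statistical
behavior under its own model, not robustness to those artifacts. Default
noise scales were chosen for test power and calibration accuracy, not
fidelity to any particular cohort's variance components, which such studies
rarely report.

## Problem sizes

The test suite and the acceptance script run simulations at reduced but
statistically meaningful sizes chosen as the smallest that make the
Monte-Carlo bounds sharp: 100 replicates for recovery and null-FDR rates
(binomial SE ≈ 3%), 200 replicates for copula calibration and the
ordination-null uniformity check (KS at α = 0.01), 199 permutations per
constrained-ordination test in calibration loops (999 for single
analyses), and enumeration oracles at n ≤ 8–9 where the exact nulls are
computable in milliseconds.
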