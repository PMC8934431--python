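# Methods

This note documents the models and procedures implemented in `meadowsucc`,
the choices made where the methodology was genuinely open, and what the
synthetic data generator does and does not emulate.

## Succession staging

Quadrats are clustered with Ward's minimum-variance agglomerative method
(Euclidean geometry, scipy linkage) and the tree is cut at `n_clusters`
(default 4, the number of community states in the degradation sequence).

**Features.** Five functional-group biomass shares (sedge, grass, desirable
forb, toxic forb, shrub) plus species richness and total aboveground
biomass. All columns are standardised to mean 0 / sd 1 before clustering:
Ward on Euclidean distances is scale-sensitive, and mixing compositional
shares (sd ≈ 0.05) with unstandardised covariates lets whichever column has
the largest variance dominate the geometry. With heterogeneous feature
scales the recovered partition reflects measurement units rather than
community structure, so a common scale is the only defensible default.

**Stage ordering.** Clusters carry no temporal information (space-for-time
design), so they are ordered by the known direction of the degradation
sequence: descending mean sedge share, ties broken by ascending mean
toxic-forb share, then by cluster label (logged when reached). A single
cluster is Stage 1.

`n_clusters` is a configuration value, not estimated from the data;
silhouette or gap-based selection is deliberately out of scope. k = 4 is an
external design choice.

## Coupling coordination degree

Per-indicator min–max standardisation uses bounds from the full analysed
table (all stages pooled), so D is comparable across stages; per-stage
standardisation would erase exactly the stage contrasts of interest. A
constant indicator is mapped to 0.5 (neutral) with a warning rather than
failing, since it cannot rank quadrats.

**Polarity.** Default: soil bulk density (SBD) negative — it rises as the
meadow degrades — and every other indicator positive. Soil temperature also
rises with degradation but its polarity is ecologically ambiguous (warmth
is not intrinsically bad for function), so it defaults to positive and is
configurable per `SubsystemSpec`.

**Subsystem membership.** Default soil = {SBD, SM, ST, STC, STN, STP,
STS}, plant = {AGB, BGB, plant density, plant height, SR}; configurable.

**PCA weights.** Eigen-decomposition of the correlation matrix of the
standardised subsystem; components with eigenvalue ≥ 1 (Kaiser) are
retained, always at least one. The weight of indicator i is
Σ_k (λ_k / Σλ_retained)·|v_ik·√λ_k|, normalised to sum 1. Absolute
loadings are used because min–max standardised indicators are already
polarity-aligned; a sign-sensitive weight could cancel an indicator that
loads negatively on a retained component. Squared-loading and
score-coefficient constructions exist; the absolute-loading form was chosen
for transparency and because it reduces to the obvious answers in the
degenerate cases (single indicator → weight 1; duplicated indicator →
equal split).

**Combination.** C = 2√(S·P)/(S+P) (defined as 0 when S+P = 0, computed as
√S·√P to avoid underflow), T = αS + βP with α = β = 0.5 by default (no
guidance favouring either subsystem), and D = C·T by default with the
classical D = √(C·T) as `variant="sqrt"`. The product form is the primary
variant; the sqrt variant dominates it pointwise (C·T ≤ 1) and preserves
the same ordering in practice.

## Multifunctionality

Z-scores use the population convention (divide by n); the choice only
rescales, never reorders, and is recorded in the run manifest via the
config echo. EMF averages all 12 function z-scores; PGI/SCI/SNI average
their subsets. The default grouping (PGI = {AGB, BGB, PD, PH}, SCI =
{STC}, SNI = {STN, STP, STS}) leaves SR, ST, SM and SBD in EMF only — the
membership of sub-indices is an artifact choice, configurable through
`index_groups`. No polarity reversal is applied inside EMF: plain z-scores
enter the average, so SBD contributes positively where the coupling module
treats it as negative. EMF is mean-zero over the analysed quadrats by
construction, so stage values are contrasts, and percentage differences
between stages are scale-unstable (a known property of z-score-averaged
indices, not a bug).

## Inferential layer

* **Stage contrasts** — one-way fixed-effects ANOVA (no random transect
  effects: the transect structure of the per-stage subsets is not part of
  the data model) with Tukey HSD p-values from the studentized-range
  distribution, and a compact letter display built by insert-and-absorb;
  letters are ordered by ascending stage.
* **Simple regression** — OLS, R² = squared Pearson correlation, two-sided
  slope test. A flat response returns slope 0 and R² 0 rather than NaN.
* **Mantel test** — Pearson correlation of upper-triangle distance
  vectors; one-sided (greater) permutation p with the add-one convention,
  p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm); default 9999 permutations.
  Distances default to Euclidean on z-scored variables.
* **Relative importance** — the LMG averaging-over-orderings decomposition
  of the linear-model R², computed by subset enumeration (≤ 12 predictors,
  ≤ 4096 subset fits). Boosted-tree importance measures were deliberately
  not used: their values depend on unreported hyperparameters and admit no
  exact oracle, whereas LMG has a factorial brute-force check and an
  additivity guarantee (shares sum to the full-model R²). This is a
  methodological substitution and is surfaced as such here.

## Synthetic data generator

The generator emulates a four-stage design with 30 quadrats per stage
(0.25 m² quadrats; biomass in g per quadrat). Per quadrat:

* **Presence** — independent Bernoulli draws over the stage species pool;
  stage detection probabilities 0.50/0.48/0.45/0.33 give mean richness
  ≈ 30/26/21/16 (lowest in Stage 4) while stage-level gamma diversity
  equals the pool sizes 61/55/47/49 with near certainty at n = 30.
  Dominant species are drawn at probability ≥ 0.9.
* **Composition** — Dirichlet-type gamma allocation whose expectation
  matches the stage's functional-group proportions (Stage 1: sedges 46 %,
  desirable forbs 28 %, grasses 15 %; … Stage 4: toxic forbs 44 %,
  desirable forbs 37 %, grasses 11 %; small remainders complete each stage
  to 1), split within groups with dominants up-weighted 4×. Concentration
  totals of 150 (Stages 1–3) and 105 (Stage 4) give within-stage share sd
  ≈ 0.03–0.05 — tight enough that the stages form the clearly
  differentiated community states the staging analysis presumes.
* **Total AGB** — log-normal with stage medians 90/80/85/45 g per quadrat
  and log-sd 0.25.
* **Covariates** — truncated Gaussians at stage means chosen as plausible
  alpine-meadow magnitudes with the qualitative orderings of the
  degradation gradient: SBD (0.95→1.28 g cm⁻³) and ST (10.8→13.2 °C)
  peak in Stage 4; STC/STN/STP/STS peak in Stage 3 and bottom out in
  Stage 4 (STN 4.8 vs 2.9 g kg⁻¹); BGB, plant density and height decline
  monotonically; SM is flat (~27–28 vol %). These are synthetic
  calibration values, not measurements.

**What it does not emulate:** spatial autocorrelation along transects,
temporal dynamics, observation error in the covariates beyond Gaussian
noise, a grazing-pressure process model, or any subsetting rule by which a larger
multi-transect survey would be reduced to 30 quadrats per stage (the
generator exposes `n_quadrats_per_stage` instead of guessing one). Passing tests on
this generator therefore demonstrate correctness and internal consistency
of the analysis machinery under the intended data structure — not that any
particular field system will show the same effect sizes.

## Numerical conventions

* Camargo evenness is computed over species with biomass > 0 via the
  sorted-proportions O(S log S) form of the pairwise sum; S counts present
  species only, keeping the index independent of the species universe.
* Species biomass 0 means "recorded absent"; a missing cell means "not
  recorded". Richness counts strictly positive biomass.
* A stored AGB must agree with the species-biomass sum to relative 10⁻⁶
  when both are present; otherwise AGB is derived as the sum.
* Result tables are written with 12 significant digits; the run manifest
  records config, seed, versions and SHA-256 checksums, and rerunning with
  the same seed is byte-identical.
* One run seed fans out to per-module child seeds (< 2³¹) through
  `numpy.random.SeedSequence.generate_state`.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks use 30 quadrats per stage (the design size) with
20 replicate seeds; convergence checks of the generator use 2000 quadrats
per stage; the Mantel calibration uses 1000 null replicates of 12×12
matrices with 199 permutations each. These sizes make the full suite run
in about a minute while keeping Monte-Carlo error well inside the asserted
margins.

## Known limitations

* The coupling coordination degree depends on min–max bounds of the
  analysed table, so D values are not transferable across surveys without
  refitting; compare D only within one analysis.
* PCA weights are unstable when a subsystem's indicators are nearly
  uncorrelated (eigenvalues cluster near 1); the weights remain valid but
  small perturbations can swap retained components.
* The LMG enumeration is exponential in the number of predictors and is
  capped at 12.
* Ward clustering with a fixed k = 4 will happily split a survey with a
  different true number of states; the silhouette on the feature matrix is
  worth inspecting when applying the pipeline to new data.
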