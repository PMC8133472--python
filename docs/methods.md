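# Methods

This note documents the models, parameter choices and numerical
decisions behind `mosaicdiv`, in the spirit of a statistical methods
appendix. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Study design the pipeline assumes

The unit of inference is the *region*: one focal protected area (SPA or
RA) plus every survey of strictly lower protection within a fixed-radius
buffer (10, 50 or 100 km). Protected-area polygons are not part of the
data model, so "distance to a protected area" is operationalized as the
minimum great-circle distance to any survey inside that PA (haversine on
a sphere of radius 6371.0 km). This is the only computable choice when
only survey coordinates are available; it under-estimates true border
distances for large PAs, which makes buffered membership slightly
conservative. A lower-protection survey inside several buffers joins
each region independently — regions may overlap, matching a per-PA
resampling design. Comparisons are the ordered pairs SPA–RA, SPA–NPA
(from SPA focals) and RA–NPA (from RA focals).

## Beta-diversity partition

The pairwise Jaccard dissimilarity is split additively into a turnover
(replacement) and a nestedness-resultant component (formulas in the
README). The identity `total = turnover + nestedness` is exact in
rational arithmetic; the test suite checks it to 1e−12 in floating
point on 10,000 random count triples and against an exact
`fractions.Fraction` oracle. One degenerate case needs a convention:
when one pool is empty (`a = 0, min(b,c) = 0`) the turnover denominator
vanishes; the limit of the formulas gives total = 1, turnover = 0,
nestedness = 1, and the comparison is logged as degenerate. Two empty
pools are an error.

## Effort standardization

Survey effort is never balanced in real mosaics, and pooled richness
grows with the number of surveys pooled. Each comparison therefore
draws `min(|high|, |low|)` surveys without replacement from each side,
pools each side by set union, computes the partition and the richness
difference ΔS, and reports across-iteration means. Defaults are 199
iterations (full-scale 999 via `n_subsample_iter`); with equal side
counts the statistic is deterministic and the implementation shortcuts
the resampling. Iterations in which both pooled sides are empty yield
NaN and are excluded from the means; an all-NaN comparison is an error.

## Curveball null model and SES

The null hypothesis is random assembly holding both survey richness
(row sums) and species frequency (column sums) fixed. The curveball
algorithm implements a Markov chain on that fixed-margin space: each
step picks two random surveys, pools the species unique to each, and
randomly re-splits that pool between them. The chain is aperiodic and
irreducible on the fixed-margin space, and its stationary distribution
is uniform; the acceptance suite verifies uniformity by chi-square
goodness of fit over the exhaustively enumerated state space of a small
matrix at 100,000 draws, and margin conservation on 1,000 random
matrices.

Mixing choices (heuristics, configurable): burn-in of 5 × n_rows trades
before the first saved state, then n_rows trades between successive
saved states. 199 null assemblages per comparison by default (999 at
full scale). For each of total, turnover and nestedness the engine
reports the null mean and SD, the standardized effect size
`SES = (obs − mean)/SD` (SD from the n−1 estimator), and add-one
permutation p-values `(1 + r)/(1 + n_null)` — one-sided in both
directions plus a two-sided value from doubling the smaller tail,
capped at 1, so p is never 0 and never overstated. When the null has
zero variance (e.g. an untradeable matrix), SES is 0 if the observation
equals the null mean and ±infinity otherwise, with p still computed
from ranks. Region-level p-values are combined per pair type with
Fisher's method (−2 Σ ln p ~ χ² with 2k df).

The generator's null configuration makes every cell an independent
Bernoulli draw whose probability depends only on the species, so the
matrix distribution conditional on the margins is exactly uniform —
the curveball null is an exact conditional null there, which is why
the type-I calibration (about 5% of |SES| > 1.96 across 500 null
regions; recomputed by `scripts/acceptance.py` and the acceptance
tests) is a sharp check rather than an approximation.

## Environmental dissimilarity and regressions

Environmental variables are ln(x+1)-transformed. For each comparison,
the same balanced subsampling scheme draws surveys with complete
environmental rows from both sides and measures the Euclidean distance
between the side centroids, averaged across iterations; surveys with
missing environmental values are dropped from environmental analyses
only (they remain in all composition analyses), and a side with fewer
than two complete surveys skips the pair. Across regions, turnover (and
ΔS) are regressed on mean environmental distance by OLS with the
two-sided slope test.

## PCoA and partial dbRDA

Survey-level response distances are the turnover component of the
Jaccard partition between individual surveys. PCoA is the
Gower-centred eigendecomposition (−½ J D² J); axes are ordered by
descending eigenvalue and axes with eigenvalues below 1e−8 of the
spectral radius are discarded. Jaccard-family distances are generally
non-Euclidean; when any eigenvalue is below −1e−8 (relative), the
Lingoes correction (add 2c₁ to all squared off-diagonal distances,
c₁ = −λ_min) restores a Euclidean embedding before the regression step.
Dropping negative axes instead is available by flag.

dbRDA regresses the embedded coordinates on predictors; with a
conditioning block, coordinates and predictors are first residualized
on [1, Z]. Predictor columns that are constant, or numerically inside
the conditioned space, are dropped with a warning. The pseudo-F uses
constrained vs residual sums of squares with df = (q, n − 1 − pz − q);
R² is the semi-partial fraction of total PCoA inertia and the adjusted
R² applies the Ezekiel correction with the conditioning df removed.
Permutation tests permute rows of the reduced-model residuals and
re-residualize (Freedman–Lane style) when conditioned, free row
permutation otherwise; p is add-one, so its resolution is
1/(n_perm + 1). Default 999 permutations (full-scale 9,999 by
config). Environmental predictors are the first 2 PCoA axes of the
Euclidean distance between log-transformed environmental rows
(configurable). The per-region report gives the joint model plus the
two marginal effects (protection | environment and environment |
protection) as raw semi-partial R² shares *and* as percentages of the
jointly explained fraction — the raw shares need not sum to the joint
R² (the confounded fraction belongs to neither margin), so both views
are reported rather than guessing an allocation.

## Summaries

Venn decomposition: regions holding all three levels are subsampled to
the common minimum survey count *per level* each iteration (a
symmetric three-way extension of the pairwise balancing), each level is
pooled, and each species of the iteration's gamma pool is assigned to
exactly one of the 7 membership subsets; mean percentages of gamma are
reported and always sum to 100. IUCN grouping: CR/EN/VU/NT →
Imperiled, LC → Not Threatened, DD or unassessed → Not Assessed — Near
Threatened species are grouped with threatened ones as
conservation-dependent. Richness: one-sample two-sided Wilcoxon
signed-rank of region-level mean ΔS against zero, zeros dropped, exact
null for n ≤ 25 without ties and the continuity-corrected normal
approximation otherwise. Rarity sensitivity: within each region,
species occurring in 1 … min_occ−1 member surveys are removed
(default threshold 3); species entirely absent from the region are
retained so the filter is the identity at min_occ = 1 and idempotent.

## Synthetic metacommunity generator

The generator is first-class code: it produces the statistical
structure the analysis assumes, with known ground truth.

* **Geometry** — region centroids on a lon/lat grid ≥ 3.2 buffer radii
  apart (regions never share surveys); SPA surveys within 8% of the
  buffer radius of the centroid, RA in the 20–50% ring, NPA in the
  20–90% ring, so at the layout buffer every lower-protection survey is
  within reach of the SPA focal.
* **Effort** — default 6 SPA / 8 RA / 12 NPA surveys per region,
  reflecting the usual imbalance toward unprotected surveys. Twenty
  regions and a 150-species pool by default: large enough for stable
  across-region tests, small enough for interactive runtimes.
* **Occupancy** — per region, each species' target occurrence count is
  drawn from a log-series truncated at the region's survey count
  (shape θ = 0.9), giving the heavy rarity tail (many singletons and
  doubletons) that makes the rarity filter meaningful; the occurrence
  probability is that count divided by the survey count.
* **Turnover** — `turnover_strength` is the fraction of the pool split
  into three equal level-exclusive compartments; at 1 the level pools
  are disjoint by construction.
* **Nestedness** — a level d ranks below SPA accesses only the first
  (1 − ν)^d fraction of the shared compartment, producing nested
  richness loss with ratio (1 − ν) per rank step.
* **Environment** — each survey gets a latent gradient score
  g = ρ·s_prot + √(1−ρ²)·ε with s_prot ∈ {+1, 0, −1} for SPA/RA/NPA
  (ρ = `env_confounding`), expressed as log-normal environmental
  variables with alternating loadings; `env_effect` tilts each
  species' occurrence log-odds by β_s·g with β_s ~ N(0,1).
* **Null configuration** — all four effect knobs at zero; cell
  probabilities then depend only on the species, giving the exact
  conditional-uniformity property used for calibration.

What the generator does **not** emulate: spatial autocorrelation within
regions, species' geographic range structure, detection error,
abundance information, and real environmental raster structure.
Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated assumptions, not that any
particular field dataset satisfies those assumptions.

## Problem sizes and defaults

Desk-scale defaults (overridable in config): 199 subsample iterations,
199 curveball nulls, 999 dbRDA permutations, 50 km buffer, 20-region
paperlike preset; the calibration script uses 500 null regions with 10
surveys per level. Paper-scale values (999 / 999 / 9,999) are config
settings, not code changes.

## Known limitations

* Distances are spherical (haversine), not ellipsoidal; differences are
  well below the buffer granularity.
* The buffer is measured from PA surveys, not PA borders (no polygons).
* The curveball mixing schedule is a heuristic; the uniformity test
  covers small matrices, and the burn-in/stride are configurable for
  larger, sparser matrices where mixing is slower.
* Marginal dbRDA shares are semi-partial R² values; with strongly
  confounded predictors both can be near zero while the joint model
  explains much more — the jointly explained percentage columns make
  that visible rather than hiding it.
* The Wilcoxon exact null is used only in the no-ties case handled by
  scipy; heavily tied ΔS vectors fall back to the normal approximation.
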