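# mosaicdiv

Beta-diversity partitioning and null-model inference for protected-area
mosaics.

Conservation areas rarely sit in isolation: a strictly protected core
(SPA, IUCN I–II), restricted-use areas (RA, IUCN III–VI) and
non-protected land or sea (NPA) form adjacent mosaics. Whether the
species inside a protected area are a *superset* of those outside
(nestedness) or *different* species altogether (turnover) decides how
much regional biodiversity protection actually covers. `mosaicdiv`
implements the full analysis pipeline for that question, for ecologists
working with survey-by-species incidence tables: region assembly around
focal protected areas, effort-standardized comparison of protection
levels, fixed-margin null models, ordination-based
environment-vs-protection attribution, and regional gamma-diversity
decomposition — plus a synthetic metacommunity generator with known
ground truth so every stage is testable without any field data.

## The statistics at the core

For two pooled species sets with `a` shared species, `b` unique to the
first and `c` unique to the second, the pairwise Jaccard dissimilarity
is additively partitioned as

```
beta_total = (b + c) / (a + b + c)
turnover   = 2 min(b,c) / (a + 2 min(b,c))
nestedness = |b - c| / (a + b + c) * a / (a + 2 min(b,c))
```

with `beta_total = turnover + nestedness` exactly. Because survey effort
differs between protection levels, each comparison draws the minimum
side count from both sides, 199 times by default (999 at full scale),
and averages the indices. Significance against random assembly uses the
**curveball algorithm** — a Markov chain that shuffles species
co-occurrences while preserving every survey's richness and every
species' frequency — and the standardized effect size

```
SES = (observed − mean(null)) / SD(null),   |SES| > 1.96  ⇒  p < 0.05 (two-sided)
```

with add-one permutation p-values combined across regions by Fisher's
method. Survey-level turnover within each region is decomposed into
protection and environment contributions with **partial distance-based
RDA** (PCoA embedding with Lingoes correction, ANOVA-like permutation
tests), and regional gamma diversity is split into the seven Venn
subsets of {SPA, RA, NPA} membership, overall and by IUCN threat group
(CR/EN/VU/NT = Imperiled, LC = Not Threatened, DD/unassessed = Not
Assessed).

## Worked example

Run the full pipeline on a synthetic eight-region mosaic (the generator
defaults emulate unequal survey effort, a log-series rarity tail,
moderate turnover and an environment partially confounded with
protection):

```bash
mosaicdiv run --seed 42 --out results/demo
# or equivalently, with a config file:
#   mosaicdiv run --config config.yaml --out results/demo
```

`results/demo/beta_ses_50km.csv` then starts:

```
region_id    pair  n_per_side    total  turnover  nestedness  ses_total  p_total
  R000-RA  RA-NPA           8 0.727169  0.689616    0.037553   5.857610     0.01
 R000-SPA  SPA-RA           6 0.729260  0.689298    0.039962   4.780194     0.01
 R000-SPA SPA-NPA           6 0.772112  0.699596    0.072516   6.086202     0.01
```

Reading the first row: between the restricted area `R000-RA` and its
non-protected neighbours, 73% of the pooled composition differs, and
almost all of that dissimilarity (0.69 of 0.73) is species replacement
rather than nested richness loss; an SES of 5.9 against 199 curveball
assemblages says this is far more differentiation than random placement
of the same species frequencies would produce (p = 0.01, the smallest
value attainable from 199 nulls with the add-one rule). The companion
tables report the Fisher-combined p per pair type (`fisher_50km.json`),
Wilcoxon tests of the standardized richness differences
(`richness_50km.csv`; e.g. median ΔS = 17.7 species in favour of SPA
over NPA, p = 0.008 across 8 regions), the partial dbRDA attribution
(`dbrda_50km.csv`; e.g. region `R000-SPA`: protection explains 14.7% of
survey-level turnover after accounting for environment, environment
9.1% after accounting for protection), and the Venn decomposition
(`venn_50km.csv`; on average 16.5% of regional gamma diversity occurs
*only* in non-protected surveys under these generator settings).

Every run writes a `manifest.json` recording the config, master seed
and derived per-stage seeds; two runs with the same config and seed
produce byte-identical tables.

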