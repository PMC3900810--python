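# Methods

This note documents the models, parameter choices and numerical
conventions behind `tfadb`, and what the synthetic-data generator does
and does not emulate.

## The assignment hierarchy

Every food receives exactly one TFA value and a provenance label, by
strict precedence: zero rule → analytic pooling (Step 1) → similarity
transfer (Step 2) → foreign-database match (Step 3) → recipe imputation
(Step 4). A food is considered by a step only if every earlier step
failed; `build_assignments` raises if anything survives Step 4, so the
output database is always complete.

### Zero rule

A food contains no TFA when it has at most a trace of fat or contains
neither partially hydrogenated oils nor ruminant-derived ingredients —
the only two sources of dietary TFA. "Trace" is `fat_threshold`,
default **0.1 g/100 g**, the reporting resolution of printed food
tables.

### Step 1 — pooling analytic values

Literature values arrive either as % of total fat or as g/100 g of food
(optionally with the article's own fat content); both are converted to a
%-of-fat scale, using the article's fat content when stated and the
composition table's otherwise. Pooling rules:

- one article, one sample → that value (`S1_SINGLE`);
- one article, several samples → the article's mean (`S1_MEAN`);
- several articles → mean of article means weighted by the number of
  samples each analysed (`S1_WEIGHTED`). When article means are
  themselves means of listed samples this equals the flat mean over all
  samples, which the tests assert to 1e-12.

An article that does not state its sample count can anchor a food on its
own but is dropped from weighted pooling (a weight cannot be formed).
If *only* unknown-count articles exist for a multi-article food the
builder raises for manual resolution rather than guessing weights. When
dropping unknown-count articles leaves a single article, the label
follows the retained article (`S1_MEAN`/`S1_SINGLE`).

### Step 2 — similarity transfer

What transfers is TFA **as % of total fat**, rescaled by the recipient's
own fat content; recipients flagged as TFA sources but with zero fat get
0.0 under their matched label, since a %-of-fat transfer is undefined at
zero fat.

Nutrient similarity is the maximum relative deviation over (energy, fat,
protein, carbohydrate) per 100 g, each component normalised by the
donor's value floored at `similarity_floor` (default **1.0**, keeping
near-zero denominators from dominating). Defaults: `similarity_threshold
= 0.25`. The score is scale-free and conservative; both knobs are
configurable.

General foods search Step-1-resolved donors in the same category of the
same group (`S2_1A`), then anywhere in the group (`S2_1B`). Meat cuts —
foods of the meat group carrying a species label — run the cascade
`S2_2A` (same species and part) → `S2_2B` (similar part of the same
species) → `S2_2C` (similar animal per the species adjacency) → `S2_2D`
(different species per the fallback map) → `S2_2E` (same meat category).
Meat-group foods *without* species/part labels (processed meat products)
take the general path; group-transfer counts in published provenance
tables for meat groups require this.

Two design choices deserve justification:

- **Thresholded vs pure nearest neighbour.** Steps `S2_1A`, `S2_1B`,
  `S2_2B` and `S2_2C` require the donor to be within the similarity
  threshold; `S2_2A`, `S2_2D` and `S2_2E` are pure nearest-neighbour.
  The split follows the steps' semantics — "same part but *different*
  composition" cannot demand similarity, while published step routings
  send foods past groups that do contain donors, which is only possible
  if group-level transfer can *fail* on dissimilar composition.
- **Adjacency as data.** The "similar part", "similar animal" and
  "different species" relations of the meat cascade are expert judgment,
  not computable structure, so they are configuration
  (`parts_adjacency`, `species_adjacency`, `species_fallback`), never
  inferred.

Ties among equidistant donors go to the lowest food id, making the build
deterministic; shuffling input rows provably changes nothing.

### Step 3 — foreign-database match

Only products with the same manufacturer on both markets qualify; among
those within the similarity threshold (computed between the domestic and
foreign nutrient vectors) the closest match donates its TFA g/100 g
directly.

### Step 4 — recipes

A composed food's TFA is the gram-weighted sum over its recipe,
`Σ (gramsᵢ/100) × TFAᵢ`. Recipes may nest; they are resolved in
topological order and cycles are errors. A dish whose ingredients are
all TFA-free gets 0.0 — with provenance `S4`, not `ZERO`, because the
zero rule did not produce it.

All values are carried at full float precision; rounding to 0.1 happens
only when report tables are rendered, so provenance-level results are
reproducible without accumulation error.

## Intake estimation

Daily intakes are sums over a day's entries (energy and fat from the
foods as recorded; TFA after venue resolution), averaged over the
subject's recorded days. Subjects with fewer than the expected 16 days
are averaged over available days with a warning rather than dropped.

- **Venue rule.** Commercial items (fast foods, baked goods,
  confectionaries) keep the TFA of the product itself. Composed
  restaurant dishes, for which no product information exists, are
  replaced by their raw materials through recipe flattening before TFA
  look-up. Venue never affects energy or fat, and never affects simple
  foods.
- **% of energy.** `energy_per_gram_fat` is the Atwater factor,
  **9 kcal/g**. Percent-of-energy expressions use the ratio of 16-day
  means rather than the mean of daily ratios: it matches the "multi-day
  mean intake" framing and is robust to low-energy days.
- **Outlier exclusion.** One pass, within sex: a subject is excluded
  when TFA in g/day *or* % energy lies outside the group mean ± k·SD
  (sample SD from the full group; `k = 3`). No iteration — published
  analyses of this design report a single exclusion round. Zero-SD
  groups exclude nobody.

## Summaries

Food-group contributions are shares of TFA **mass** (g/day), not of
%energy — the contribution table is a decomposition of intake mass — and
per subject they sum to 100 exactly; subjects with zero total TFA have
no defined shares and are dropped with a warning. The industrial share
is the sum of mean contributions over "(I)"-labelled groups.

Urban/rural classification thresholds population density at **1000
persons/km²**, which cleanly separates the emulated study's four areas
(11743 and 4446 vs 786 and 285). Urban vs rural means are compared with
a two-sided unpaired Student's t-test; age decades with one-way ANOVA
followed by Tukey–Kramer pairwise comparisons (the groups are
unbalanced, so the Kramer form is required); degenerate variance yields
NaN p-values rather than errors. Distribution tables use half-open
[lo, hi) bins with fixed interior edges (g/day: 1.0, 1.5, 2.0, 2.5, 3.0;
%energy: 0.5, 0.75, 1.0, 1.25, 1.5), open-ended extremes truncated at
the observed range in the row labels. Frequencies above the WHO ceiling
count strictly greater than 1% of energy.

Database comparison (full vs base food list) re-estimates intakes with
the assignment table restricted to base foods — missing foods contribute
zero — so per subject the reduced estimate never exceeds the full one.
A subtlety: composed restaurant dishes on the added list decompose into
base-list raw materials, so their TFA survives the reduction.

## The synthetic study generator

The generator emulates the *structure* of a national-food-table TFA
study, not any real table's contents: 11 TFA-bearing food groups
labelled industrial/natural, a zero-TFA remainder (default 1469 of 1995
foods), per-group step-routing counts that mirror a published database
development summary (526 assigned foods; e.g. 122 confectionaries), a
literature corpus with the published 13/71/59 split of Step-1 sub-modes,
and a 225-subject cohort (119 women, 106 men) stratified over four areas
and four age decades with marginals matching the emulated study.

Routing is exact by construction. Step-1 donors sit on a multiplicative
macronutrient grid whose adjacent levels differ by ×1.7 (relative gap
≈ 0.41, well above the 0.25 threshold), designated recipients are
jittered within ±3% of their donor, and Step-3/4 foods are placed a full
grid octave away from every donor. Each similarity recipient's true
%-of-fat equals its donor's — exactly the transfer rule's modelling
assumption — so on noiseless inputs the pipeline recovers the truth
through *all four* steps, and the ground-truth closure test asserts
estimator = truth to 1e-9. Article means carry multiplicative noise
(mean 1, SD 0.08 by default), making pooled values unbiased for the
truth.

The consumption model is a per-subject budget model: each subject draws
an energy target (normal; women 1847 ± 289, men 2372 ± 389 kcal/day) and
a TFA target (log-normal; mean 1.7 g/day, SD 0.7/0.6 g), the latter
scaled by urban (×1.15) and age-decade (×1.24/1.12/1.00/0.71)
multipliers normalised to a design-weighted mean of one so cohort-level
targets are preserved while the urban > rural and younger > older
gradients appear. Per day, TFA-bearing foods (chosen via per-subject
Dirichlet group weights) are scaled to meet the day's TFA target and
zero-TFA staples fill the remaining energy budget, making realized means
unbiased for the targets; day-level log-normal noise (σ = 0.12 energy,
0.25 TFA) supplies within-subject variation. Fat intake is *emergent* —
it follows from the food profiles rather than being targeted — and lands
near 28% of energy under the defaults.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: real menus and food co-occurrence, correlation
between energy and TFA intake (targets are drawn independently, so the
mean per-subject TFA %energy exceeds `9×1.7/1847` by a Jensen factor of
about 1.04), misreporting, seasonal effects, and anthropometric realism
beyond plausible ranges. Count-based and structural results are exact;
distribution shapes are merely plausible.

## Problem sizes and determinism

The default study (1995 foods, 225 subjects × 16 days ≈ 50 000 record
rows) generates in under a second and the full pipeline runs in a few
seconds; the test suite, including a 100 000-shuffle permutation oracle
for the ANOVA, completes in well under a minute. A single
`numpy.random.Generator` seeded from the configuration drives all
randomness; identical config and seed give byte-identical CSVs, which
the tests assert.

## Known limitations

- The similarity metric and threshold are a modelling choice; published
  database builds resolved similarity by expert judgment that a scalar
  score can only approximate.
- Step-1 sub-mode labels after dropping unknown-count articles follow
  the retained articles, which may differ from how a human compiler
  would have logged the food.
- The estimator deliberately implements no measurement-error or
  usual-intake correction; it is an exact aggregator of what the records
  say.
- Tukey output is reported as explicit pairwise p-values rather than
  compact letter groupings.
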