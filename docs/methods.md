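# Methods

## Overview

`gaitscreen` implements a mass-univariate ("forward screen") analysis for
wide blocks of longitudinal gait variables: baseline normalization, one
ANOVA per variable, per-term hit sets, hypergeometric tag enrichment, and
hit-set visualization. This note records the statistical model, the
defaults and why they were chosen, the design decisions that were
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Data model and cleaning

Input is one wide table per acquisition timepoint (one row per animal, one
numeric column per gait variable) plus a master lookup table mapping animal
id → group/genotype/treatment metadata. Blanks and the sentinel strings
`""`, `"-"`, `"NaN"`, `"NA"` (configurable) are treated as missing.
Variable names are whitespace-trimmed but otherwise preserved, because they
feed tag fragmentation. If an export contains several runs (crossings) per
animal, `average_runs` collapses them to per-animal means first: the
screening models assume one observation per animal per timepoint, and
averaging runs is the package's explicit choice where practice varies.

After joining metadata and concatenating timepoints into a long-format
`StudyDataset`, variables that are entirely missing, or entirely zero among
their non-missing values, are dropped and logged. The rule is evaluated
over the combined dataset, not per timepoint: a variable observed at any
timepoint is informative and is retained. Every drop, exclusion and
imputation is appended to a provenance log carried on the dataset.

## Baseline normalization

Each animal's post-baseline values are expressed relative to its own value
at the declared baseline timepoint, per variable:

- `ratio` (default): yᵢₜ / yᵢ,base — fold of baseline. Chosen as the
  default because it puts variables with heterogeneous units on one common
  scale, which the heatmap and UMAP consume directly. A value equal to its
  baseline maps to exactly 1.
- `difference`: yᵢₜ − yᵢ,base, for settings where an additive scale is more
  natural. Baseline-equal values map to exactly 0.

The baseline timepoint is removed from the returned dataset so it cannot
distort downstream modeling. A zero baseline under the ratio transform is
undefined; the default marks those normalized values missing
(`set_missing`), with an `epsilon_offset` alternative for count-like
variables. Animals with no baseline session are handled by policy:
`exclude_subject` removes the animal (logged), `impute_group_mean`
normalizes the animal's post values against the mean of its group's
baseline values for each variable. Excluded-policy animals are always a
subset of imputed-policy animals. `baseline_summary` reports raw per-group
baseline means/sd/n, since group differences already present at baseline
(expected, e.g., across genotypes) are part of interpreting normalized
results.

## The screening ANOVA

The user declares a `ModelSpec`: between-subject factors (metadata
columns, in entry order), an optional within-subject factor (timepoint)
for repeated measures, the effect terms (default: full factorial), α
(default 0.05), and a multiplicity adjustment (default none).

The engine computes classical fixed-effects ANOVA with **sequential
(Type I) sums of squares**, factors entered in the declared order. This
matches the behavior of base R's `aov`, the de facto reference for this
kind of screen; on balanced designs sequential, Type II and Type III sums
of squares coincide (verified by test), which bounds the practical impact
of entry order. Internally, each term's dummy-coded design block is
residualized against everything entered before it and orthonormalized
(SVD with relative singular-value cutoff 1e-9); the term's SS is the
squared norm of the response's projection onto the new directions. Because
the projection basis depends only on the design and the missingness
pattern, all variables sharing a pattern are decomposed in one matrix pass.

With a within factor, the decomposition adds a subject stratum: intercept →
between terms → subject indicators → within terms → residual. Between
terms are tested against the subject stratum (MS_term / MS_subject),
within terms against the residual stratum — the classical split-plot
F tests. Subjects missing any within-factor level for a variable are
dropped for that variable (and logged), keeping the stratum decomposition
exact; this mirrors complete-case repeated-measures practice. Sphericity
corrections are off by default (classical `aov` output); a
Greenhouse–Geisser option adjusts within-term p-values using the pooled
within-group covariance of the repeated measures, with ε clipped to
[1/(k−1), 1].

Missing responses are deleted casewise per variable. If a variable's
design degenerates (a factor collapses to one level, a term becomes
inestimable, or an error stratum loses all residual df), that variable is
skipped with a recorded reason rather than failing the screen.

**Hits and multiplicity.** A variable is a hit for a term when its
(adjusted) p is strictly below α. The default applies no multiple-testing
adjustment: the screen is exploratory and descriptive, and the effective
dimensionality is far below the variable count because gait variables are
strongly inter-correlated; an unadjusted per-test α is the deliberate
default, with Bonferroni and Benjamini–Hochberg (per term, across
variables) available. Hit sets are monotone in α and reproducible: the
screen is deterministic given input ordering.

## Tag enrichment

Variable names are tokenized on configurable delimiters (space, `_`, `->`,
`-`, parentheses, `/`) and matched against an ordered fragment→tag
dictionary, longest fragment first with token consumption (so `Step Cycle`
is not double-matched by `Step`). The shipped dictionary covers CatWalk XT
conventions: paw codes (`RF`, `LF`, `RH`, `LH` and spelled-out forms) map
to four paw tags, measurement fragments (`Stand`, `Swing`, `Stride`,
`Support`, `Couplings`, `Duty`, `Cadence`, `BOS`, `PrintArea`,
`MaxContact`, `Speed`, …) to category tags, and each paw tag also derives
its side (`left paws`/`right paws`) and girdle (`forepaws`/`hindpaws`)
tags. The dictionary is fully user-overridable from YAML, since variable
naming varies across acquisition software versions.

For a term's hit set of size n inside the screened universe of N
variables, a tag carried by K universe variables and k hits gets the exact
upper-tail hypergeometric probability P(X ≥ k) (computed via the scipy
survival function; verified against exact rational enumeration for all
parameter combinations with N ≤ 30). Only over-representation is tested —
the question is which aspects of gait are disproportionately affected —
and no cross-tag adjustment is applied by default, mirroring the screen's
philosophy; tags overlap heavily by construction, so their tests are not
independent and the p-values are ranking devices more than error
guarantees.

## Visualization

Every figure is backed by a plain table so results are re-derivable
without a plotting backend:

- **Heatmap:** (variable × term) −log₁₀ p, capped at 4 for display so
  extreme values do not flatten the color scale; rows ordered by each
  variable's minimum p.
- **Venn:** exact disjoint-region counts for 2–3 term hit sets (brute-force
  verified); >3 terms fall back to a pairwise-overlap table. Drawing uses
  plain matplotlib circles.
- **Word cloud:** per-tag size = k (tags absent from the hits are
  omitted), color score = −log₁₀ p_enrich clipped at 4; glyph placement is
  seeded and cosmetic — the tested surface is the weight table.
- **Trajectories:** per-group per-timepoint mean ± sem (sd/√n) of a
  variable, on the normalized scale.
- **UMAP:** animal(-timepoint) rows of the normalized variable matrix are
  z-scored per variable, missing values imputed (variable median by
  default), and embedded in 2-D with a fixed `random_state`; identical
  seed and input give identical coordinates. Whether rows are
  animal-timepoints (default) or per-animal means is a flag, since either
  view can be the relevant one. The embedding is treated as an external
  component behind this standardize→impute→embed interface; only the
  pre-processing and the determinism contract are this package's own.

## Synthetic-study generator

`simulate_study(SimConfig)` emulates the structure the models assume. Per
animal and variable, a positive baseline value is drawn as
(per-variable scale) × (per-animal lognormal heterogeneity, sd 0.2) ×
(1 + session noise, sd 0.15), with per-variable scales spanning roughly
three orders of magnitude as real gait variables do. Every post-baseline
value is that same realized baseline times (1 + μ + ε), ε ~ N(0,
noise_sd); ratio normalization therefore recovers exactly 1 + μ + ε, and
the animal-level heterogeneity cancels. Effect sizes are standardized: a
term effect of size d shifts the normalized response by d·noise_sd. Group
effects apply to all non-reference-group animals at all post timepoints;
time effects ramp linearly over post timepoints to full size at the last;
interaction effects apply to non-reference groups at the last timepoint
only. An additive mode (effects in raw units of the variable's scale)
supports the difference transform. Missingness is injected completely at
random; declared all-zero columns exercise the cleaning step. Defaults —
2 groups × 10 animals, baseline + two post timepoints, 60 variables, noise
sd 0.15 — represent a typical adequately powered rodent injury study.

What the generator does **not** emulate: correlated variables (real
CatWalk blocks are strongly inter-correlated; here variables are
independent given the animal), informative missingness, non-normal
response noise, drift or batch structure, and run-to-run within-session
variability. Passing tests therefore demonstrate correctness of the
statistics under the models' own assumptions, not robustness to every
property of real gait data — in particular, observed false-positive rates
on real, correlated variables share the per-test α only marginally, not
jointly.

At these defaults the pipeline's operating characteristics, recomputed by
`scripts/acceptance.py` from seeded simulation, are a null per-term hit
fraction statistically indistinguishable from α = 0.05 (pooled over 200
replicate screens of 200 variables) and sensitivity ≈ 0.99 for group
effects of standardized size 1.5 at 10 animals/group (50 replicates).
Simulation sizes throughout (replicate counts, variable counts) were
chosen to make Monte-Carlo error small relative to the quantities checked
while keeping the default test run fast on one core.

## Numerical and degenerate-input choices

- Rank detection in the projection engine uses singular values above 1e-9
  of the block norm; aliased or collapsed terms surface as
  `DegenerateDataError` (skipped per variable during screening).
- Hit rule is strict inequality p < α, so α = 1 marks every tested
  variable and a p exactly at α is not a hit.
- Hypergeometric parameters are validated (0 ≤ K ≤ N, 0 ≤ n ≤ N,
  0 ≤ k ≤ min(K, n)); k = 0 returns exactly 1.
- Ties in enrichment ranking are broken alphabetically by tag;
  heatmap row order ties follow the pivot's variable order — both
  deterministic.
- Seeds: every stochastic component (generator, permutations, UMAP, word
  cloud layout) takes an explicit seed; no global RNG state is used.

## Known limitations

- Sequential SS makes main-effect tests order-dependent on unbalanced
  data; this is deliberate (reference-engine compatibility) but users with
  strongly unbalanced designs should order factors thoughtfully or balance
  by design.
- The repeated-measures engine is a classical error-stratum ANOVA, not a
  mixed model: subjects with incomplete within profiles are dropped per
  variable rather than partially pooled, and no REML/unbalanced-stratum
  machinery is provided.
- Tag enrichment treats variables as exchangeable draws, ignoring their
  correlation; enrichment p-values are honest ranks, optimistic as error
  rates.
- The case-study loader expects cleaned per-timepoint exports; it does not
  parse CatWalk's native run-level or video-derived files.
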