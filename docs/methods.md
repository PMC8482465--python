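# Methods

## Scope and model

The package implements desk-side analysis of a bait-prey AP-MS experiment:
from a MaxQuant protein-group LFQ table to filtered interactor calls and a
shared/unique comparison between two test baits sharing one IgG mock
control. Peptide-level processing, database search, normalization between
runs beyond MiST's per-run fraction normalization, and targeted (PRM)
validation are out of scope; the protein-group table is taken as given.

## Preprocessing

1. **Flag filter.** Rows marked potential contaminant, reverse decoy, or
   only-identified-by-site are dropped; a row with several flags is
   dropped once. Flag columns use MaxQuant's `"+"` convention strictly;
   any other non-empty token is a dialect error rather than silently
   coerced. A missing flag column is treated as all-false with a warning,
   since exported tables sometimes omit empty columns.
2. **Missingness.** A stored LFQ intensity of 0 means "not quantified"
   and becomes missing (NaN). Treating zeros as measurements would make
   both the valid-value filter and the technical-replicate median
   meaningless.
3. **Collapse.** Intensities are log2-transformed and technical
   replicates collapsed to their median over valid values only; a
   (bait, biological-replicate) cell with no valid technical replicate
   stays missing.
4. **Valid-value filter.** A protein group is retained if it has at least
   `k_valid` (default 3) valid values within at least one bait's
   biological replicates, counted after collapsing. The "group" is the
   bait — IgG counts as a group, so a protein seen only in the control
   survives to be scored (and will fail the IgG threshold later, which is
   the correct place for that decision).

The stage order is fixed: transform → median → valid-value filter →
scoring. The filter is idempotent and monotone in `k_valid`.

## MiST scoring

Collapsed log2 values are de-logged and each (bait, biological replicate)
column is normalized to fractions summing to 1; missing cells contribute
0. A column with zero total is an error — that pull-down quantified
nothing and the experiment, not the code, is at fault. For a prey with
fractions a_1..a_n across one bait's n biological replicates:

- reproducibility R = normalized Shannon entropy of p_i = a_i / Σa_j with
  log base n, so R ∈ [0, 1] for any replicate count; R = 0 when the prey
  was never observed, or observed in a single replicate;
- abundance A = mean fraction, missing counted as 0 (absence of evidence
  of binding lowers A but not R, which is computed on the observed
  distribution);
- specificity S = A(bait) / Σ over the scoring group's baits of A, with
  S = 0 everywhere for an all-zero prey. The IgG control is an ordinary
  bait here and receives its own composite score — the IgG threshold
  presupposes one.

Composite: score = w_R·R + w_A·A + w_S·S. Default weights are the
published MiST-trained values (0.30853, 0.00596, 0.68551), renormalized to
sum to 1 and overridable in config; whether a given study used retrained
weights is generally unknowable from its text, so no result here should
hinge on the exact weights, and the tests exercise the formulas rather
than one weight vector.

### Scoring group: per-control pairs vs joint

`score_dataset` can score all baits jointly (one specificity denominator
across every bait; Σ_baits S = 1 per prey) or one test bait against the
control in isolation. The pipeline defaults to per-control pairs. The
reason is structural: with the default weights, a score of 0.75 requires
S ≥ ~0.64, and under joint scoring a prey genuinely shared by two baits
can reach that for at most one of them (their S values sum to ≤ 1). A
design with two related baits that share real partners would therefore
report an empty shared interactome as an artifact of the scoring group,
not the data. Scoring each pull-down against its own control — the
comparison the experiment was designed around — removes that artifact;
`scoring: joint` remains available for many-bait panels where cross-bait
specificity is the point.

## Interactor calling

A prey is called for test bait B iff score(B) ≥ τ_bait AND score(IgG) ≤
τ_igg, defaults 0.75/0.75, both non-strict exactly as the inequalities are
conventionally printed — a prey at exactly (0.75, 0.75) passes both. This
boundary behaviour is deliberate and tested, because it is surprising.

The contaminant-frequency filter retains a call iff its detection count
over the repository's control IP panel, divided by the panel size (default
126), is strictly below `f_max` (default 0.40; "less than 40%"). Preys
absent from the repository have frequency 0. Detection is any non-missing
value, with no intensity threshold. The threshold filter and the
frequency filter are independent per-prey predicates, so their order does
not affect membership; thresholds run first only so that provenance
records the narrowing in procedure order.

Ranking uses mean valid log2 intensity in the bait's replicates minus the
same mean in the control's, a control-undetected prey contributing a
control mean of 0 so that control-absent preys rank on their absolute
bait intensity (top of the list). Ties break lexicographically by prey id
— an arbitrary but deterministic rule, required for byte-stable outputs.

## Comparison, exports, enrichment

Shared/unique partners are exact set operations on prey ids. Exports (SIF
edges, node attributes, heatmap matrices with missing as `NA`, TSV call
tables) are sorted deterministically; identical inputs give byte-identical
files. The heatmap matrix includes both the bait's and the control's
replicate columns, since the pull-down-vs-control contrast is what such
heatmaps display.

Over-representation is a plain hypergeometric upper tail: for a universe
of N ids, a term with K members in the universe, and a query of n ids
overlapping the term in k, p = P(X ≥ k); adjustment across terms uses the
Holm procedure (the standard reading of "Bonferroni step-down"). The
universe is a required explicit input — results are meaningless without a
stated background, and the package does not guess one. Matching is on
protein-group id; supply a mapping upstream if annotation sets use gene
symbols.

## Synthetic data generator

The generator emulates the target design: baits (FOSL1, FOSL2, IgG), 3
biological × 3 technical replicates, 1000 protein groups. Per prey, a base
log2 intensity ~ Normal(mu_log2 = 24, sigma_log2 = 0.5) (raw-scale
log-normal, the shape LFQ intensities actually have); biological-replicate
effects Normal(0, 0.25) and technical noise Normal(0, 0.1) in log2 units;
6 flagged decoy rows exercising the flag filter. Planted structure:

- 50 true interactors per test bait, 20 of them shared, enriched by
  `enrich_log2` = 6 log2 units only in their bait's runs;
- 100 frequent background binders present in every pull-down, each with a
  per-bait affinity offset ~ Normal(0, 2) log2 units (sticky proteins
  showing antibody preference) and a repository count drawn from
  [⌈0.40·126⌉, 126] so the frequency filter must remove them — without
  the affinity scatter none would pass the MiST thresholds and the filter
  would never be exercised;
- everything else is rare background with near-uniform specificity.

Missingness is intensity-dependent (missing-not-at-random): each cell
drops with probability logistic((dropout_mid − log2 intensity) ·
dropout_slope), defaults (22.0, 1.0) giving roughly 12% dropout at
background intensity and essentially none at enriched levels;
dropout_slope = 0 disables dropout. A single seed fans out into named
streams (base, affinity, replicate effects, technical noise, dropout,
repository counts), so extending one stream never perturbs another and
all outputs are byte-reproducible.

What the generator does **not** emulate: correlated peptide-level
missingness, interference between co-eluting proteins, run-order drift,
ratio compression from match-between-runs, or realistic protein-abundance
dynamic range (a single log-normal mode rather than the several-decade
skew of real lysates). Passing recovery tests therefore demonstrate that
the pipeline's logic is correct under the stated generative model, not
that real datasets of this design will yield comparable precision.

## Numerical choices and degenerate inputs

- 0·log 0 := 0 in the entropy; R is clipped into [0, 1] against rounding.
- Specificity of an all-zero prey is 0 for every bait (sum rule Σ S ∈
  {0, 1}).
- Weights renormalize at construction; all-zero or negative weights are
  rejected.
- Empty repositories are valid (every frequency 0); counts above the
  panel size are not.
- An empty call set exports a valid empty SIF; recall is 0 and precision
  is reported as NaN rather than an arbitrary 0 or 1.
- Config validation (thresholds in range, known keys only) happens before
  any file I/O, and every stage failure is reported with the stage name.

## Problem sizes

The test suite and the acceptance script run the full design at 1000
protein groups × 27 runs over 10 seeds; a complete pass of both takes
well under a minute on one CPU. Oracle comparisons for the MiST formulas
use exhaustive/loop-based reimplementations on matrices of up to 5 preys
× 3 baits × 3 replicates at 1e-12 tolerance; enrichment oracles enumerate
hypergeometric tails exactly on universes of up to 25 ids.

## Known limitations

- Comparative scoring methods (SAINT, CompPASS) and MiST's optional
  PCA-based weight retraining are not implemented.
- The contaminant repository is a frequency table, not a probabilistic
  (CRAPome-style) model; no empirical FDR is estimated.
- Enrichment does not group related terms or build term networks; it
  reports per-term statistics only.
- Identifier namespaces are the caller's responsibility; no remapping
  between protein-group ids and gene symbols is attempted.
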