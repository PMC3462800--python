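# Methods

This note documents the models and procedures implemented in `chemopath`,
the parameters that matter, the synthetic study conditions, and the design
choices made where the procedure was genuinely open.

## Data model

All matrices are pandas DataFrames aligned to a fixed, ordered `CellPanel`;
column order is preserved through every stage and never re-inferred by
name sorting. Missing entries are NaN, and `isna()` is the missingness
mask — NaN cannot collide with a valid GI50 z-score or expression value,
so no separate boolean array is carried. Expression rows must have at
least 3 observed values (the minimum for a defined correlation).

## Filtering and normalization

A chemoactivity profile is kept when **more than** `min_cells_reported`
(default 40) cell lines report a value — the rule is strict, a profile with
exactly 40 values is dropped — and when its coefficient of variation
(sd/|mean| over observed entries) is at least `min_cv` (default 0.05).
CV with |mean| below 1e-12 is ill-defined; such profiles are scored by
their sd alone, since a mean near zero on the raw scale is exactly the
regime where variation is informative rather than pathological.

Normalization is two-stage. Stage 1 standardizes each cell-line column
across compounds (full z-score by default; `stage1_mode="center"` gives
mean-centering only — the weaker reading of "remove systematic bias"),
removing per-cell sensitivity offsets. Stage 2 z-scores each compound row
over its observed cells (sample sd, ddof 1). Positive values mark
chemo-sensitive cells. Two caveats discovered in implementation:

- A *single-compound* set skips stage 1 (a per-cell bias is not estimable
  from one record; subtracting the column "mean" would zero the data).
- The literal two-stage recomposition is **not** idempotent: the column
  means of a row-z-scored matrix are O(1/√n), not zero. `normalize_chemo`
  therefore treats the `normalized` flag as a guard and returns a
  normalized set unchanged, which is the behaviour downstream code needs.

Expression genes are kept when CV > `min_cv` **and** they share at least
one pathway with another measured gene; pathways are kept when at least
`min_pathway_genes` (default 2) members are measured. Gene-symbol matching
is exact and case-sensitive after whitespace trimming: silent case-folding
makes overlap statistics irreproducible across annotation releases.

## Self-organizing map

A rectangular batch SOM (default 54 × 37 = 1998 nodes, row-major 0-based
indexing) clusters the normalized profiles. Distances are masked
Euclidean — the mean squared difference over a profile's observed cells —
so profiles with different missingness compare on the same scale.
Codebooks are initialized from data rows in greedy farthest-point order
(missing entries filled with the cell-line mean), which seeds distinct
response groups on distinct prototypes. Each epoch assigns every profile
to its best-matching unit (ties to the lowest node index), then blends
each codebook toward the neighborhood-weighted masked mean of its
assigned samples. The Gaussian neighborhood radius decays linearly from
max(rows, cols)/2 to 0.3 and the blending rate from 0.5 to 0.01 over 50
epochs. The final radius is deliberately **below one grid step**: ending
at a full grid step leaves neighboring prototypes tied together and
distinct compound clusters collapse onto a single node; sub-step radii
let the map finish in a winner-take-all refinement phase. Quantization
error consequently rises during the early smoothing phase and then falls
monotonically — the diagnostic recorded per epoch in `qe_history`.
Training is bit-reproducible for a fixed seed.

## Pathway H-scores

For each reference profile (codebook vector, or a raw compound profile
where requested) every gene's expression is Pearson-correlated over
jointly observed cells; entries with fewer than 3 overlapping cells or
zero variance are undefined and excluded from ranking. For each pathway
the correlations are jointly midranked and the two-group Kruskal-Wallis
statistic computed with the tie-correction divisor 1 − Σ(t³−t)/(N³−N);
p-values come from χ² with 1 df (two groups). The stored score is |H|
signed by sign(r̄_in − r̄_out): positivity is defined by the mean
comparison, not by a one-sided test, and a zero statistic carries no
sign. An important structural fact: because the two-group rank statistic
is a *location* statistic, a pathway whose members split evenly between
strongly positive and strongly negative correlations scores H ≈ 0 — only
a dominant direction registers. The synthetic generator (below) is built
around this.

The top-decile cut at a node keeps ceil(percentile/100 × n) pathways by
signed H descending, including boundary ties, with name as the
deterministic tie-break. Signed (not absolute) H is used: the procedure
targets coordinated positive association.

## Discriminating-gene selection

The candidate pool is the union of the top-decile pathways' measured
genes, restricted to those whose correlation with the node profile is
significant at `corr_alpha` (two-sided p from t = r√((n−2)/(1−r²))).
Trimming then iterates two Student's t-tests (pooled variance by default,
Welch by flag): per gene, expression in the current sensitive vs
insensitive cells (drop genes with p ≥ `trim_alpha`); per cell, that
cell's expression in the over-associated vs under-associated gene groups
(drop cells with p ≥ `trim_alpha`). Gene groups are fixed once by the
sign of the initial correlation; cells with chemoactivity exactly 0 count
as insensitive; a t-test with a group smaller than 2 drops the tested
item. The passes run strictly sequentially (genes, then cells) within an
iteration, terminating when a full pass drops nothing (convergence), when
one of the four classes empties (reported failure), or at `max_iter`
(default 100 — far above the bound |pool| + |cells|, since every
non-final pass drops something). Final gene order is by initial
correlation ascending (most negative first), cell order by chemoactivity
ascending, so the output is invariant to input ordering.

The permutation null (`shuffle_null_fpr`) destroys the gene-cell linkage:
in each round every discriminating gene's values are independently
permuted across the retained cells and the full iterative trim re-run
from the original class labels; the estimate is the fraction of shuffled
genes surviving to a converged set. This is deliberately the *joint*
procedure, not a single re-test at `trim_alpha` (which would return
~alpha by construction): survival requires passing the gene test in every
iteration while enough cells remain separable on noise, and the measured
rate on synthetic sets is orders of magnitude below the nominal
threshold (about 1e-5 at 10⁴ permutations).

## Evaluation

`lda_cv_accuracy` fits Fisher LDA (scikit-learn, SVD solver — which
handles p ≫ n via the pseudo-inverse-equivalent scatter decomposition;
optional auto-shrinkage via the lsqr solver) on stratified, seed-shuffled
k-folds (default 5) and reports the pooled ("consensus") held-out
accuracy: each cell predicted exactly once by the model trained without
its fold. k ≥ n degenerates to leave-one-out. Folds with a missing class
in training are redrawn (up to 10 attempts).

`method_comparison` runs four arms per unit — pathway/conventional ×
trimmed/untrimmed — with identical fold seeds so the comparison is
paired; the conventional baseline selects genes by direct correlation
(p < alpha, or a top-|r| percentile) and reuses the same trim operation.
`pathway_overlap_concordance` compares the top-decile pathway set of a
node's codebook against the sets derived from member compounds' raw
profiles, reporting |top(raw) ∩ top(node)| / |top(raw)| per draw.
`noise_degradation` bisects the white-noise sd until the mean
original-vs-degraded per-gene correlation hits a target (±0.02), then
re-derives the discriminating genes and reports the gene-count ratio.

## Enrichment

Overlap-style enrichment uses the hypergeometric upper tail
P(X ≥ k | N, K, n) via scipy, with the universe defined as the genes that
survived expression filtering — overlap probabilities must condition on
what was measurable, so published-style p-values from a different
universe are format references only. Sets need k ≥ `min_overlap`
(default 2) to be reported; ranking follows the raw p (names break ties)
with Benjamini-Hochberg values reported alongside, adjusted across all
sets tested. Only over-representation is tested.

## Synthetic study conditions

The default generator emulates an NCI60-like experiment at desk scale:
59 cells, 600 genes, 40 pathways of size 8–25, 4 compound clusters × 10
compounds, effect size 1.5, noise sd 0.5, 5% missing GI50 entries.
Construction, per cluster:

- Each cell line is sensitive in exactly half of the clusters (random
  half). This balanced design means no cell has a net sensitivity bias —
  precisely the situation the across-cell normalization stage assumes;
  with unbalanced independent splits and only a handful of clusters, the
  stage-1 column means confound cluster structure and flip borderline
  cells' signs.
- The base profile is +1 on sensitive and −1 on insensitive cells; each
  member compound adds N(0, noise_sd²) replicate noise and missingness.
- The cluster's planted pathway genes are shifted by ±effect_size/2 × base
  between classes on top of N(0, noise_sd²) expression noise (background
  genes are i.i.d. N(0,1)). Roughly three quarters shift up in sensitive
  cells and at least two members shift the other way: the dominant tilt
  gives the pathway a large positive H at its node (a 50/50 mix would
  null the rank statistic, see above), while the minority populates the
  under-expressed classes so all four discriminant classes exist.
- For a planted gene, corr(gene, base profile) has expectation
  e/√(e² + 4·sd²) — about 0.83 at the defaults — which the property tests
  check at n_cells = 500.

What the generator does **not** emulate: tissue-of-origin correlation
structure among cell lines, dose-response curve shapes, gene-gene
co-expression beyond the planted blocks, and pathway overlap/sharing of
genes. Passing tests therefore demonstrate that the machinery recovers
planted coordinated signal under honest noise and missingness — not that
it would rank real pathways correctly on real panels, where annotation
overlap and correlated backgrounds add difficulty.

Problem sizes in the test-suite and acceptance runs (3 × 3 maps for the
synthetic panels, 20-seed recovery sweeps, 25-panel comparisons, 10⁴
shuffle permutations) were chosen as the smallest sizes at which the
statistical assertions have comfortable Monte-Carlo margins; the full
54 × 37 grid is exercised where the grid size itself is the claim.

## Numerical choices

- Pearson correlations are clipped to [−1, 1]; p-values use the exact
  t-transform with |r| = 1 mapping to p = 0.
- Degenerate two-sample t-tests (both groups constant) give p = 1 on an
  exact tie and p = 0 otherwise; groups smaller than 2 are undefined and
  the tested item is dropped.
- Ties everywhere break deterministically: lowest node index for BMU
  assignment, pathway name for equal H or p, insensitive for
  zero chemoactivity.
- All stochastic stages (SOM init, folds, permutations, the generator)
  take explicit seeds; identical configuration and seed give
  byte-identical outputs, which the pipeline's digest-based stage
  skipping relies on.

## Known limitations

- The χ²₁ approximation to the two-group rank statistic is slightly
  inaccurate for very small pathways (n_in near 2); no permutation
  p-values are offered.
- Trimming applies no multiple-testing correction by design (the
  permutation null quantifies the realized false-positive rate instead).
- The SOM training schedule (epochs, rates, radius) is a declared
  default, not a fitted one; quality on real 60k-compound panels would
  need schedule tuning.
- `conventional_selection` in alpha mode inherits the node-profile's
  label noise: genes correlated with the profile's estimation error are
  admitted, which is visible in the comparison as larger conventional
  pools with no accuracy gain.
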