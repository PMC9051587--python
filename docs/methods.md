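# Methods

## The overlap model

The statistical object throughout is the two-by-two overlap between a
curated target-gene list and a predefined gene set inside a finite
background. Under the null hypothesis the targets are a simple random
sample of size *n* from the *N* background genes, so the overlap count *X*
with a set of *K* genes is hypergeometric, and the enrichment p-value is
the upper tail P(X ≥ k). Only over-representation is tested; depletion is
out of scope because the scientific question is whether targets concentrate
in a process, not whether they avoid it.

Tail probabilities are computed by summing hypergeometric point masses in
log space: each term is assembled from log-binomial coefficients via
`scipy.special.gammaln` and the terms combined with `logsumexp`. This keeps
p-values of order 1e-26 and far smaller exact to full double precision,
where a naive linear-space sum would underflow term by term. Results are
clamped to (0, 1]; a computed 0 is replaced by the smallest positive normal
double so downstream BH multiplication and log-scale reporting stay
defined. Agreement with exact rational enumeration (all valid parameter
combinations with N ≤ 12) and with `scipy.stats.hypergeom.sf` at realistic
sizes is enforced by tests.

## Background policy

*N* is the number of genes annotated in the database a gene set came from,
operationalised as the union of gene symbols across all sets in that
database's background GMT file. This is a deliberate choice: a database
"annotates" a gene exactly when the gene appears in at least one of its
sets, and it makes *N* reproducible from the deposited file alone. Sets
derived from individual publications have no database of their own and
resolve to the largest registered universe — the most conservative choice
available, since a larger *N* makes any fixed overlap less surprising.

Set genes absent from their own background are retained (K stays the raw,
reported set size) but the missing fraction is logged per set, so a
mismatched background is visible without silently changing the published
K values.

Two policies govern *n*. The default, `intersect_background`, counts only
target genes present in the resolved universe — the coherent choice, since
genes outside the universe cannot be drawn under the null. The `raw`
policy uses the full target-list size, which some published analyses
implicitly do; both are implemented and the active policy is logged, so a
reproduction attempt can try either. In the rare corner where an overlap
gene is itself missing from the universe (possible only because K is kept
raw), the gene is counted into *n* as well, keeping k ≤ min(n, K).

## Multiple testing

Benjamini–Hochberg step-up adjustment (delegated to
`statsmodels.stats.multitest`, verified in tests against the literal
min-over-suffix definition) is applied per *correction family*. The default
family is one target list's battery of tests — one column of a merged
report — matching the structure in which results are read. A `per_run`
family pooling all target lists is available. Significance is `p_adj <
alpha` with alpha = 0.05 by default.

## Evidence-based curation

Interaction tables are CTD-style TSVs; a gene enters a target list when the
union of reference identifiers across all of its interaction records (all
rows, including different descendant chemicals of the queried compound)
contains at least `min_refs = 2` distinct identifiers. Pooling per gene
rather than per row reflects the aim of gene-level evidence — two
independent single-reference reports are two pieces of evidence for the
gene; a per-row scope is available (`--evidence-scope row`) for
sensitivity analysis. Symbol harmonization applies a supplied old→current
mapping table after the evidence filter (both pre- and post-harmonization
counts are logged); unmapped symbols are kept unchanged, and collisions
collapse under set semantics with a log record. No ortholog inference or
live nomenclature queries are performed — the mapping table is the single
source of truth.

## The empirical null

The randomized-sampling confirmation draws *n* genes uniformly without
replacement from the background and records the overlap with the tested
set, R = 100,000 times by default. Because only the count matters, the
draw is reduced to sampling the marked count directly
(`numpy.random.Generator.hypergeometric`), which is distributionally
identical to identity-level sampling and orders of magnitude cheaper; a
literal gene-identity sampler is kept and cross-checked in tests. The tail
estimate is the add-one form (#exceedances + 1)/(R + 1), which can never
return exactly zero. A resampling run cannot confirm tails below its
resolution; rows with analytic p < 10/R are flagged `below_resolution`
and no agreement claim is made for them — at the default R that limit is
1e-4, far above the strongest analytic enrichments, which only the
log-space analytic path can quantify.

## Synthetic data

`make_instance` builds a labelled universe per source, draws each gene set
uniformly from its source universe, and draws the target list by weighted
sampling without replacement: a gene's weight is the maximum odds ρ over
the planted sets containing it, 1 otherwise. Sampling uses the
exponential-race construction (keys Exp(1)/w, keep the n smallest), which
is exactly sequential sampling proportional to remaining weights — a
Wallenius-type noncentral scheme — and reduces to uniform simple random
sampling at ρ = 1, i.e. to the null of the overlap test. Instances are
pure functions of (config, seed).

`vitamin_cakut_fixture` writes a file-based replica of the motivating
study's inputs by deterministic label allocation: one shuffled pool of
1,702 symbols is sliced so that the vitamin A sources have 1086 and 521
genes with 229 shared (1378 combined), the vitamin D sources 263 and 210
with 15 shared (458 combined), and the combined lists share exactly 134
genes; the tested collection carries the fourteen published set sizes
(42, 74, 315, 306, 96, 18, 38, 328, 233, 149, 47, 43, 17, 23). Universe
sizes are not printed in the study, so the fixture adopts realistic
annotation counts — GO:BP 17,600, Reactome 10,800, WikiPathways 7,800 —
nested so every target gene is present in every background. What the
fixture does **not** emulate: real gene-symbol vocabulary, the GO term
hierarchy, inter-set correlation of real databases, or any association
between targets and pathway sets (those overlaps are whatever the seeded
draws produce). Passing fixture tests therefore demonstrates that the
pipeline's arithmetic and file plumbing are correct at the study's scale,
not that the study's biological conclusions follow.

## Benchmark scales and numerical choices

The calibration and recovery suites run at the scale a desk-check can
afford while keeping the statistics meaningful: null calibration uses
2,000 tests (13 sets with the study's set sizes, n = 500, N = 10,000,
ρ = 1) and checks the empirical rate of raw p ≤ 0.05 against
0.05 + 3·√(α(1−α)/m) — hypergeometric discreteness makes the test
conservative, so rates sit visibly below α. Recovery uses 200 instances
with 3 of 13 sets planted at ρ = 5 (K = 100, n = 500, N = 10,000), where
the planted overlap expectation (≈22 genes vs 5 under the null) puts true
positives far beyond the BH threshold: observed mean TPR is ≈0.99 against
the ≥0.9 requirement, with false-positive rates near 0.01. Analytic vs
empirical agreement is checked at R = 100,000 on twelve parameter settings
spanning p from ~1e-3 to 1, within 3 binomial standard errors plus the
add-one offset 1/(R+1).

Tie-breaking and ordering are fixed everywhere: results keep the
(collection, set) input order, overlap genes are sorted lexicographically,
GMT output sorts genes within a line, and merged reports take row order
from their first source. P-values are reported in scientific notation at 3
significant digits while stored values keep full precision.

## Known limitations

- The GO term hierarchy is ignored; parent/child sets are tested as
  independent sets even though their gene content overlaps heavily, and
  the BH family treats them as distinct tests.
- Reproducing the motivating study's exact table values requires its
  deposited gene lists and background GMTs; the fixture reproduces every
  printed cardinality but the per-cell p-values on it are incidental to
  the seed.
- The background definition (union of the background GMT) may differ from
  a database's own annotation count for genes annotated only outside the
  deposited file; the registry accepts any explicitly supplied universe if
  a different definition is wanted.
- No gene-length, expression-level, or annotation-bias correction: the
  null is uniform sampling, as the overlap model assumes.
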