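# Methods

## Consensus model

A crowd decision for one photo-question is the modal answer of the raters who
saw it. Two rules are provided: **plurality** (modal answer wins outright)
and **supermajority** (the leading vote fraction must also reach a threshold
in (0.5, 1]). An exact tie for the lead, or a sub-threshold plurality, yields
the sentinel `NO_CONSENSUS` rather than a random choice: failed consensus is
a routing signal (the photo escalates to expert review), so determinism
matters more than forcing an answer. In the failure case the reported vote
fraction is that of the lexicographically smallest leading answer, so results
are reproducible across runs and platforms.

The continuous classifier score for a photo is its **vote fraction** — the
share of raters reporting the target present. Thresholding it at 0.5 recovers
the majority vote, which is why the closed-form majority accuracy
P(Binomial(n, p) > n/2) serves as an analytic oracle for the simulation.

## Crop geometry

Crop boxes are axis-aligned pixel rectangles with origin at the top-left and
half-open extents [x0, x1) × [y0, y1), so areas are exact pixel counts and
adjacent boxes sharing an edge do not overlap. Agreement between two raters'
boxes is intersection-over-union; boxes from different raters denote the same
item when they share a tag and their IoU reaches a threshold (default 0.5,
the standard detection-overlap convention). Clustering is single-linkage —
connected components of the thresholded IoU graph — with the coordinate-wise
median box as each cluster's representative. Single linkage is the right
choice here because jittered copies of one true box form a dense clique-like
cloud, while distinct items on a storefront are separated by far more than
the jitter scale; chains across distinct items would require overlapping
truth, in which case merging is arguably correct anyway.

## Usability statistics

Comparisons between task arms (e.g. storefront-only vs cropped-image raters)
use the Pearson chi-square test of homogeneity with expected counts from the
margins, df = (r−1)(c−1), and no continuity correction. Proportions are
reported with Wilson score intervals, which stay inside [0,1] and behave
sensibly at 0/n and n/n. Price crowds are summarised by arithmetic mean,
sample SD (n−1 denominator; undefined for a single reading; exactly 0 for a
unanimous crowd), count, and minimum. Price strings are parsed as decimal
currency with "$" and thousands separators stripped, rounded to cents.

## Synthetic study generator

The generator emulates the reference crowd-size design: a fixed pool of
raters who all rate the same photo set (defaults: 500 raters, 8 photos, one
binary feature at prevalence 0.5). Each rater has a sensitivity and a
specificity (default 0.75/0.75, optionally heterogeneous via a truncated
normal across the pool); rating errors are independent across raters and
photos. Price readings are the true price plus Gaussian noise (default SD
$0.25), except that with probability `distractor_rate` the rater reports a
salient cheap distractor price (default $2.59) instead — the failure mode
where a low-priced non-target ad is read as the lowest target price. Crop
boxes are the true box with independent Gaussian jitter on each edge
(default SD 4 px against ad footprints of 120–480 px), clamped to the frame.

What this does **not** model: correlated rater errors (shared confusions,
photo-level difficulty latent variables beyond per-feature accuracy), rater
learning or fatigue, spam/adversarial raters, and anything about actual
pixels. Passing tests therefore demonstrate that the procedures are correct
under independent-error crowds of known accuracy, not that any particular
real crowd attains these numbers; task difficulty is expressed by lowering
sensitivity/specificity, the simplest mechanism that reproduces
hard-item behaviour.

All generation flows from one `numpy` PCG64 stream seeded by the study
config; the seed is echoed in `manifest.json`, and identical configs produce
byte-identical output files.

## ROC/AUC and crowd-size resampling

The ROC curve sweeps the decision threshold over the distinct score values;
photos with tied scores enter as a single step (a diagonal segment). Under
this convention the trapezoidal area is identical to the Mann–Whitney
pairwise estimator with half-credit for ties, and the implementation computes
it via midranks in O(n log n). Degenerate inputs (all-positive or
all-negative gold) raise rather than return a conventional value.

Crowd-size resampling draws, for each k in the plan, M simple random
k-subsets of the rater pool — without replacement within a draw, independent
across draws (the operational reading of "jackknife subsampling" here; it is
not leave-one-out). Each draw's AUC comes from the subset's vote-fraction
scores; subsets are applied in sorted index order so floating-point summation
cannot make two identical rater sets produce different scores, which keeps
the between-sample variance exactly zero when k equals the pool size.
Summaries per k: mean, percentile confidence bounds (2.5/97.5 by default),
and between-sample SD (snapped to 0 when all draws coincide). Percentile
bounds are widened minimally to bracket the mean in the rare heavily-skewed
case (one imperfect draw among many perfect ones), preserving the
`ci_lo ≤ mean ≤ ci_hi` invariant consumers rely on.

Two decision rules read the curve. `minimal_crowd_size` returns the smallest
tested k whose mean AUC (criterion `mean`) or lower confidence bound
(criterion `ci_lower`, i.e. the whole spread of consensus) reaches the
target, defaulting to 0.90. `stabilization_point` returns the smallest k from
which the between-sample SD stays at or below epsilon (default 0.02 on the
AUC scale) for all larger tested sizes — a suffix condition, not a first
crossing, so a lucky early dip does not count.

## Workflow engine

Tiers form a DAG validated at load time (cycle detection, no dangling tier
references, and every routing table must cover `NO_CONSENSUS`). Routing rules
are evaluated in declaration order, first match wins — auditable and
deterministic. Filter tiers drop photos on an "absent" consensus; failed
consensus escalates; escalation is a terminal queue (the expert workflow
beyond that point is a configuration hook, not modelled). Every transition is
logged, and the audit log replays through the routing tables to the identical
final state.

Reverse-crop masking stores the union of found boxes as a region list (never
pixels); the masked area is the area of the rectangle union computed
geometrically, so overlapping crops are never double-counted, masking is
idempotent, and the masked area is monotone across rounds. Discoveries are
deduplicated across rounds with the same IoU clustering as crop agreement;
an item's discovery round is the earliest round containing a member of its
cluster. Payment is graded geometrically: a discovery first made in round r
pays `base_rate × multiplier^(r−1)` (defaults $0.05 and 2.0) to its
discoverers in that round, while re-finds of known items pay the base rate —
the principle that harder-to-find items pay more, given a concrete formula.

## File formats and CLI

Tabular artifacts are UTF-8 CSV with headers and RFC 4180 quoting; currency
travels as decimal strings to avoid float drift in round-trips; crop
coordinates are written as integer pixels under the half-open convention.
The CLI (`simulate | consensus | workflow run | calibrate | report`) is a
thin layer over the library; exit codes are 0 (success), 2 (input
validation), 3 (configuration). Every randomised command accepts `--seed`
and records it in its outputs.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run at desk scale, chosen so the
statistical assertions have power without long runtimes: exhaustive AUC
oracle checks on all label patterns up to 8 photos; majority-accuracy
recovery on 10,000 photos per (n, p) grid point; resampling-oracle
convergence with M = 2,000 draws from a 5-rater pool; crowd-size curves on
200-photo, 30–60-rater studies with 30–50 draws per size; 500-photo workflow
runs. Monte-Carlo assertions use 3-standard-error bands throughout.

## Known limitations

- Majority/plurality aggregation only; no latent rater-quality models
  (Dawid–Skene style confusion matrices) — deliberate scope.
- ROC analysis is unadjusted (no covariate ROC regression, no cost-sensitive
  threshold choice).
- The resampling design assumes a complete rating matrix (every rater rated
  every photo); incomplete designs are rejected rather than imputed.
- Independence of rater errors is assumed everywhere; correlated crowds will
  look better in these simulations than in the field.
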