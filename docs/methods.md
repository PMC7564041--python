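# Methods

## Model and assumptions

SSIR treats every conjunction rule over categorical descriptor levels as an
"extractor" that draws a subset of samples from the study cohort.  Under the
null hypothesis that a rule's draw is exchangeable with a uniform random
draw of the same size, the number of interest-class samples it captures is
hypergeometric: for a cohort of `a` samples with `b` of interest, a rule
condensing `c` samples of which `d` are of interest has enrichment
significance `p(d+) = Σ_{i=d}^{min(b,c)} P(i, c; b, a)` and depletion
significance `p(d−) = Σ_{i=max(0,c+b−a)}^{d} P(i, c; b, a)`.  The method's
working assumption — that systematic, deterministic rules can be scored as
if they were random draws — is an approximation: rules over correlated
descriptors produce correlated draws, and the raw cutoff `p_c` is
deliberately not corrected for the multiplicity of rules tested.  The
cutoff is instead calibrated empirically by cross-validation and the
randomization test, which is why those two protocols are part of the core
package rather than optional extras.

Votes are unit-valued (±1).  The enrichment/depletion duality
`p(d−, c; b, a) = p([b−d]+, a−c; b, a)` means a depletion rule is exactly
the complement of an enrichment rule on the complementary sample set; both
signs are admitted to the pool by default (`positive_only` disables the
negative side).  A sample's score is the sum of the votes of all pool rules
condensing it; duplicated coverage across rules and orders is allowed — the
pool is a superposition, not a disjoint partition.

## Canonical rule space

On a position with `m` levels there are `m` positive and `m` negated
selectors, but on a two-level position the negation of one level is the
positive selector of the other.  Canonical form rewrites those negations
positively, leaving `2` selectors on binary positions and `2m` otherwise
(a vacuous negation is retained on a degenerate one-level position, matching
the closed form; constant descriptors are normally removed upstream).  The
order-k space is then `Σ_{combos} Π_i w_i`, evaluated exactly as the `x^k`
coefficient of `Π_i (1 + w_i x)`; for all-binary data this is `C(n,k)·2^k`.
No further deduplication is attempted: rules that happen to select identical
sample subsets *on a particular library* remain distinct pool members, which
is the convention implied by published rule-count totals of this method.
Enumeration order is fixed (position combinations lexicographically, then
levels, then negations) so streams, logs and models are reproducible.
Exhaustive enumeration is capped at order 4; the Monte Carlo sampler draws
uniformly from the canonical space by exact integer unranking and covers
higher orders or very large spaces.

## Numerics

Float-mode probabilities use log-gamma binomials; tail sums add the shorter
tail directly (`math.fsum`) and obtain the longer one by complement, keeping
absolute error well below 1e-12 across the supported range.  An exact
`Fraction` mode reproduces small-urn probabilities as rationals (20/63,
5/126, 45/126 in the toy cohort) and anchors the float path in tests.
Training uses a per-(a, b) tail table built from a vectorized PMF grid by
cumulative sums; entries outside the support are zero, which makes tail
queries total: an upper tail below the support minimum is 1, above the
maximum 0 (and symmetrically for lower tails), so rule scoring needs no
special-casing.  Rules condensing zero samples are skipped (their upper
tail is 1, so they can never be selected with `p_c < 0.5`).  `p_c` is
restricted to (0, 0.5), which guarantees a rule receives at most one vote
sign since `p(d+) + p(d−) = 1 + P(d) ≥ 1`.

Alphabets are part of a library's schema: inferred once (sorted observed
tokens per descriptor) and preserved under sample subsetting.  This makes
every leave-one-out fold enumerate exactly the full library's rule space —
the property that renders the incremental L1O path below *identical*, not
approximately equal, to naive retraining.  In external scoring, an unseen
token fails positive selectors and satisfies negated ones; the designated
missing token (default `?`) satisfies neither, so missing data never
contributes evidence.

## Validation protocols

**Leave-one-out** retrains the entire rule selection per held-out sample.
The incremental implementation caches each rule's full-data coverage mask
and counts (c, d); removing sample i can only map a rule's counts to
(c, d), (c−1, d) or (c−1, d−1) with a−1 samples and b or b−1 of interest,
so a prefilter retains exactly those rules for which some reachable state
crosses `p_c`, and each fold re-derives its counts from the cache.  A
held-out sample's score only collects rules that condense it, whose fold
counts are (c−1, d−label_i).  Equality with literal from-scratch retraining
is asserted over randomized libraries in the test suite; the incremental
path is ~25x faster at test scales.  Folds that would lose a class entirely
are rejected up front, naming the offending sample.

**Randomization (Y-scrambling)** permutes the training labels (preserving
class counts, never touching the external set), retrains from scratch per
shuffle, and records training and external AU-ROC.  The external values are
summarized by their sample mean and standard deviation (ddof 1), the true
model's externally validated AU-ROC by its z-score against that Gaussian
and the normal upper-tail p.  Per-shuffle RNG substreams are spawned from
one master seed, so runs are reproducible and parallelizable.

AU-ROC is the mid-rank (Mann–Whitney) area computed via scikit-learn and
cross-checked in the tests against an O(n²) pairwise oracle; reversed
rankings are reported as AUC < 0.5 rather than negative values.  Confusion
metrics (accuracy, sensitivity, specificity, precision, Matthews CC) use
the neutral net-score > 0 classification threshold, configurable on the
estimator.

## Synthetic data generator

The generator emulates the *shape* of categorical call matrices: samples ×
descriptors with small per-descriptor alphabets, i.i.d. background levels
and a binary label at a requested balance.  Planted rules impose their
selector pattern on interest-class samples independently per sample with
probability `penetrance`; non-interest samples show the pattern only at
background rates, exactly matching the urn model's enrichment mechanism.
Defaults model a small two-class cohort: 40 samples, 30 binary A/P
descriptors, balanced labels, uniform background, one fully penetrant
order-2 rule.  For perfect-separation fixtures the tests use a degenerate
background (all mass on one level) so the planted pattern cannot arise by
chance and the rule is recoverable in every cross-validation fold.

What the generator deliberately does not model: correlation between
descriptors, class-dependent background composition, call-noise structure
of real array pipelines, and batch effects.  Passing tests on synthetic
libraries therefore demonstrate the correctness of the machinery —
enumeration, significance, voting, validation protocols — not the method's
discriminative performance on real transcription data, which depends on
external datasets outside this package's scope.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `orders` | (1, 2) | rule orders enumerated; exhaustive cap at 4 — higher-order rules rarely help and explode combinatorially |
| `p_c` | 0.01 | raw tail-p cutoff in (0, 0.5); tune by L1O sweep — tightening it shrinks the pool monotonically |
| `mode` / `n_rules` | exhaustive | `sample` draws `n_rules` per order uniformly (seeded) |
| `positive_only` | False | drop depletion (−1) rules |
| `missing_token` | `?` | cell token that matches no selector |
| `decision_threshold` | 0 | net score above which a sample is called positive |

Problem sizes used throughout the tests and documentation examples —
cohorts of 9–40 samples, 5–30 descriptors, 2–3 levels, up to 200 label
shuffles — were chosen as the smallest scales at which every protocol
(enumeration, L1O, Y-scrambling) exercises its full code path with stable
statistics; the counting and enumeration cross-checks additionally run the
full 3645- and 2541-descriptor binary schemas.

## Known limitations

* Exhaustive enumeration above order 2 on thousands of descriptors is
  impractical by design; use the uniform sampler.
* Rule significances are raw, correlated and uncorrected; `p_c` has no
  false-discovery interpretation and must be calibrated by validation.
* Vote totals are rank scores, not calibrated probabilities.
* The order-1 convention for descriptors whose observed level set differs
  from their declared alphabet follows the declared alphabet; libraries
  built by the readers infer alphabets from observed tokens only.
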