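# Methods

## Model and assumptions

The package operates on 2-tuple linguistic interval-valued q-rung orthopair
fuzzy numbers (2TLIVq-ROFNs). A judgement on a linguistic term set
𝔏 = {J₀, …, J_τ} is R = ([r, t], [u, y]): an interval membership and an
interval non-membership, each endpoint a linguistic 2-tuple (J_ℓ, υ) with
symbolic translation υ ∈ [−0.5, 0.5). Writing a, b, c, d for the four
τ-normalized endpoint values, validity requires interval ordering (a ≤ b,
c ≤ d) and the rung constraint b^q + d^q ≤ 1 for the chosen rung q > 0.
The rung is a modelling choice: q = 1 is the interval-valued intuitionistic
case, q = 2 the Pythagorean case, and larger q admits judgements whose
membership and non-membership are both strong. All operations assume every
operand shares one scale τ and one rung q; mixing scales raises an error.

The MABAC ranking assumes that "better" is monotone in the score function —
alternatives are compared only through their signed Hamming distances to
the per-attribute border approximation area (the geometric mean over
alternatives), and the cumulative value S_i simply adds those distances
over attributes. No interaction between attributes is modelled; attribute
weights enter multiplicatively through the scalar-multiplication law
before the border is built.

## Conventions that the implementation fixes

Several points are underdetermined in the wider literature on this model
family; the package fixes them as follows.

- **Unit-scale score/accuracy/distance.** Score, accuracy and Hamming
  distance are computed and reported on [0, 1] from τ-normalized
  components. The linguistic forms Δ(τ·K), Δ(τ·F), Δ(τ·d) are available as
  the secondary accessors `score_two_tuple`, `accuracy_two_tuple`,
  `hamming_two_tuple`. The unit scale is what published worked examples of
  this method tabulate, and it makes 0.5 a fixed neutral point independent
  of τ.
- **Term indexing.** Terms are indexed 0…τ (τ+1 labels). The embedded
  case study uses τ = 8 with nine labels.
- **Δ rounding.** round(ξ) rounds half *up* (toward the larger index), so
  υ stays in [−0.5, 0.5); at ξ = τ the result is (J_τ, 0). Half-way cases
  are rare in practice (aggregation outputs are irrational almost surely),
  so the choice is about a clean invariant, not numerics.
- **Comparison ties.** `compare` orders by score, then accuracy, treating
  differences below 1e−9 (absolute) as ties. The same band gives the
  exact-zero branch of the signed-distance step.
- **Weight-sum policy.** Theory requires Σw = 1, but elicited weight
  vectors sometimes do not satisfy it. `WeightVector` supports three
  policies: `as-given` (default; weights used verbatim, a warning logged
  when |Σw − 1| > 1e−6), `renormalize`, and `strict` (raise). The default
  keeps published inputs reproducible while surfacing the discrepancy.
  Zero weights are allowed and contribute exactly nothing.
- **Validation mode.** The rung constraint is checked in `warn` mode by
  default (log and continue). Strict validation would make rung
  sensitivity sweeps impossible: data elicited as valid at q = 6 routinely
  violates the constraint at q < 1, and the sweep is precisely the tool
  for studying that regime, so `sensitivity_sweep` always runs in warn
  mode and reports violations. Interval ordering, by contrast, is a type
  invariant and is always enforced at construction.

## Numerical choices

- Arithmetic runs on τ-normalized floats; 2-tuple encoding happens only
  when results are materialized. The encoding is exact (ℓ is recovered by
  rounding and υ = ξ − ℓ is an exact float subtraction in this range), so
  chained operations do not accumulate representation error.
- Expressions of the form 1 − Π(1 − x^q)^w lose relative precision
  catastrophically when x^q is tiny (routine at q = 6, where (3/8)^6 ≈
  3e−3 and smaller components vanish entirely): the subtraction from 1
  leaves ~1e−16 absolute noise that the subsequent q-th root amplifies to
  ~1e−8 on the unit scale. The closed forms therefore accumulate
  Σ w_j·log1p(−x^q) and finish with −expm1(·), which keeps full relative
  precision; with it, closed forms, operational-law folds and a 60-digit
  decimal re-evaluation agree to better than 1e−9.
- Conventions 0^ε = 0 (ε > 0) and x^0 = 1 are applied explicitly, and
  intermediate probabilities are clamped to [0, 1] against underflow
  before roots are taken.
- Ranking ties (equal S) are broken stably by original alternative index.
- Printed tables in reports are rounded to 4 decimals for display; all
  stored values keep full precision and all test comparisons use
  tolerances, never rounded equality.

## The embedded case study and its one irreproducible stage

The breast-cancer fixture carries every published intermediate of the
worked example: four 7×4 expert matrices, the aggregated matrix, the
weighted normalized matrix and its scores, the border approximation area
and its scores, the signed distance matrix, the cumulative values and the
ranking, together with the stated weights (expert ω′ = (0.2192, 0.2134,
0.1930, 0.1906), attribute ϖ = (0.2542, 0.2533, 0.2480, 0.2445)), q = 6,
τ = 8, and the nine term labels. The chain from the aggregated matrix
onward reproduces to within 5e−4 per 2-tuple component, ~1e−4 per score
(the published scores carry their own last-digit rounding on top of the
4-decimal rounding of the matrix they derive from), and 2e−4 per
cumulative value.

The expert-pooling stage is the exception: the stated expert weights sum
to 0.8162, and WA-pooling the expert matrices reproduces the published
aggregated matrix neither with the weights as given (max component
deviation ≈ 0.83 on the ξ scale) nor renormalized (≈ 0.29). Which weights
or procedure produced the published aggregate is not recoverable. The
pipeline therefore accepts `entry_stage="aggregated"` so that everything
verifiable anchors on published data, and
`fixtures.expert_aggregation_deviation` reports the discrepancy per cell
rather than asserting agreement. The pooling stage itself is covered by
exact property tests (idempotency, identity weights, closed-form/fold
equivalence) instead of a table regression.

Rung sweeps on the fixture run from the aggregated matrix (the published
sweep does not state its own entry point, so exact numeric agreement is
not claimed); qualitatively, the top alternative is stable from moderate
q upward while small rungs reshuffle the order, matching the published
discussion.

## Synthetic generator

`generate_cube` draws interval endpoints as a uniform lower term index plus
a bounded uniform width (defaults: τ = 8, q = 6, 4 experts × 7
alternatives × 4 attributes — the shape of the case study; `crisp=True`,
matching how raw expert judgements are published). In `enforce` mode each
entry is rejection-sampled until the rung constraint holds, with an
explicit infeasibility error after a bounded number of rejections (small
rungs can make nonzero judgements almost surely invalid). Generation is
deterministic for a fixed seed.

What the generator does *not* emulate: correlation between experts or
between attributes, systematic expert bias, or the benefit/cost mix of
real elicitations (all entries are drawn i.i.d.). Property tests on
generated instances therefore establish algebraic correctness of the
pipeline, not behaviour on realistic judgement distributions; the
case-study regression provides the realistic anchor.

## Known limitations

- Only the probabilistic-sum (algebraic) t-norm family is implemented; no
  Dombi/Hamacher variants, and no ordered-weighted or Bonferroni
  aggregation.
- Expert and attribute weights are inputs; no elicitation or
  consensus-reaching procedures.
- The CSV dialect carries crisp terms only; full-precision exchange is
  JSON.
- Theorem-level properties (idempotency, monotonicity, boundedness,
  closed-form/fold equivalence) are established by randomized testing at
  1e−9 tolerances, not by proof.
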