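# Methods

## Model and assumptions

`riverval` implements hierarchical multi-attribute value/utility
assessment.  An objectives hierarchy decomposes one root objective (the
ecological state of a river reach, level 0) into sub-objectives on levels
1–5; every lowest-level objective carries one or more measurable
attributes with a declared worst-to-best range, where "best" is the
best-achievable state under fixed constraints (existing towns, roads,
agriculture), not a pristine reference.  Assessment proceeds in three
steps: value functions map measured attribute levels onto `[0, 1]`,
aggregation functions combine child values into parent values up to the
root, and an optional utility transform applies expert risk attitude to
the root value.

Assumptions worth making explicit:

* **Piecewise-linear interpolation.**  Value functions and utility curves
  pass exactly through their elicited anchor points and are linear in
  between.  Elicitation records anchors, not a functional form; the
  piecewise-linear interpolant reproduces every anchor exactly and is
  monotone between anchors by construction.  Some experts may have
  intended smooth asymptotic curves; the difference is bounded by the
  anchor spacing and is largest midway between anchors.
* **Preferential structure.**  Additive aggregation assumes full
  compensation between siblings; minimum aggregation none; the
  multiplicative model interpolates compensation via a directly assessed
  synergy factor `k`.  Weights are local to each sibling group; a node's
  global weight (product down the path) is a derived diagnostic only.
* **Pooling by medians.**  Wherever several experts supplied the same
  quantity (weights, synergy factors, value functions for one attribute),
  the group value is the median over contributing experts.  Explicit zero
  weights contribute (they are deliberate exclusions); "not elicited /
  not applicable" entries (Ø in printed tables) do not.  Even counts take
  the midpoint of the central pair — required, for instance, to obtain
  the level-1 synergy median of 0.75 from the four contributing entries
  (1, 0.25, 0.5, 1).
* **Risk at the root only.**  Risk attitude is elicited for the overall
  objective; per-branch utilities would require per-branch expertise and
  are out of scope.  With no utility supplied the engine applies the
  identity — the risk-neutrality simplification, left explicit.

## The synergy (multiplicative) model

The multiplicative aggregate of child values `v_i` with weights `w_i`
(summing to 1) and synergy factor `k ∈ (0, 1]` uses the raw score

    r(v) = (Π_i (k · w_i · v_i + 1) − 1) / k

`k = 1` is defined as "no synergy" and dispatches to the additive formula
exactly.  For `k < 1` the raw score does not reach 1 at the all-best
profile, so the engine reports the normalized `f_mult(v) = r(v) / r(1)`,
which is 0 at all-worst and 1 at all-best.

Two consequences of this normalization deserve attention:

* `f_mult ≤ f_add` everywhere, with equality only at the extremes —
  checked on a 10⁴-point random grid in the test suite.
* `f_mult` is *not* bounded below by the minimum.  On a uniform profile
  `f_mult(v, …, v) < v = f_min` for `v ∈ (0, 1)`; e.g. with two equal
  weights and `k = 0.25`, `f_mult(0.5, 0.5) ≈ 0.485`.  A sandwich
  `f_min ≤ f_mult ≤ f_add` is therefore impossible for this functional
  form: any function equal to the additive and the minimum on the
  diagonal would have to be idempotent there, which the normalized
  product is not.  The test suite contains a deliberately failing check
  (`test_aggregator_ordering_min_mult_add_on_grid`) documenting this; the
  acceptance script reports the observed worst violation
  (`minimum_exceeds_synergy_max`, ≈ 0.036 on a random grid) rather than
  hiding it.  For divergent profiles — the case the synergy model is
  about — minimum ≤ multiplicative does hold.

Alternative readings of the synergy formula's typography (e.g. an
exponent `1/k`) fail the stated `k = 1 ⇒ additive` semantics and are not
implemented.

## Tunable parameters

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| shape-classification tolerance `tol` | 0.02 | value scale | chord deviation below visually distinguishable curvature; elicitation granularity is ~0.05 |
| risk-classification tolerance `τ` | 0.02 | value scale | attitudes are reported as "slightly" averse/prone; a band this wide absorbs elicitation noise around the diagonal |
| synergy factor `k` | per node, from {0.25, 0.5, 0.75, 1} | — | the four directly assessed levels; the engine accepts any `k ∈ (0, 1]` |
| mixed-model `α` | per node, `[0, 1]` | — | 1 = additive, 0 = minimum |
| weight-variation threshold | 0.4 (inclusive) | weight scale | the published criterion for "large" between-expert spread |
| `restrict_to_top_objectives` n | 10 | leaves | emulates the common five-to-ten-objectives practice |
| sibling-weight sum tolerance | 0.015 | — | printed weight columns can sum to 1.01 from rounding; larger deviations are flagged |
| elicitation value grid | {0, 0.1, 0.25, 0.5, 0.75, 0.9, 1} | value scale | the granularity used in the underlying elicitation protocol |

Percentages in censuses are rounded half-up to integer percent (37/49 →
76, 60/74 → 81).

## Fixtures and provenance

The packaged attribute catalogue transcribes the 80 published attribute
records verbatim: 69 distinct attribute numbers (number 24 was never
assigned and is *not* renumbered), 4 literature-sourced records, 2
discrete expert records (binary indicators), and one record ("mean
suspended solids at low flow") explicitly without a value function — it
is kept as a continuous expert record without a curve, which is the only
reading under which the published census arithmetic (76 expert records,
74 continuous) closes.  Three printed two-limb ranges have limbs that do
not share a peak level (`floodbed-P` 1–3 // 20–5, `structdiv`
0–15 // 100–17, `driftbenthos` 10–2 // 0–1.5); they are stored as printed,
flagged for review, with each limb peaking at its own best end and levels
between the limbs treated as out of range.

The consolidated hierarchy file is named
`hierarchy_consolidated_synthetic.json` because the published tree exists
only as a figure: its level counts (3/7/18/51/23), branch names, and
every objective named in the running text are as published, while the
remaining interior wiring and the placement of attributes on leaves are
an editorial reconstruction.  Analyses that depend only on counts,
weights, and catalogue contents are unaffected by the reconstruction;
analyses of specific interior nodes would not be faithful and are not
offered.  Similarly, the aggregation-choice table reproduces the
published branch totals (49 decisions: 37 multiplicative, 12 additive,
split 7/14 physical, 2-of-5 chemical, 1/26 biological, 2-of-4 top-level)
with per-record expert attribution beyond the named cases filled by
placeholders.  The certainty-equivalent sets in
`fixtures.example_ce_sets()` are synthetic stand-ins (the elicited values
are in unavailable supplementary tables) constructed to the reported
qualitative pattern: all three experts risk averse at root values 0.25
and 0.75, the BioA-style set risk prone at 0.5 with `u = 0.5` at the CE
of 0.6.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structural* study conditions: exact
per-level node counts (default 3/7/18/51/23), attribute ranges of all
three orientations, 81% non-linear value functions, 76% multiplicative
aggregation choices, synergy factors on {0.25, 0.5, 0.75, 1}, flat-simplex
(Dirichlet(1)) weights, never-neutral risk profiles, and controlled
missingness.  Non-linearity is operationalized as a mid-value anchor
displaced ≥ 0.1 (value scale) from the chord — unambiguously above the
0.02 classification tolerance, so generator labels are exact ground truth
for classifier tests.  One seeded generator is threaded through all
draws; identical spec + seed give byte-identical artifacts.

Deliberately not emulated: ecological covariance between attributes
(states are independent uniform draws), the empirical spread of expert
weights beyond the variation diagnostics, expert-specific hierarchy
variants, and any particular shape family for non-linear curves.  Passing
tests on synthetic data therefore demonstrate the *arithmetic* of the
engine (recovery, invariance, oracle equivalence), not predictive realism
for any actual river.

## Numerical choices and degenerate inputs

* Weights are validated to sum to 1 within 1e-6 at the aggregation call
  (after the engine's own renormalizations they are exact to 1e-9);
  sibling groups whose available weights sum to 0 raise.
* Missing leaf measurements drop the leaf and renormalize the surviving
  sibling weights proportionally; each renormalization is logged in the
  assessment provenance.  A node with all children missing is missing; a
  missing root raises.
* Inverse value lookups on unimodal functions require naming a limb; the
  inverse is otherwise ambiguous.
* Bisection and CE answers violating monotonicity raise as inconsistent
  elicitation; the consistency checker returns the violating pairs
  instead when a report is wanted.
* Noisy synthetic transcripts are clipped strictly inside the attribute
  range and re-monotonized by sorting in the orientation's direction,
  with strict ordering enforced at 1e-9 of the range span.
* The exponential utility fit is a diagnostic summary only (constant
  risk aversion); assessment always uses the piecewise-linear
  interpolant.

## Design choices where the design was open

* The root ("ecological state") is modelled at level 0 so the published
  level-1 weights attach to its children and the published level counts
  exclude the root.
* Attribute identity is the printed abbreviation (unique), not the
  printed number (duplicated across experts for shared quantities).
* Swing and reversed swing share one normalization; the framing
  difference is metadata (`reversed_frame`).
* Rank agreement in model comparisons uses pairwise
  concordant/discordant counting with ties counted separately
  (`(C − D) / pairs`), which equals Kendall's tau-a when no ties occur.
* "Linearize" replaces each continuous limb by its endpoint chord and
  leaves discrete functions untouched.
* The excluded "good water quality" branch is present as a structural
  placeholder node flagged non-assessable, so the level-2 count of seven
  is preserved without pretending the branch can be scored.

## Problem sizes

Default test and acceptance runs use compact problem sizes chosen to
exercise every code path: 100 random hierarchies (2–5 nodes per level,
three levels) for the roll-up oracle check, a 10⁴-point random grid for
aggregator contracts, ~540 generated value functions for classifier
agreement, 50 replicates for each noiseless-recovery check, and 200
replicates per noise level for the noise-degradation ordering.  The full
suite completes in a few seconds on one CPU.

## Known limitations

* Interior wiring of the packaged hierarchy below level 2 is
  reconstructed, not transcribed (see Fixtures above).
* The published 19%/81% linear/non-linear split, the "12 of 85"
  weight-variation count, and branch-level weight medians cannot be
  recomputed here: they require per-expert tables that were never
  machine-readable.  The corresponding operations exist and are
  exercised on synthetic data instead.
* Value functions outside their declared range raise rather than
  extrapolate; callers must decide how to handle out-of-range
  measurements.
* The synergy model's sub-minimum behaviour on near-uniform profiles is
  a property of the assessed functional form itself (see above), not an
  implementation artifact.
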