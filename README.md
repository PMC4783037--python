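# riverval

Hierarchical multi-attribute value/utility assessment for ecological river
evaluation.

River rehabilitation has to trade off many ecological objectives at once —
a good physical, chemical, and biological state each decompose into dozens
of measurable indicators.  Multi-attribute value theory (MAVT/MAUT) handles
this by arranging the objectives in a hierarchy, translating each measured
attribute level onto a common value scale `v ∈ [0, 1]` with an elicited
value function, and aggregating values level by level up to a single root
score.  `riverval` implements that machinery for river assessment and
packages an elicited expert preference set for a Swiss gravel-bed river
(the lower Wigger): a consolidated hierarchy of 102 objectives on five
levels, a catalogue of 80 attribute records, level-1 weights, aggregation
choices, and synergy factors from six river experts.

It is written for decision analysts and river scientists who want to run
value-function based assessments, and to examine how four common
simplifications — few objectives, linear value functions, additive
aggregation, risk neutrality — distort results relative to fully elicited
preferences.

## The model

* **Value functions** `v(x)`: piecewise-linear monotone (or two-limb
  unimodal) maps from an attribute's natural scale to `[0, 1]`, anchored at
  the worst (`v = 0`) and best (`v = 1`) achievable levels and at elicited
  mid-value points (bisection method: `x_0.5` is the level judged halfway
  in value).
* **Aggregation** of child values `v_i` with weights `w_i` (`Σ w_i = 1`):
  - additive: `f_add = Σ w_i v_i`
  - minimum (one-out-all-out): `f_min = min(v_i)`
  - multiplicative with synergy factor `k ∈ (0, 1]`:
    `r(v) = (Π(k w_i v_i + 1) − 1)/k`, normalized as `f_mult = r(v)/r(1)`;
    `k = 1` is exactly the additive model, smaller `k` rewards improving
    all sub-objectives together
  - mixed: `α f_add + (1 − α) f_min`
* **Weights** from swing, reversed-swing, or direct rating (scores
  normalized to sum 1); multiple experts are pooled by the group median
  (explicit zeros count, "not elicited" does not).
* **Risk attitude**: certainty equivalents `x_0.25, x_0.5, x_0.75` for
  50–50 lotteries define a monotone utility `u` with `u(x_p) = p`; a CE
  below the lottery's expected value (concave `u`) is risk averse, above
  it risk prone.  Utilities apply at the root objective.

## Worked example

```python
import riverval as rv
from riverval import fixtures as fx

h = fx.load_consolidated_hierarchy()
rv.count_by_level(h)
# {'per_level': (3, 7, 18, 51, 23), 'total': 102}

vf = fx.nase_value_function()          # adult nase, 0-2000 individuals
rv.evaluate(vf, 150), rv.evaluate(vf, 300), rv.evaluate(vf, 1150)
# (0.25, 0.5, 0.75)                    # first fish matter most ...
rv.classify_shape(vf)
# 'nonlinear'                          # ... far off the straight chord

medians = fx.load_level1_weight_table().medians()
# {'physical': 0.28, 'chemical': 0.23, 'biological': 0.45}
w = rv.direct_rating_weights(list(medians.values()))   # -> sum to 1
v = (0.62, 0.55, 0.43)                 # physical, chemical, biological
round(rv.aggregate_additive(v, w), 4)          # 0.5142
round(rv.aggregate_multiplicative(v, w, 0.75), 4)  # 0.4628
rv.aggregate_minimum(v)                        # 0.43

u = rv.utility_from_ce(fx.example_ce_sets()["BioA"])
round(rv.apply_risk(0.4628, u), 4)             # 0.4183
```

The three aggregates show the compensation spectrum: the additive score
(0.5142) lets the weaker biological state be offset by the others, the
minimum (0.43) is dictated by it alone, and the synergy model with
`k = 0.75` (0.4628) sits between.  The final line converts the root value
to a utility under a risk-prone-at-medium-state expert: below the medium
state the curve lies under the diagonal, so the utility (0.4183) is lower
than the value.

A command-line interface mirrors the library:

```sh
riverval validate src/riverval/data/hierarchy_consolidated_synthetic.json
riverval summarize --report report.json
riverval simulate --seed 4 --out sim/ && \
    riverval assess --hierarchy sim/hierarchy.json --model sim/model.json \
        --state sim/states.csv --value-functions sim/value_functions.json
riverval compare --simplify linear,additive --states 20
```

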