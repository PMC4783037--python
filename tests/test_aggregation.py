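import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riverval.aggregation import (
    AggregationError,
    AggregationSpec,
    aggregate_additive,
    aggregate_minimum,
    aggregate_mixed,
    aggregate_multiplicative,
    rollup,
)
from riverval.synthetic import GeneratorSpec, generate_preferences, generate_states
from riverval.value_functions import construct_from_bisection

from conftest import recursive_rollup


class TestAdditive:
    def test_constant_inputs_idempotent(self):
        assert aggregate_additive([0.5, 0.5, 0.5], [0.2, 0.3, 0.5]) == 0.5

    def test_level1_weights_dot_product(self):
        # published level-1 weights of the Fish expert
        out = aggregate_additive([0.8, 0.6, 0.9], [0.32, 0.23, 0.45])
        assert out == pytest.approx(0.799)

    def test_equal_weights_are_arithmetic_mean(self):
        v = [0.1, 0.4, 0.7]
        assert aggregate_additive(v, [1 / 3] * 3) == pytest.approx(np.mean(v))

    @pytest.mark.parametrize(
        "values, weights",
        [([0.5], [0.5, 0.5]), ([0.5, 0.5], [0.9, 0.3])],
    )
    def test_contract_violations_raise(self, values, weights):
        with pytest.raises(AggregationError):
            aggregate_additive(values, weights)


class TestMinimum:
    def test_returns_worst(self):
        assert aggregate_minimum([0.2, 0.9, 0.7]) == 0.2

    def test_all_equal(self):
        assert aggregate_minimum([0.4, 0.4]) == 0.4

    def test_insensitive_to_better_children(self):
        base = aggregate_minimum([0.2, 0.5, 0.7])
        assert aggregate_minimum([0.2, 0.9, 0.95]) == base

    def test_empty_raises(self):
        with pytest.raises(AggregationError):
            aggregate_minimum([])


class TestMultiplicative:
    def test_k_one_is_exactly_additive(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(2, 6)
            w = rng.dirichlet(np.ones(n))
            v = rng.random(n)
            assert aggregate_multiplicative(v, w, 1.0) == aggregate_additive(v, w)

    def test_all_zero_gives_zero_all_one_gives_one(self):
        for k in (0.25, 0.5, 0.75):
            assert aggregate_multiplicative([0, 0, 0], [0.2, 0.3, 0.5], k) == 0
            assert aggregate_multiplicative([1, 1, 1], [0.2, 0.3, 0.5], k) == (
                pytest.approx(1.0))

    def test_hand_computed_example(self):
        # raw 0.5 normalized by raw(1,1) = 1.125
        out = aggregate_multiplicative([1, 0], [0.5, 0.5], 0.5)
        assert out == pytest.approx(4 / 9, abs=1e-12)

    def test_k_outside_range_raises(self):
        for k in (0, -0.5, 1.5):
            with pytest.raises(AggregationError):
                aggregate_multiplicative([0.5, 0.5], [0.5, 0.5], k)

    def test_never_exceeds_additive(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(2, 6))
            w = rng.dirichlet(np.ones(n))
            v = rng.random(n)
            k = float(rng.choice([0.25, 0.5, 0.75]))
            assert (aggregate_multiplicative(v, w, k)
                    <= aggregate_additive(v, w) + 1e-12)

    def test_self_aggregation_below_diagonal_for_synergy(self):
        # with k < 1 a uniform profile scores below its own value ...
        for v in np.linspace(0.05, 0.95, 10):
            out = aggregate_multiplicative([v] * 4, [0.25] * 4, 0.25)
            assert out <= v + 1e-12
        # ... which also means the minimum can exceed the aggregate there
        assert aggregate_multiplicative([0.5, 0.5], [0.5, 0.5], 0.25) < 0.5


class TestMixed:
    def test_alpha_limits(self):
        v, w = [0.3, 0.9], [0.5, 0.5]
        assert aggregate_mixed(v, w, 1.0) == aggregate_additive(v, w)
        assert aggregate_mixed(v, w, 0.0) == aggregate_minimum(v)

    def test_hand_example(self):
        assert aggregate_mixed([1, 0], [0.5, 0.5], 0.5) == pytest.approx(0.25)

    def test_alpha_out_of_range(self):
        with pytest.raises(AggregationError):
            aggregate_mixed([0.5, 0.5], [0.5, 0.5], 1.2)


class TestSpec:
    def test_parameter_presence_enforced(self):
        with pytest.raises(AggregationError):
            AggregationSpec("n", "multiplicative", (0.5, 0.5))
        with pytest.raises(AggregationError):
            AggregationSpec("n", "additive", (0.5, 0.5), k=0.5)
        with pytest.raises(AggregationError):
            AggregationSpec("n", "mixed", (0.5, 0.5))


@settings(max_examples=60, deadline=None)
@given(
    data=st.data(),
    n=st.integers(2, 5),
    method=st.sampled_from(["additive", "minimum", "multiplicative", "mixed"]),
)
def test_monotone_in_every_input(data, n, method):
    """Improving any single child never decreases any aggregate."""
    v = np.array(data.draw(st.lists(
        st.floats(0, 1), min_size=n, max_size=n)))
    raw_w = np.array(data.draw(st.lists(
        st.floats(0.01, 1), min_size=n, max_size=n)))
    w = raw_w / raw_w.sum()
    i = data.draw(st.integers(0, n - 1))
    bump = data.draw(st.floats(0.0, 1.0))
    v2 = v.copy()
    v2[i] = min(1.0, v2[i] + bump)
    kwargs = {}
    if method == "multiplicative":
        kwargs = {"k": data.draw(st.sampled_from([0.25, 0.5, 0.75, 1.0]))}
    elif method == "mixed":
        kwargs = {"alpha": data.draw(st.floats(0, 1))}

    def f(values):
        if method == "minimum":
            return aggregate_minimum(values)
        if method == "additive":
            return aggregate_additive(values, w)
        if method == "multiplicative":
            return aggregate_multiplicative(values, w, kwargs["k"])
        return aggregate_mixed(values, w, kwargs["alpha"])

    assert f(v2) >= f(v) - 1e-12


def test_zero_weight_children_never_matter():
    rng = np.random.default_rng(3)
    for _ in range(50):
        w = np.array([0.6, 0.4, 0.0])
        v = rng.random(3)
        v_alt = v.copy()
        v_alt[2] = rng.random()
        for f in (
            lambda vv: aggregate_additive(vv, w),
            lambda vv: aggregate_multiplicative(vv, w, 0.5),
            lambda vv: aggregate_mixed(vv, w, 1.0),
        ):
            assert f(v) == pytest.approx(f(v_alt), abs=1e-12)


class TestRollup:
    def test_all_best_levels_give_one_everywhere(self, small_prefs):
        fx = small_prefs.fixture
        state = {}
        for abbr, attr in fx.hierarchy.catalogue.items():
            state[abbr] = attr.peak if attr.is_unimodal else attr.best
        result = rollup(fx.hierarchy, state, fx.specs, fx.value_functions)
        for nid, val in result.node_values.items():
            assert val == pytest.approx(1.0, abs=1e-9), nid

    def test_toy_matches_hand_composition(self, toy_hierarchy):
        from riverval.value_functions import from_attribute

        vfs = {a: [from_attribute(attr)]
               for a, attr in toy_hierarchy.catalogue.items()}
        specs = {
            "root": AggregationSpec("root", "multiplicative", (0.6, 0.4), k=0.5),
            "A": AggregationSpec("A", "additive", (0.7, 0.3)),
            "B": AggregationSpec("B", "minimum", (1.0,)),
        }
        state = {"x1": 5.0, "x2": 25.0, "x3": 0.4}
        result = rollup(toy_hierarchy, state, specs, vfs)
        va = 0.7 * 0.5 + 0.3 * 0.75  # x2 decreasing: (100-25)/100
        vb = 0.4
        raw = (0.5 * 0.6 * va + 1) * (0.5 * 0.4 * vb + 1) - 1
        expected = (raw / 0.5) / (((1.3 * 1.2) - 1) / 0.5)
        assert result.root_value == pytest.approx(expected, abs=1e-12)
        assert result.node_values["A"] == pytest.approx(va)

    def test_missing_leaf_renormalizes_sibling(self, toy_hierarchy):
        from riverval.value_functions import from_attribute

        vfs = {a: [from_attribute(attr)]
               for a, attr in toy_hierarchy.catalogue.items()}
        specs = {
            "root": AggregationSpec("root", "additive", (0.5, 0.5)),
            "A": AggregationSpec("A", "additive", (0.7, 0.3)),
        }
        state = {"x1": 5.0, "x3": 0.4}  # x2 missing
        result = rollup(toy_hierarchy, state, specs, vfs)
        assert result.node_values["A"] == pytest.approx(0.5)  # weight 1 on a1
        assert any("renormalized" in line for line in result.provenance)

    def test_root_unassessable_raises(self, toy_hierarchy):
        with pytest.raises(AggregationError, match="root"):
            rollup(toy_hierarchy, {}, {}, {})

    def test_median_pools_multiple_sources(self, toy_hierarchy):
        vf_a = construct_from_bisection("x1", 0, 10)
        vf_b = construct_from_bisection("x1", 0, 10, {0.5: 2.0})
        vfs = {"x1": [vf_a, vf_b]}
        state = {"x1": 2.0}
        sub = rollup(toy_hierarchy, state, {}, vfs)
        # median of (0.2, 0.5); other leaves missing
        assert sub.node_values["a1"] == pytest.approx(0.35)

    def test_oracle_equivalence_on_generated_hierarchies(self):
        rng = np.random.default_rng(42)
        for rep in range(25):
            spec = GeneratorSpec(
                level_counts=tuple(int(c) for c in rng.integers(2, 7, size=3)),
                missingness=0.2,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            prefs = generate_preferences(spec)
            fx = prefs.fixture
            states = generate_states(fx.hierarchy, 4, spec.missingness,
                                     seed=int(rng.integers(0, 2**31 - 1)))
            for _, row in states.iterrows():
                state = row.to_dict()
                mine = rollup(fx.hierarchy, state, fx.specs,
                              fx.value_functions).root_value
                oracle = recursive_rollup(fx.hierarchy, state, fx.specs,
                                          fx.value_functions)
                assert mine == pytest.approx(oracle, abs=1e-12)
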