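import numpy as np
import pytest

from riverval.elicitation import ExpertWeightTable
from riverval.fixtures import (
    load_aggregation_choices,
    load_level1_weight_table,
    load_value_function_records,
)
from riverval.simplification import (
    SimplificationConfig,
    compare_models,
    round_half_up_pct,
    summarize_aggregations,
    summarize_shapes,
    summarize_weight_variation,
    synergy_demo,
)
from riverval.synthetic import GeneratorSpec, generate_preferences, generate_states


class TestRounding:
    @pytest.mark.parametrize(
        "fraction, expected",
        [(37 / 49, 76), (60 / 74, 81), (0.5, 50), (0.755, 76), (0.005, 1)],
    )
    def test_half_up(self, fraction, expected):
        assert round_half_up_pct(fraction) == expected


class TestShapeCensus:
    def test_packaged_catalogue_counts(self):
        census = summarize_shapes(load_value_function_records())
        assert census["n_total"] == 80
        assert census["n_expert"] == 76
        assert census["n_literature"] == 4
        assert census["n_continuous_expert"] == 74
        assert census["n_discrete"] == 4

    def test_counts_partition_input(self):
        census = summarize_shapes(load_value_function_records())
        assert census["n_expert"] + census["n_literature"] == census["n_total"]
        assert census["n_continuous"] + census["n_discrete"] == census["n_total"]
        assert census["n_linear"] + census["n_nonlinear"] == census["n_classified"]

    def test_all_linear_synthetic_set(self):
        prefs = generate_preferences(
            GeneratorSpec(level_counts=(2, 4, 8), pct_nonlinear=0.0, seed=5))
        vfs = [vf for fns in prefs.fixture.value_functions.values()
               for vf in fns]
        census = summarize_shapes(vfs)
        assert census["pct_nonlinear"] == 0
        assert census["n_nonlinear"] == 0

    def test_generator_hits_nonlinear_target(self):
        # 99% binomial CI of p=0.8 at n>=500
        prefs = generate_preferences(
            GeneratorSpec(level_counts=(3, 30, 360), pct_nonlinear=0.8, seed=3))
        vfs = [vf for fns in prefs.fixture.value_functions.values()
               for vf in fns if vf.kind == "continuous"]
        assert len(vfs) >= 500
        census = summarize_shapes(vfs)
        frac = census["n_nonlinear"] / census["n_classified"]
        half_width = 2.576 * np.sqrt(0.8 * 0.2 / census["n_classified"])
        assert abs(frac - 0.8) <= half_width


class TestAggregationCensus:
    def test_packaged_decisions(self):
        census = summarize_aggregations(load_aggregation_choices())
        assert census["n_total"] == 49
        assert census["n_additive"] == 12
        assert census["n_multiplicative"] == 37
        assert census["pct_multiplicative"] == 76

    def test_all_additive(self):
        census = summarize_aggregations(["additive"] * 7)
        assert census["pct_multiplicative"] == 0

    def test_equal_split(self):
        census = summarize_aggregations(
            ["additive"] * 5 + ["multiplicative"] * 5)
        assert census["pct_multiplicative"] == 50

    def test_counts_sum_to_total(self):
        census = summarize_aggregations(load_aggregation_choices())
        assert sum(census["by_method"].values()) == census["n_total"]


class TestWeightVariationCensus:
    def test_level1_rows_two_of_three_large(self):
        out = summarize_weight_variation([load_level1_weight_table()])
        assert out["n_objectives"] == 3
        # ranges: physical 0.32, chemical 0.44, biological 0.72
        assert out["ranges"]["physical"] == pytest.approx(0.32)
        assert out["ranges"]["chemical"] == pytest.approx(0.44)
        assert out["ranges"]["biological"] == pytest.approx(0.72)
        assert out["n_large"] == 2

    def test_identical_columns_give_zero(self):
        table = ExpertWeightTable(
            ("a", "b"), ("e1", "e2"),
            {("a", "e1"): 0.5, ("a", "e2"): 0.5,
             ("b", "e1"): 0.5, ("b", "e2"): 0.5})
        assert summarize_weight_variation([table])["n_large"] == 0

    def test_injected_ranges_recovered_exactly(self):
        rng = np.random.default_rng(9)
        objectives, cells = [], {}
        experts = ("e1", "e2", "e3")
        n_large_truth = 0
        for i in range(40):
            name = f"o{i}"
            objectives.append(name)
            base = rng.uniform(0.05, 0.4)
            wide = bool(rng.random() < 0.3)
            spread = rng.uniform(0.45, 0.55) if wide else rng.uniform(0.0, 0.3)
            n_large_truth += wide
            cells[(name, "e1")] = base
            cells[(name, "e2")] = base + spread
            cells[(name, "e3")] = base + spread / 2
        table = ExpertWeightTable(tuple(objectives), experts, cells)
        out = summarize_weight_variation([table])
        assert out["n_objectives"] == 40
        assert out["n_large"] == n_large_truth


@pytest.fixture(scope="module")
def prefs_and_states():
    prefs = generate_preferences(
        GeneratorSpec(level_counts=(3, 6, 14), seed=21))
    states = generate_states(prefs.fixture.hierarchy, 12, seed=22)
    return prefs, states


class TestCompareModels:
    def test_all_flags_off_is_identity(self, prefs_and_states):
        prefs, states = prefs_and_states
        cmp = compare_models(prefs.fixture, SimplificationConfig(), states)
        np.testing.assert_allclose(cmp.scores_full, cmp.scores_simplified)
        assert cmp.reversals == []
        assert cmp.concordance == 1.0

    def test_linearize_is_fixed_point_on_linear_fixture(self):
        prefs = generate_preferences(
            GeneratorSpec(level_counts=(2, 4, 9), pct_nonlinear=0.0, seed=8))
        states = generate_states(prefs.fixture.hierarchy, 8, seed=9)
        cmp = compare_models(
            prefs.fixture,
            SimplificationConfig(linearize_value_functions=True), states)
        np.testing.assert_allclose(cmp.scores_full, cmp.scores_simplified,
                                   atol=1e-12)

    def test_force_additive_identity_when_k_one_everywhere(self):
        prefs = generate_preferences(
            GeneratorSpec(level_counts=(2, 5, 10), pct_multiplicative=1.0,
                          synergy_distribution=((1.0, 1.0),), seed=13))
        states = generate_states(prefs.fixture.hierarchy, 8, seed=14)
        cmp = compare_models(
            prefs.fixture, SimplificationConfig(force_additive=True), states)
        np.testing.assert_allclose(cmp.scores_full, cmp.scores_simplified,
                                   atol=1e-12)

    def test_restriction_keeps_n_leaves(self, prefs_and_states):
        prefs, states = prefs_and_states
        cmp = compare_models(
            prefs.fixture,
            SimplificationConfig(restrict_to_top_objectives=5), states)
        assert len(cmp.scores_simplified) == len(states)
        assert np.all(cmp.scores_simplified >= 0)
        assert np.all(cmp.scores_simplified <= 1)

    def test_concordance_matches_kendall_when_no_ties(self, prefs_and_states):
        from scipy.stats import kendalltau

        prefs, states = prefs_and_states
        cmp = compare_models(
            prefs.fixture,
            SimplificationConfig(force_additive=True,
                                 linearize_value_functions=True),
            states)
        if cmp.tied == 0:
            tau = kendalltau(cmp.scores_full, cmp.scores_simplified).statistic
            assert cmp.concordance == pytest.approx(tau)


class TestSynergyDemo:
    def test_k_one_curves_coincide(self):
        demo = synergy_demo([0.25] * 4, 1.0, n_grid=21)
        np.testing.assert_allclose(demo["joint"], demo["lone"], atol=1e-12)

    def test_synergy_separates_curves_at_top(self):
        demo = synergy_demo([0.25] * 4, 0.25, n_grid=21)
        assert demo["joint"][-1] == pytest.approx(1.0)
        assert demo["lone"][-1] < 1.0

    def test_two_objective_hand_value(self):
        demo = synergy_demo([0.5, 0.5], 0.5, n_grid=3)
        assert demo["lone"][-1] == pytest.approx(2 * 4 / 9)

    @pytest.mark.parametrize("k", [0.25, 0.5, 0.75, 1.0])
    def test_curves_monotone(self, k):
        demo = synergy_demo([0.4, 0.3, 0.3], k, n_grid=41)
        assert np.all(np.diff(demo["joint"]) >= -1e-12)
        assert np.all(np.diff(demo["lone"]) >= -1e-12)
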