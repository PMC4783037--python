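import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None,
                          deadline=None)
settings.load_profile("deterministic")

from riverval import fixtures
from riverval.hierarchy import Attribute, Hierarchy, ObjectiveNode
from riverval.synthetic import GeneratorSpec, generate_preferences


@pytest.fixture(scope="session")
def consolidated():
    return fixtures.load_consolidated_hierarchy()


@pytest.fixture(scope="session")
def catalogue():
    return fixtures.load_attribute_catalogue()


@pytest.fixture(scope="session")
def level1_table():
    return fixtures.load_level1_weight_table()


@pytest.fixture
def toy_hierarchy():
    """Two-level toy: 3 leaves under 2 internal nodes under the root."""
    nodes = [
        ObjectiveNode("root", "Overall", 0),
        ObjectiveNode("A", "Branch A", 1, "root"),
        ObjectiveNode("B", "Branch B", 1, "root"),
        ObjectiveNode("a1", "Leaf a1", 2, "A", attributes=["x1"]),
        ObjectiveNode("a2", "Leaf a2", 2, "A", attributes=["x2"]),
        ObjectiveNode("b1", "Leaf b1", 2, "B", attributes=["x3"]),
    ]
    attrs = [
        Attribute("x1", worst=0.0, best=10.0),
        Attribute("x2", worst=100.0, best=0.0),
        Attribute("x3", worst=0.0, best=1.0),
    ]
    return Hierarchy(nodes, attrs)


@pytest.fixture(scope="session")
def small_prefs():
    """A compact generated preference set shared across tests."""
    return generate_preferences(GeneratorSpec(level_counts=(3, 6, 12), seed=11))


def recursive_rollup(h, state, specs, vfs, node_id=None):
    """Independent straight-line evaluator used as the roll-up oracle.

    Plain recursion applying the aggregation formulas inline; shares no
    code path with riverval.aggregation.rollup.
    """
    import statistics

    from riverval.value_functions import evaluate

    node = h.nodes[node_id or h.root.id]
    if node.is_leaf:
        if not node.assessable or not node.attributes:
            return None
        vals = []
        for abbr in node.attributes:
            x = state.get(abbr)
            if x is None or (isinstance(x, float) and np.isnan(x)):
                continue
            sources = vfs.get(abbr, ())
            if not sources:
                continue
            vals.append(statistics.median(evaluate(vf, x) for vf in sources))
        return statistics.median(vals) if vals else None
    child_vals, child_ws = [], []
    spec = specs.get(node.id)
    weights = (spec.weights if spec is not None and spec.weights
               else [1 / len(node.children)] * len(node.children))
    for cid, w in zip(node.children, weights):
        cv = recursive_rollup(h, state, specs, vfs, cid)
        if cv is not None:
            child_vals.append(cv)
            child_ws.append(w)
    if not child_vals or sum(child_ws) == 0:
        return None
    ws = np.array(child_ws) / sum(child_ws)
    vs = np.array(child_vals)
    method = spec.method if spec is not None else "additive"
    if method == "minimum":
        return float(vs.min())
    if method == "additive" or (method == "multiplicative" and spec.k == 1):
        return float(ws @ vs)
    if method == "multiplicative":
        k = spec.k
        raw = (np.prod(k * ws * vs + 1) - 1) / k
        return float(raw / ((np.prod(k * ws + 1) - 1) / k))
    return float(spec.alpha * (ws @ vs) + (1 - spec.alpha) * vs.min())
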