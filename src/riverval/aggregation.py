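"""Aggregation models and hierarchical roll-up of attribute values.

Values of sub-objectives are combined level by level up to the root.  Four
aggregation functions are supported:

* additive — the weighted arithmetic mean, f = Σ w_i v_i (full
  compensation between sub-objectives);
* minimum — one-out-all-out, f = min(v_i) (no compensation);
* multiplicative — a synergy-weighted product with a directly assessed
  synergy factor k ∈ (0, 1]; k = 1 means no synergy and is exactly the
  additive model, smaller k rewards improving all sub-objectives jointly;
* mixed — a convex combination α·f_add + (1−α)·f_min, tempering both the
  full compensation of the additive model and the pessimism of the minimum.

For k < 1 the multiplicative raw score r(v) = (Π(k·w_i·v_i + 1) − 1)/k is
divided by r(1, …, 1) so that the aggregate is 0 when every sub-objective
is at its worst and 1 when every one is at its best.  The result never
exceeds the additive aggregate; note that for near-uniform value profiles
it can drop slightly below the minimum (see docs/methods.md).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .hierarchy import Hierarchy, renormalize_weights
from .value_functions import ValueFunction, ValueFunctionError, evaluate

SYNERGY_LEVELS = (0.25, 0.5, 0.75, 1.0)

_WTOL = 1e-9


class AggregationError(ValueError):
    pass


def _check(values: Sequence[float], weights: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise AggregationError("values and weights differ in length")
    if v.size == 0:
        raise AggregationError("empty input")
    if np.any(w < 0):
        raise AggregationError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-6:
        raise AggregationError(f"weights must sum to 1 (got {w.sum():.6f})")
    return v, w


def aggregate_additive(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted arithmetic mean of the child values."""
    v, w = _check(values, weights)
    return float(w @ v)


def aggregate_minimum(values: Sequence[float]) -> float:
    """Worst child value (one-out-all-out)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise AggregationError("empty input")
    return float(v.min())


def aggregate_multiplicative(
    values: Sequence[float], weights: Sequence[float], k: float
) -> float:
    """Synergy aggregation with factor ``k`` ∈ (0, 1].

    ``k = 1`` (no synergy) dispatches to the additive model exactly; for
    ``k < 1`` the raw product score is normalized by its all-ones value so
    the [0, 1] contract holds at the extremes.
    """
    if not 0 < k <= 1:
        raise AggregationError(f"synergy factor k={k} outside (0, 1]")
    v, w = _check(values, weights)
    if k == 1:
        return float(w @ v)
    raw = (np.prod(k * w * v + 1.0) - 1.0) / k
    raw_best = (np.prod(k * w + 1.0) - 1.0) / k
    return float(raw / raw_best)


def aggregate_mixed(
    values: Sequence[float], weights: Sequence[float], alpha: float
) -> float:
    """Additive-minimum blend: α·f_add + (1−α)·f_min, α ∈ [0, 1]."""
    if not 0 <= alpha <= 1:
        raise AggregationError(f"alpha={alpha} outside [0, 1]")
    v, w = _check(values, weights)
    return float(alpha * (w @ v) + (1 - alpha) * v.min())


@dataclass
class AggregationSpec:
    """Per-node aggregation recipe: method, child weights, and parameters.

    ``weights`` are one per child in child order and must sum to 1 (they are
    renormalized on construction when ``normalize=True``).  ``k`` is present
    iff the method is multiplicative, ``alpha`` iff mixed.
    """

    node: str
    method: str = "additive"
    weights: tuple[float, ...] = ()
    k: float | None = None
    alpha: float | None = None

    def __post_init__(self):
        if self.method not in ("additive", "minimum", "multiplicative", "mixed"):
            raise AggregationError(f"unknown method {self.method!r}")
        if self.method == "multiplicative":
            if self.k is None:
                raise AggregationError(f"{self.node}: multiplicative needs k")
        elif self.k is not None:
            raise AggregationError(f"{self.node}: k only valid for multiplicative")
        if self.method == "mixed":
            if self.alpha is None:
                raise AggregationError(f"{self.node}: mixed needs alpha")
        elif self.alpha is not None:
            raise AggregationError(f"{self.node}: alpha only valid for mixed")
        self.weights = tuple(float(w) for w in self.weights)

    def apply(self, values: Sequence[float], weights: Sequence[float] | None = None) -> float:
        w = self.weights if weights is None else weights
        if self.method == "minimum":
            return aggregate_minimum(values)
        if self.method == "additive":
            return aggregate_additive(values, w)
        if self.method == "multiplicative":
            return aggregate_multiplicative(values, w, self.k)
        return aggregate_mixed(values, w, self.alpha)


@dataclass
class AssessmentResult:
    """Per-node values from a roll-up, with a missing-data provenance log.

    ``node_values`` maps node id -> value in [0, 1]; nodes that could not be
    assessed are absent.  Every weight renormalization triggered by missing
    children is logged in ``provenance``.
    """

    node_values: dict[str, float] = field(default_factory=dict)
    root_utility: float | None = None
    provenance: list[str] = field(default_factory=list)

    @property
    def root_value(self) -> float | None:
        return self._root_value

    _root_value: float | None = None


def _leaf_value(
    node,
    state: Mapping[str, float],
    value_functions: Mapping[str, Sequence[ValueFunction]],
    log: list[str],
) -> float | None:
    """Median value over the leaf's available attribute measurements."""
    vals = []
    for abbr in node.attributes:
        if abbr not in state or state[abbr] is None:
            continue
        x = state[abbr]
        if isinstance(x, float) and np.isnan(x):
            continue
        vfs = value_functions.get(abbr, ())
        if not vfs:
            continue
        per_source = [evaluate(vf, x) for vf in vfs]
        vals.append(statistics.median(per_source))
    if not vals:
        log.append(f"{node.id}: no assessable attribute, marked missing")
        return None
    return float(statistics.median(vals))


def rollup(
    h: Hierarchy,
    state: Mapping[str, float],
    specs: Mapping[str, AggregationSpec],
    value_functions: Mapping[str, Sequence[ValueFunction]],
) -> AssessmentResult:
    """Roll attribute measurements up the hierarchy to the root value.

    ``state`` maps attribute abbreviation -> measured level (missing
    attributes may be absent, None, or NaN).  Leaves take the median value
    across their available value-function sources; internal nodes apply
    their :class:`AggregationSpec`.  Children without a value are dropped
    and the sibling weights renormalized (logged in the provenance); a node
    whose children are all missing is itself missing.  A missing root
    raises.
    """
    result = AssessmentResult()
    values = result.node_values
    log = result.provenance
    # iterative post-order over the tree (the test oracle recurses instead)
    order: list[str] = []
    stack = [h.root.id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(h.nodes[nid].children)
    for nid in reversed(order):
        node = h.nodes[nid]
        if node.is_leaf:
            if not node.assessable or not node.attributes:
                log.append(f"{nid}: non-assessable placeholder, skipped")
                continue
            val = _leaf_value(node, state, value_functions, log)
            if val is not None:
                if not 0 <= val <= 1:
                    raise AggregationError(f"{nid}: leaf value {val} outside [0, 1]")
                values[nid] = val
            continue
        child_vals, child_w, avail = [], [], []
        spec = specs.get(nid)
        if spec is None:
            # unspecified nodes default to equal-weight additive aggregation
            spec = AggregationSpec(nid, "additive",
                                   tuple([1 / len(node.children)] * len(node.children)))
        weights = spec.weights or tuple([1 / len(node.children)] * len(node.children))
        if len(weights) != len(node.children):
            raise AggregationError(
                f"{nid}: {len(weights)} weights for {len(node.children)} children"
            )
        for cid, w in zip(node.children, weights):
            ok = cid in values
            avail.append(ok)
            if ok:
                child_vals.append(values[cid])
                child_w.append(w)
        if not child_vals or sum(child_w) <= _WTOL:
            log.append(f"{nid}: all children missing, marked missing")
            continue
        if not all(avail):
            child_w = list(renormalize_weights(weights, avail))
            dropped = [c for c, ok in zip(node.children, avail) if not ok]
            log.append(
                f"{nid}: renormalized weights over {len(child_w)} of "
                f"{len(node.children)} children (missing: {', '.join(dropped)})"
            )
        else:
            total = sum(child_w)
            child_w = [w / total for w in child_w]
        values[nid] = spec.apply(child_vals, child_w)
    root_id = h.root.id
    if root_id not in values:
        raise AggregationError("root not assessable: no leaf carries a measurement")
    result._root_value = values[root_id]
    return result
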