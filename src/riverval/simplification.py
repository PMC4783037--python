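"""Headline summaries and full-vs-simplified model comparison.

Four simplifications are common in applied multi-criteria river
assessment: restricting attention to a handful of objectives, assuming
linear value functions, aggregating additively, and assuming risk
neutrality.  This module quantifies how elicited preferences depart from
those assumptions (shape, aggregation-choice, and weight-variation
censuses) and compares assessments under the full elicited model against a
simplified variant with any subset of the four assumptions switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import (
    AggregationSpec,
    aggregate_multiplicative,
    rollup,
)
from .elicitation import ExpertWeightTable, global_weights, variation_stats
from .hierarchy import Hierarchy
from .risk_utility import UtilityFunction, apply_risk
from .value_functions import ValueFunction, classify_shape, linearize


def round_half_up_pct(fraction: float) -> int:
    """Percentage rounded half-up to an integer (0.755 -> 76)."""
    return int(math.floor(fraction * 100 + 0.5))


@dataclass
class SimplificationConfig:
    """Which of the four common simplifications to apply.

    Each flag is independently toggleable; ``restrict_to_top_objectives``
    keeps the n highest-global-weight leaves (None = keep all; the common
    practice is five to ten).
    """

    linearize_value_functions: bool = False
    force_additive: bool = False
    force_risk_neutral: bool = False
    restrict_to_top_objectives: int | None = None

    @property
    def any_active(self) -> bool:
        return (self.linearize_value_functions or self.force_additive
                or self.force_risk_neutral
                or self.restrict_to_top_objectives is not None)


@dataclass
class PreferenceFixture:
    """Everything elicited for one assessment model.

    ``specs`` is the consolidated per-node aggregation model;
    ``value_functions`` maps attribute abbreviation -> the available
    sources' functions; ``weight_tables`` and ``synergy_entries`` hold the
    per-expert raw material behind the consolidated model; ``utility`` is
    the root value->utility transform (None = risk neutral).
    """

    hierarchy: Hierarchy
    value_functions: dict[str, list[ValueFunction]]
    specs: dict[str, AggregationSpec]
    weight_tables: list[ExpertWeightTable] = field(default_factory=list)
    synergy_entries: dict[str, float | None] = field(default_factory=dict)
    utility: UtilityFunction | None = None

    def validate(self) -> list[str]:
        problems = self.hierarchy.validate()
        for nid, spec in self.specs.items():
            node = self.hierarchy.nodes.get(nid)
            if node is None:
                problems.append(f"{nid}: aggregation spec for unknown node")
            elif node.is_leaf:
                problems.append(f"{nid}: aggregation spec attached to a leaf")
            elif spec.weights and len(spec.weights) != len(node.children):
                problems.append(f"{nid}: weight count != child count")
        for abbr in self.value_functions:
            if abbr not in self.hierarchy.catalogue:
                problems.append(f"{abbr}: value function for unknown attribute")
        return problems


# -- censuses --------------------------------------------------------------


def summarize_shapes(
    vfs: Iterable[ValueFunction], tol: float = 0.02
) -> dict:
    """Census of value-function records by source, kind, and shape.

    Counts partition the input: every record is either expert-sourced or
    from the literature, and either continuous or discrete.  Shape
    classification (chord deviation > ``tol`` on the value scale =
    nonlinear) covers the continuous records that carry a curve; records
    without one are counted but not classified.  ``pct_nonlinear`` is
    rounded half-up over the classified records.
    """
    vfs = list(vfs)
    n_expert = sum(1 for vf in vfs if vf.source != "literature")
    n_discrete = sum(1 for vf in vfs if vf.kind == "discrete")
    n_continuous = sum(1 for vf in vfs if vf.kind == "continuous")
    n_continuous_expert = sum(
        1 for vf in vfs if vf.kind == "continuous" and vf.source != "literature"
    )
    classifiable = [vf for vf in vfs if vf.kind == "continuous" and vf.limbs]
    n_linear = sum(1 for vf in classifiable if classify_shape(vf, tol) == "linear")
    n_classified = len(classifiable)
    n_nonlinear = n_classified - n_linear
    return {
        "n_total": len(vfs),
        "n_expert": n_expert,
        "n_literature": len(vfs) - n_expert,
        "n_continuous": n_continuous,
        "n_continuous_expert": n_continuous_expert,
        "n_discrete": n_discrete,
        "n_classified": n_classified,
        "n_linear": n_linear,
        "n_nonlinear": n_nonlinear,
        "pct_nonlinear": (round_half_up_pct(n_nonlinear / n_classified)
                          if n_classified else 0),
    }


def summarize_aggregations(records: pd.DataFrame | Sequence) -> dict:
    """Counts and percentage of aggregation decisions by method.

    Accepts the packaged decision table (or anything with a ``method``
    column/attribute).  Percentages are rounded half-up.
    """
    if isinstance(records, pd.DataFrame):
        methods = records["method"].tolist()
    else:
        methods = [getattr(r, "method", r) for r in records]
    counts: dict[str, int] = {}
    for m in methods:
        counts[m] = counts.get(m, 0) + 1
    total = len(methods)
    n_mult = counts.get("multiplicative", 0)
    return {
        "n_total": total,
        "by_method": counts,
        "n_additive": counts.get("additive", 0),
        "n_multiplicative": n_mult,
        "pct_multiplicative": round_half_up_pct(n_mult / total) if total else 0,
    }


def summarize_weight_variation(
    tables: Iterable[ExpertWeightTable], large_threshold: float = 0.4
) -> dict:
    """Count objectives whose between-expert weight range is large.

    Only objectives weighted by at least two experts enter; the fraction is
    over those.  An objective's spread is large when max − min reaches the
    threshold (inclusive).
    """
    n_counted = 0
    n_large = 0
    ranges: dict[str, float] = {}
    for table in tables:
        for obj in table.objectives:
            row = table.row(obj)
            contributing = [c for c in row if c is not None]
            if len(contributing) < 2:
                continue
            stats = variation_stats(row, large_threshold)
            n_counted += 1
            ranges[obj] = stats["range"]
            if stats["large"]:
                n_large += 1
    return {
        "n_objectives": n_counted,
        "n_large": n_large,
        "fraction_large": (n_large / n_counted) if n_counted else 0.0,
        "pct_large": round_half_up_pct(n_large / n_counted) if n_counted else 0,
        "ranges": ranges,
    }


# -- model comparison ------------------------------------------------------


def _simplified_fixture(
    fixture: PreferenceFixture, config: SimplificationConfig
) -> PreferenceFixture:
    h = fixture.hierarchy
    specs = dict(fixture.specs)
    vfs = fixture.value_functions
    utility = fixture.utility
    if config.linearize_value_functions:
        vfs = {abbr: [linearize(vf) for vf in fns] for abbr, fns in vfs.items()}
    if config.force_additive:
        specs = {
            nid: AggregationSpec(nid, "additive", spec.weights)
            for nid, spec in specs.items()
        }
    if config.force_risk_neutral:
        utility = None
    if config.restrict_to_top_objectives is not None:
        n = config.restrict_to_top_objectives
        local = {
            nid: dict(zip(h.nodes[nid].children, spec.weights))
            for nid, spec in specs.items()
            if spec.weights
        }
        gw = global_weights(local, h)
        leaves = [l for l in h.leaves() if l.assessable and l.attributes]
        keep = {l.id for l in sorted(leaves, key=lambda l: -gw.get(l.id, 0.0))[:n]}
        # retain exactly the root-to-kept-leaf paths
        kept_ids: set[str] = set()
        for lid in keep:
            nid: str | None = lid
            while nid is not None and nid not in kept_ids:
                kept_ids.add(nid)
                nid = h.nodes[nid].parent
        from .hierarchy import ObjectiveNode

        nodes = [
            ObjectiveNode(nd.id, nd.name, nd.level, nd.parent, [],
                          list(nd.attributes), dict(nd.labels), nd.assessable)
            for nd in h.nodes.values() if nd.id in kept_ids
        ]
        kept_attrs = {a for nd in nodes for a in nd.attributes}
        h = Hierarchy(nodes, [a for k, a in h.catalogue.items()
                              if k in kept_attrs])
        specs = {
            nid: replace(
                spec,
                weights=tuple(
                    w for c, w in zip(fixture.hierarchy.nodes[nid].children,
                                      spec.weights)
                    if c in h.nodes
                ),
            )
            for nid, spec in specs.items()
            if nid in h.nodes and not h.nodes[nid].is_leaf
        }
        # renormalize surviving sibling weights
        for nid, spec in specs.items():
            total = sum(spec.weights)
            if spec.weights and total > 0:
                specs[nid] = replace(
                    spec, weights=tuple(w / total for w in spec.weights)
                )
    return PreferenceFixture(h, vfs, specs, fixture.weight_tables,
                             fixture.synergy_entries, utility)


def _score(fixture: PreferenceFixture, state: Mapping[str, float]) -> float:
    result = rollup(fixture.hierarchy, state, fixture.specs,
                    fixture.value_functions)
    return apply_risk(result.root_value, fixture.utility)


@dataclass
class ModelComparison:
    """Per-state root scores of the full and the simplified model."""

    scores_full: np.ndarray
    scores_simplified: np.ndarray
    concordant: int
    discordant: int
    tied: int
    reversals: list[tuple[int, int]]

    @property
    def concordance(self) -> float:
        """Kendall-type rank concordance: (C − D) / number of pairs."""
        n_pairs = self.concordant + self.discordant + self.tied
        if n_pairs == 0:
            return 1.0
        return (self.concordant - self.discordant) / n_pairs


def compare_models(
    fixture: PreferenceFixture,
    config: SimplificationConfig,
    states: Sequence[Mapping[str, float]] | pd.DataFrame,
    tie_tol: float = 1e-12,
) -> ModelComparison:
    """Score every river state under the full and the simplified model.

    With all flags off the simplified model is the full model and the
    comparison is the identity (no reversals, concordance 1).  Rank
    agreement is measured by pairwise concordant/discordant counting over
    all state pairs; pairs tied in either ranking count as ties.  The
    reversal list names the discordant state pairs (by position).
    """
    if isinstance(states, pd.DataFrame):
        states = [row.dropna().to_dict() for _, row in states.iterrows()]
    simplified = _simplified_fixture(fixture, config)
    full_scores = np.array([_score(fixture, s) for s in states])
    simp_scores = np.array([_score(simplified, s) for s in states])
    concordant = discordant = tied = 0
    reversals: list[tuple[int, int]] = []
    n = len(states)
    for i in range(n):
        for j in range(i + 1, n):
            df = full_scores[i] - full_scores[j]
            ds = simp_scores[i] - simp_scores[j]
            if abs(df) <= tie_tol or abs(ds) <= tie_tol:
                tied += 1
            elif df * ds > 0:
                concordant += 1
            else:
                discordant += 1
                reversals.append((i, j))
    return ModelComparison(full_scores, simp_scores, concordant, discordant,
                           tied, reversals)


# -- synergy demonstration -------------------------------------------------


def synergy_demo(
    weights: Sequence[float], k: float, n_grid: int = 101
) -> dict[str, np.ndarray]:
    """Joint-vs-lone improvement curves for multiplicative aggregation.

    ``joint(t)`` raises all n objectives together from 0 to t;
    ``lone(t)`` raises one objective at a time to t (others at 0) and sums
    the resulting aggregates.  For k = 1 the two curves coincide (no
    synergy: additive); for k < 1 improving everything together beats the
    summed lone improvements at the top end (lone(1) < joint(1) = 1).
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 2:
        raise ValueError("synergy demonstration needs n >= 2 objectives")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be normalized")
    t = np.linspace(0.0, 1.0, n_grid)
    joint = np.array(
        [aggregate_multiplicative(np.full(w.size, ti), w, k) for ti in t]
    )
    lone = np.zeros_like(t)
    for i in range(w.size):
        for j, ti in enumerate(t):
            v = np.zeros(w.size)
            v[i] = ti
            lone[j] += aggregate_multiplicative(v, w, k)
    return {"t": t, "joint": joint, "lone": lone}
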