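"""Objectives hierarchy: data model, consolidation, and serialization.

An objectives hierarchy decomposes an overall goal (here: the ecological
state of a river reach) into sub-objectives arranged on levels 1..5 below a
level-0 root.  Lowest-level objectives carry one or more measurable
attributes (indicators) with a defined worst--best range.  Experts label
objectives as ``essential`` / ``very_valuable`` / ``desirable``; the
consolidated hierarchy keeps exactly those objectives labelled essential by
at least one expert.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

ESSENTIALITY_CATEGORIES = ("essential", "very_valuable", "desirable")

ROOT_ID = "ecological_state"


class HierarchyError(ValueError):
    """Structural invariant violation in a hierarchy document."""


@dataclass
class Attribute:
    """A measurable indicator attached to a lowest-level objective.

    ``worst``/``best`` span the attribute scale from the worst-possible to
    the best-possible level; the worst level may be numerically larger (a
    decreasing orientation, e.g. maximum summer temperature 24–10 °C).
    Unimodal attributes carry a second limb starting at ``worst2`` whose best
    end is ``peak2`` (equal to ``best`` when both limbs share the optimum).
    Discrete attributes enumerate their admissible levels.
    """

    abbreviation: str
    number: int | None = None
    measure: str = ""
    unit: str = ""
    worst: float | None = None
    best: float | None = None
    peak: float | None = None
    worst2: float | None = None
    peak2: float | None = None
    discrete: bool = False
    levels: tuple[float, ...] | None = None  # admissible discrete levels
    source: str = "expert"
    has_value_function: bool = True
    flagged: bool = False
    note: str = ""

    @property
    def is_unimodal(self) -> bool:
        return self.worst2 is not None

    @property
    def orientation(self) -> str:
        if self.is_unimodal:
            return "unimodal"
        if self.worst is None or self.best is None:
            return "undefined"
        return "increasing" if self.worst < self.best else "decreasing"

    def domain(self) -> list[tuple[float, float]]:
        """Closed interval(s) of admissible continuous levels, one per limb."""
        if self.worst is None or self.best is None:
            return []
        first_best = self.peak if self.peak is not None else self.best
        limbs = [(min(self.worst, first_best), max(self.worst, first_best))]
        if self.is_unimodal:
            b2 = self.peak2 if self.peak2 is not None else first_best
            limbs.append((min(self.worst2, b2), max(self.worst2, b2)))
        return limbs


@dataclass
class ObjectiveNode:
    """One objective in the tree.

    ``level`` is 0 for the root and 1..5 below; a node has either children
    (internal objective) or attributes (lowest-level objective), never both.
    ``labels`` maps expert id -> essentiality category.  ``assessable=False``
    marks structural placeholders that carry neither (e.g. a branch excluded
    from elicitation).
    """

    id: str
    name: str
    level: int
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    attributes: list[str] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)
    assessable: bool = True

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Hierarchy:
    """Objectives tree plus its attribute catalogue, keyed by ids."""

    def __init__(
        self,
        nodes: Iterable[ObjectiveNode],
        catalogue: Iterable[Attribute] = (),
    ):
        self.nodes: dict[str, ObjectiveNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise HierarchyError(f"duplicate node id: {node.id}")
            self.nodes[node.id] = node
        self.catalogue: dict[str, Attribute] = {}
        for attr in catalogue:
            if attr.abbreviation in self.catalogue:
                raise HierarchyError(f"duplicate attribute: {attr.abbreviation}")
            self.catalogue[attr.abbreviation] = attr
        self._link_children()

    def _link_children(self) -> None:
        """Recompute child lists from parent pointers, preserving input order."""
        for node in self.nodes.values():
            node.children = []
        for node in self.nodes.values():
            if node.parent is not None:
                parent = self.nodes.get(node.parent)
                if parent is not None:
                    parent.children.append(node.id)

    # -- basic queries ----------------------------------------------------

    @property
    def root(self) -> ObjectiveNode:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise HierarchyError(f"expected one root, found {len(roots)}")
        return roots[0]

    def leaves(self) -> list[ObjectiveNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def subtree_ids(self, node_id: str) -> list[str]:
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return out

    # -- validation -------------------------------------------------------

    def validate(self) -> list[str]:
        """Return one message per invariant violation (empty list = valid)."""
        problems: list[str] = []
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            problems.append(f"hierarchy must have exactly one root, found {len(roots)}")
        for node in self.nodes.values():
            if node.parent is not None:
                parent = self.nodes.get(node.parent)
                if parent is None:
                    problems.append(f"{node.id}: dangling parent {node.parent!r}")
                elif node.level <= parent.level:
                    problems.append(
                        f"{node.id}: level {node.level} not below parent level {parent.level}"
                    )
            if node.children and node.attributes:
                problems.append(f"{node.id}: has both children and attributes")
            if not node.children and not node.attributes and node.assessable:
                problems.append(f"{node.id}: assessable leaf without attributes")
            for abbr in node.attributes:
                if abbr not in self.catalogue:
                    problems.append(f"{node.id}: unknown attribute {abbr!r}")
        # connectivity: every node reachable from the root
        if len(roots) == 1:
            reachable = set(self.subtree_ids(roots[0].id))
            for nid in self.nodes:
                if nid not in reachable:
                    problems.append(f"{nid}: unreachable from root")
        return problems

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def clean(d: dict) -> dict:
            return {k: v for k, v in d.items() if v not in (None, [], {}, "")
                    or k in ("worst", "best")}

        return {
            "nodes": [
                clean(
                    {
                        "id": n.id,
                        "name": n.name,
                        "level": n.level,
                        "parent": n.parent,
                        "attributes": list(n.attributes),
                        "labels": dict(n.labels),
                        "assessable": None if n.assessable else False,
                    }
                )
                for n in self.nodes.values()
            ],
            "attributes": [
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(a).items()
                 if v not in (None, "", False) or k in ("worst", "best", "discrete")}
                for a in self.catalogue.values()
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Hierarchy":
        nodes = []
        for nd in doc.get("nodes", []):
            nodes.append(
                ObjectiveNode(
                    id=nd["id"],
                    name=nd.get("name", nd["id"]),
                    level=int(nd["level"]),
                    parent=nd.get("parent"),
                    attributes=list(nd.get("attributes", [])),
                    labels=dict(nd.get("labels", {})),
                    assessable=bool(nd.get("assessable", True)),
                )
            )
        attrs = []
        for ad in doc.get("attributes", []):
            ad = dict(ad)
            if "levels" in ad and ad["levels"] is not None:
                ad["levels"] = tuple(ad["levels"])
            attrs.append(Attribute(**ad))
        h = cls(nodes, attrs)
        problems = h.validate()
        if problems:
            raise HierarchyError("; ".join(problems))
        return h


def load_hierarchy(source: str | Path | Mapping) -> Hierarchy:
    """Load and validate a hierarchy from a JSON file, JSON text, or mapping.

    Raises :class:`HierarchyError` naming the offending node for duplicate
    ids, dangling parents, assessable leaves without attributes, and unknown
    attribute references.
    """
    if isinstance(source, Mapping):
        return Hierarchy.from_dict(source)
    path = Path(source)
    if path.exists():
        return Hierarchy.from_dict(json.loads(path.read_text(encoding="utf-8")))
    return Hierarchy.from_dict(json.loads(str(source)))


# -- consolidation ---------------------------------------------------------


def consolidate(expert_hierarchies: Sequence[Hierarchy]) -> Hierarchy:
    """Merge labelled expert hierarchies, keeping essential-by-one objectives.

    A node is retained iff at least one expert labelled it ``essential``
    (root nodes are always retained).  Parent links and levels must agree
    wherever a node id appears in several inputs; the attribute catalogues
    share one namespace.  Retained nodes whose parent was dropped are
    removed as well (an objective cannot outlive its branch).
    """
    merged: dict[str, ObjectiveNode] = {}
    catalogue: dict[str, Attribute] = {}
    for h in expert_hierarchies:
        for abbr, attr in h.catalogue.items():
            catalogue.setdefault(abbr, attr)
        for node in h.nodes.values():
            if node.id in merged:
                prev = merged[node.id]
                if prev.parent != node.parent or prev.level != node.level:
                    raise HierarchyError(
                        f"{node.id}: conflicting parentage across experts "
                        f"({prev.parent!r} vs {node.parent!r})"
                    )
                prev.labels.update(node.labels)
                for abbr in node.attributes:
                    if abbr not in prev.attributes:
                        prev.attributes.append(abbr)
            else:
                merged[node.id] = ObjectiveNode(
                    id=node.id,
                    name=node.name,
                    level=node.level,
                    parent=node.parent,
                    attributes=list(node.attributes),
                    labels=dict(node.labels),
                    assessable=node.assessable,
                )

    def essential(node: ObjectiveNode) -> bool:
        return node.parent is None or "essential" in node.labels.values()

    kept = {nid for nid, n in merged.items() if essential(n)}
    # drop nodes whose ancestor chain is broken
    def chain_ok(nid: str) -> bool:
        while True:
            n = merged[nid]
            if n.parent is None:
                return True
            if n.parent not in kept:
                return False
            nid = n.parent

    kept = {nid for nid in kept if chain_ok(nid)}
    nodes = [n for nid, n in merged.items() if nid in kept]
    used = {a for n in nodes for a in n.attributes}
    return Hierarchy(nodes, [a for k, a in catalogue.items() if k in used])


def count_by_level(h: Hierarchy) -> dict:
    """Objective counts per level (root excluded) and their total."""
    per_level: dict[int, int] = {}
    for node in h.nodes.values():
        if node.parent is None:
            continue
        per_level[node.level] = per_level.get(node.level, 0) + 1
    levels = tuple(per_level[k] for k in sorted(per_level))
    return {"per_level": levels, "total": sum(levels)}


# -- weight plumbing -------------------------------------------------------


def renormalize_weights(
    sibling_weights: Sequence[float],
    available: Sequence[bool] | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Rescale the weights of the available siblings to sum to one.

    Used when some sub-objectives cannot be assessed (missing data): the
    remaining weights keep their proportions.  Raises ``ValueError`` when no
    sibling is available or the available weights sum to zero.
    """
    w = np.asarray(sibling_weights, dtype=float)
    if available is None:
        avail = np.ones(len(w), dtype=bool)
    else:
        avail = np.asarray(available, dtype=bool)
        if avail.shape != w.shape:
            raise ValueError("weights and availability flags differ in length")
    if not avail.any():
        raise ValueError("no available sibling to renormalize over")
    total = w[avail].sum()
    if total <= tol:
        raise ValueError("available sibling weights sum to zero")
    return w[avail] / total


def prune_zero_weight(h: Hierarchy, weights: Mapping[str, float]) -> Hierarchy:
    """Remove subtrees whose node weight is 0 (expert-excluded objectives).

    ``weights`` maps node id -> local weight; nodes without an entry are
    kept.  Raises on a zero-weight root and on sibling groups whose weights
    are all zero.
    """
    root = h.root
    if weights.get(root.id, 1.0) == 0:
        raise HierarchyError("root weight is 0: nothing left to assess")
    drop: set[str] = set()
    for node in h.nodes.values():
        if node.children:
            ws = [weights.get(c, 1.0) for c in node.children]
            if node.id not in drop and all(w == 0 for w in ws):
                raise HierarchyError(f"{node.id}: all sibling weights are 0")
        if weights.get(node.id, 1.0) == 0:
            drop.update(h.subtree_ids(node.id))
    nodes = [n for n in h.nodes.values() if n.id not in drop]
    kept_attrs = {a for n in nodes for a in n.attributes}
    out = Hierarchy(
        [ObjectiveNode(n.id, n.name, n.level, n.parent, [], list(n.attributes),
                       dict(n.labels), n.assessable) for n in nodes],
        [a for k, a in h.catalogue.items() if k in kept_attrs],
    )
    return out
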